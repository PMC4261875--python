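"""In-frame stop-codon census.

The fraction of codons in an annotated reading frame that are stop codons is
the raw observable behind neutral-decay dating of an endogenous retrovirus:
once a provirus is fixed in the germ line its reading frames decay neutrally
and in-frame stops accumulate at a clock-like rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import CodingSequence

__all__ = ["STANDARD_STOPS", "StopCodonCensus", "census_stop_codons"]

#: Stop codons of the standard genetic code (mammalian nuclear genomes).
STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class StopCodonCensus:
    """Counts of in-frame stop codons in one reading frame."""

    n_codons: int
    n_stops: int
    stop_positions: list[int] = field(default_factory=list)

    @property
    def frequency(self) -> float:
        return self.n_stops / self.n_codons

    @property
    def frequency_display(self) -> str:
        """The frequency rendered to 3 significant figures."""
        return f"{self.frequency:.3g}"

    def as_dict(self) -> dict:
        return {
            "n_codons": self.n_codons,
            "n_stops": self.n_stops,
            "frequency": self.frequency,
            "frequency_display": self.frequency_display,
            "stop_positions": list(self.stop_positions),
        }


def census_stop_codons(seq: CodingSequence,
                       stop_set: frozenset[str] = STANDARD_STOPS
                       ) -> StopCodonCensus:
    """Count in-frame stop codons in *seq*.

    Counting follows the sequence's own framing rules: gaps are stripped,
    ``frame_offset`` bases are skipped, a trailing partial codon is ignored,
    the terminal codon is excluded when ``exclude_terminal`` is set, and
    codons containing non-ACGT symbols are excluded from both the stop count
    and the codon total.

    Raises ``ValueError`` on an empty reading frame (zero countable codons).
    """
    counted = seq.counted_codons()
    if not counted:
        raise ValueError(f"{seq.id}: empty reading frame")
    stop_positions = [i for i, c in counted if c in stop_set]
    return StopCodonCensus(
        n_codons=len(counted),
        n_stops=len(stop_positions),
        stop_positions=stop_positions,
    )
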