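"""Neutral nucleotide substitution over geological time.

The substitution process is the equal-rates single-site chain (the
Jukes-Cantor model): a site leaves its current base at a total rate *r* and
the replacement is uniform over the other three bases.  That is the unique
Markov chain that is homogeneous and symmetric across sites and base types,
so it formalises a "neutral, homogeneous, independent" decay assumption with
no free parameters beyond the rate.

Sites are sampled directly from the closed-form transition probabilities at
the endpoint,

    P(site unchanged after t years) = 1/4 + (3/4) * exp(-(4/3) r t),

which is distributionally identical to simulating individual substitution
events and runs in O(sites) per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CodingSequence

__all__ = [
    "MAMMAL_NEUTRAL_RATE",
    "OVERESTIMATE_RATE",
    "NeutralModel",
    "evolve_sequence",
    "analytic_stop_probability",
    "mutate_alignment_members",
    "translate_codons",
]

#: Average neutral substitution rate of mammalian genomes (subs/site/year).
MAMMAL_NEUTRAL_RATE = 2.2e-9

#: A deliberate overestimate of the mammalian neutral rate (subs/site/year),
#: used to stress-test whether neutral decay alone can explain a tree
#: placement ("10 x 10^-9").
OVERESTIMATE_RATE = 1.0e-8

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class NeutralModel:
    """Equal-rates neutral substitution model.

    ``rate`` is the total per-site leave rate in substitutions/site/year.
    """

    rate: float = MAMMAL_NEUTRAL_RATE

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("substitution rate must be positive")

    def p_same(self, t: float) -> float:
        """Probability a site shows its original base after *t* years."""
        return 0.25 + 0.75 * np.exp(-(4.0 / 3.0) * self.rate * t)


def _encode(bases: str) -> np.ndarray:
    """Map bases to 0..3, with -1 for gaps/ambiguity (left untouched)."""
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def _decode(codes: np.ndarray, template: str) -> str:
    chars = list(template)
    for i in np.nonzero(codes >= 0)[0]:
        chars[i] = _BASES[codes[i]]
    return "".join(chars)


def mutate_codes(codes: np.ndarray, model: NeutralModel, t: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorised endpoint sampling of the equal-rates chain.

    Entries < 0 (gaps, ambiguity codes) are carried through unchanged.
    """
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    out = codes.copy()
    sites = codes >= 0
    p_same = model.p_same(t)
    changed = sites & (rng.random(codes.shape) > p_same)
    # replacement uniform over the 3 other bases
    offset = rng.integers(1, 4, size=codes.shape)
    out[changed] = (codes[changed] + offset[changed]) % 4
    return out


def evolve_sequence(seq: CodingSequence, model: NeutralModel, t: float,
                    seed=None) -> CodingSequence:
    """Evolve *seq* neutrally for *t* years; reproducible under *seed*.

    Gap and ambiguity symbols keep their positions, so the output has the
    same length and alignment coordinates as the input.  *seed* may be an
    integer or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = _encode(seq.bases)
    mutated = mutate_codes(codes, model, t, rng)
    return CodingSequence(
        id=seq.id,
        bases=_decode(mutated, seq.bases),
        frame_offset=seq.frame_offset,
        exclude_terminal=seq.exclude_terminal,
    )


# match-count table: for each codon id (base-4) and each stop codon, the
# number of positions at which they agree
_MATCHES = np.zeros((64, len(_STOP_CODONS)), dtype=np.int8)
for _cid in range(64):
    _codon = (_cid // 16, (_cid // 4) % 4, _cid % 4)
    for _k, _stop in enumerate(_STOP_CODONS):
        _MATCHES[_cid, _k] = sum(
            _codon[_j] == _CODE[_stop[_j]] for _j in range(3)
        )


def analytic_stop_probability(seq: CodingSequence, model: NeutralModel,
                              t: float) -> float:
    """Exact expected stop-codon frequency of *seq* after *t* years.

    For each counted codon the probability of reading as each stop codon is
    the product over its three sites of stay/change probabilities; the value
    returned is the mean over counted codons.  This is the independent
    closed-form oracle for the Monte-Carlo simulator.
    """
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    counted = seq.counted_codons()
    if not counted:
        raise ValueError(f"{seq.id}: empty reading frame")
    p_s = model.p_same(t)
    p_d = (1.0 - p_s) / 3.0
    cids = np.array(
        [_CODE[c[0]] * 16 + _CODE[c[1]] * 4 + _CODE[c[2]] for _, c in counted]
    )
    m = _MATCHES[cids]  # (n_codons, 3)
    probs = p_s ** m * p_d ** (3 - m)
    return float(probs.sum(axis=1).mean())


_STANDARD_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _STANDARD_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _STANDARD_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _STANDARD_TABLE[stop] = "*"
    return _STANDARD_TABLE


def translate_codons(bases: str, frame_offset: int = 0,
                     stop_symbol: str = "*") -> str:
    """Codon-wise translation preserving alignment coordinates.

    ``---`` translates to ``-``; codons with ambiguity or partial gaps
    translate to ``X``; stops render as *stop_symbol*.
    """
    table = _codon_table()
    s = bases[frame_offset:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        if codon == "---":
            out.append("-")
        elif set(codon) <= set("ACGT"):
            aa = table[codon]
            out.append(stop_symbol if aa == "*" else aa)
        else:
            out.append("X")
    return "".join(out)


@dataclass
class MutatedAlignment:
    """Neutrally mutated alignment members: nucleotide and translated."""

    nucleotide: list[CodingSequence]
    protein: list[tuple[str, str]]  # (id, amino-acid string)


def mutate_alignment_members(seqs: list[CodingSequence], model: NeutralModel,
                             t: float, seed=None) -> MutatedAlignment:
    """Mutate each member of an in-frame alignment for *t* years.

    Each sequence gets an independent random stream derived from *seed*;
    ids and order are preserved, and no re-alignment is performed (gap
    columns keep their coordinates), so the translated output can be
    re-inserted into the source protein alignment directly.
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(seqs))
    nt, aa = [], []
    for seq, stream in zip(seqs, streams):
        mutated = evolve_sequence(
            seq, model, t, seed=np.random.default_rng(stream)
        )
        nt.append(mutated)
        aa.append(
            (mutated.id, translate_codons(mutated.bases, seq.frame_offset))
        )
    return MutatedAlignment(nucleotide=nt, protein=aa)
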