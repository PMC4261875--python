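"""Input/output and the shared sequence data model.

FASTA reading and writing goes through Biopython's SeqIO; trees come from
:mod:`paleofv.trees`; tip associations and host node ages travel as plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import NodeAges, PhyloTree, read_newick, write_newick  # noqa: F401

__all__ = [
    "CodingSequence",
    "TipAssociation",
    "read_fasta",
    "write_fasta",
    "read_associations",
    "write_associations",
    "validate_inputs",
]

_VALID = set("ACGTN-")
_ACGT = set("ACGT")


@dataclass
class CodingSequence:
    """An in-frame nucleotide sequence.

    ``frame_offset`` bases are skipped before the first codon; a trailing
    partial codon is ignored.  With ``exclude_terminal`` (the default) the
    last full codon of the span — the position where an annotated reading
    frame would carry its natural stop — is excluded from all codon counts.
    Codons containing any symbol outside A/C/G/T (gaps are stripped before
    framing) are excluded from both numerator and denominator of any
    frequency computed downstream.
    """

    id: str
    bases: str
    frame_offset: int = 0
    exclude_terminal: bool = True

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - _VALID
        if bad:
            raise ValueError(
                f"{self.id}: invalid symbols {sorted(bad)}; "
                "expected A,C,G,T,N,-"
            )
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be >= 0")

    def ungapped(self) -> str:
        return self.bases.replace("-", "")

    def framed_codons(self) -> list[str]:
        """All full codons of the span (gaps stripped, offset applied)."""
        s = self.ungapped()[self.frame_offset:]
        return [s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    def counted_codons(self) -> list[tuple[int, str]]:
        """(index, codon) pairs entering codon counts.

        Indices are positions in :meth:`framed_codons`.  The terminal codon
        is dropped when ``exclude_terminal`` is set; ambiguous codons
        (non-ACGT symbols) are dropped from the count entirely.
        """
        codons = self.framed_codons()
        if self.exclude_terminal and codons:
            codons = codons[:-1]
        return [
            (i, c) for i, c in enumerate(codons) if set(c) <= _ACGT
        ]

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta(path) -> list[CodingSequence]:
    """Read a FASTA file; one record per header, order preserved, uppercased."""
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(
                f"{path}:{lineno}: expected FASTA header '>' , got "
                f"{first.strip()[:30]!r}"
            )
    records = list(SeqIO.parse(str(path), "fasta"))
    out = []
    for rec in records:
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        out.append(CodingSequence(id=rec.id, bases=str(rec.seq).upper()))
    return out


def write_fasta(seqs: list[CodingSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class TipAssociation:
    """A bijection between virus tip labels and host tip labels."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        hosts = list(self.pairs.values())
        dupes = sorted({h for h in hosts if hosts.count(h) > 1})
        if dupes:
            raise ValueError(f"host tips associated more than once: {dupes}")

    def host_of(self, virus_tip: str) -> str:
        return self.pairs[virus_tip]

    def virus_of(self, host_tip: str) -> str:
        return {h: v for v, h in self.pairs.items()}[host_tip]

    def items(self):
        return self.pairs.items()

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, vtree: PhyloTree, htree: PhyloTree) -> None:
        """Require the association to cover exactly both trees' tip sets."""
        vtips = set(vtree.tip_labels())
        htips = set(htree.tip_labels())
        if set(self.pairs) != vtips:
            missing = sorted(vtips - set(self.pairs))
            extra = sorted(set(self.pairs) - vtips)
            raise ValueError(
                f"association does not match virus tips "
                f"(missing={missing}, unknown={extra})"
            )
        if set(self.pairs.values()) != htips:
            missing = sorted(htips - set(self.pairs.values()))
            extra = sorted(set(self.pairs.values()) - htips)
            raise ValueError(
                f"association does not match host tips "
                f"(missing={missing}, unknown={extra})"
            )


def read_associations(path) -> TipAssociation:
    """Read a two-column TSV (virus_tip, host_tip) into a bijection."""
    pairs: dict[str, str] = {}
    dup_v: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            v, h = cols
            if v in pairs:
                dup_v.append(v)
            pairs[v] = h
    if dup_v:
        raise ValueError(f"virus tips associated more than once: {sorted(set(dup_v))}")
    return TipAssociation(pairs)


def write_associations(assoc: TipAssociation, path) -> None:
    with open(path, "w") as fh:
        for v, h in sorted(assoc.items()):
            fh.write(f"{v}\t{h}\n")


def validate_inputs(vtree: PhyloTree, htree: PhyloTree,
                    assoc: TipAssociation,
                    ages: NodeAges | None = None) -> None:
    """Cross-check a virus tree, host tree, association and optional ages."""
    if not vtree.is_binary():
        raise ValueError("virus tree must be binary")
    if not htree.is_binary():
        raise ValueError("host tree must be binary")
    assoc.validate(vtree, htree)
    if ages is not None:
        ages.validate(htree)
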