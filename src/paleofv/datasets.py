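"""Bundled mammalian foamy-virus study system.

Seventeen foamy viruses (extant simian/feline/bovine/equine viruses plus the
endogenous elements of the sloth, the aye-aye and the Cape golden mole, and
the bat virus RhiFV) and their mammalian hosts.  The virus topology follows
the published Bayesian phylogeny of concatenated Pol-Env proteins: the
golden-mole element ChrEFV is basal (mirroring the Afrotheria split); the
aye-aye element PSFVaye and the bat virus RhiFV form a weakly supported
sister pair placed outside the boreoeutherian virus clade but inside the
exafroplacentalian clade; the New World monkey viruses do not mirror their
hosts' internal branching order; everything else is congruent with the host
tree.

Because the published figure is a drawing, the topologies here are a
transcription of that figure's narrative description, with no branch
lengths on the virus tree (the underlying estimates are not published as
numbers).  Host node ages are APPROXIMATE values from published mammal
timetrees, bundled for worked examples; only the 101.1 Ma exafroplacentalian
radiation is used as an actual calibration constant.
"""

from __future__ import annotations

from fractions import Fraction

from .io import TipAssociation
from .trees import NodeAges, PhyloTree

__all__ = [
    "foamy_virus_tree",
    "host_tree",
    "fv_host_associations",
    "host_node_ages",
    "PSFVAYE_N_CODONS",
    "PSFVAYE_N_STOPS",
    "CHREFV_N_CODONS",
    "CHREFV_N_STOPS",
    "PSFVAYE_STOP_FREQUENCY",
    "CHREFV_STOP_FREQUENCY",
    "OBSERVED_COSPECIATIONS",
    "CONSERVATIVE_COSPECIATIONS",
    "EXAFROPLACENTALIA_AGE_MA",
    "PSFVAYE_RHIFV_STEM_BRANCH",
]

# Stop-codon census of the endogenous Pol reading frames (terminal codon
# excluded): the aye-aye element has 9 stops in 1,163 codons, the golden-mole
# element 14 in 975.
PSFVAYE_N_CODONS = 1163
PSFVAYE_N_STOPS = 9
CHREFV_N_CODONS = 975
CHREFV_N_STOPS = 14
PSFVAYE_STOP_FREQUENCY = float(Fraction(PSFVAYE_N_STOPS, PSFVAYE_N_CODONS))
CHREFV_STOP_FREQUENCY = float(Fraction(CHREFV_N_STOPS, CHREFV_N_CODONS))

#: Cospeciation count of the maximum-cospeciation reconciliation.
OBSERVED_COSPECIATIONS = 14
#: Conservative re-count discounting the PSFVaye/RhiFV node, whose
#: cospeciation reading requires an unsampled host lineage.
CONSERVATIVE_COSPECIATIONS = 13

#: Calibration: age of the exafroplacentalian radiation (Ma).
EXAFROPLACENTALIA_AGE_MA = 101.1
#: Parental branch of the RhiFV + PSFVaye pair (aa substitutions/site).
PSFVAYE_RHIFV_STEM_BRANCH = 0.0564

_HOST_NEWICK = """
(golden_mole,(sloth,(((aye_aye,galago),((marmoset,(squirrel_monkey,
spider_monkey)),((african_green_monkey,macaque),(orangutan,(gorilla,
(chimpanzee,human)))))),(horseshoe_bat,(cow,(horse,cat))))));
""".replace("\n", "")

_VIRUS_NEWICK = """
(ChrEFV,((PSFVaye,RhiFV),(SloEFV,((PSFVgal,((SFVsqu,(SFVmar,SFVspm)),
((SFVagm,SFVmac),(SFVora,(SFVgor,(SFVcpz,SFVhum)))))),(BFV,(EFV,FFV))))));
""".replace("\n", "")

_ASSOCIATIONS = {
    "ChrEFV": "golden_mole",
    "SloEFV": "sloth",
    "PSFVaye": "aye_aye",
    "PSFVgal": "galago",
    "SFVmar": "marmoset",
    "SFVsqu": "squirrel_monkey",
    "SFVspm": "spider_monkey",
    "SFVagm": "african_green_monkey",
    "SFVmac": "macaque",
    "SFVora": "orangutan",
    "SFVgor": "gorilla",
    "SFVcpz": "chimpanzee",
    "SFVhum": "human",
    "RhiFV": "horseshoe_bat",
    "BFV": "cow",
    "EFV": "horse",
    "FFV": "cat",
}

# Approximate node ages (Ma) for the host tree above, for worked examples.
_HOST_AGES = [
    (("golden_mole", "rest"), 105.0),        # placental root
    (("sloth", "rest"), EXAFROPLACENTALIA_AGE_MA),
    (("primates", "laurasiatheria"), 96.0),  # boreoeutherian radiation
    (("aye_aye", "anthropoids"), 74.0),      # strepsirrhine/haplorhine
    (("aye_aye", "galago"), 59.0),
    (("marmoset", "macaque"), 43.0),         # platyrrhine/catarrhine
    (("marmoset", "squirrel_monkey"), 20.0),
    (("squirrel_monkey", "spider_monkey"), 16.0),
    (("macaque", "human"), 29.0),            # catarrhine crown
    (("african_green_monkey", "macaque"), 14.0),
    (("orangutan", "human"), 16.0),
    (("gorilla", "human"), 9.0),
    (("chimpanzee", "human"), 6.7),
    (("horseshoe_bat", "cat"), 78.0),        # laurasiatherian crown
    (("cow", "cat"), 76.0),
    (("horse", "cat"), 74.0),
]


def host_tree() -> PhyloTree:
    """The 17-taxon mammal host topology."""
    return PhyloTree.from_newick(_HOST_NEWICK)


def foamy_virus_tree() -> PhyloTree:
    """The 17-taxon foamy virus topology (no branch lengths)."""
    return PhyloTree.from_newick(_VIRUS_NEWICK)


def fv_host_associations() -> TipAssociation:
    """The virus-to-host tip bijection."""
    return TipAssociation(dict(_ASSOCIATIONS))


def host_node_ages() -> NodeAges:
    """Approximate ages (Ma) for every internal node of the host tree."""
    tree = host_tree()
    tipsets = {n: tree.tip_set(n) for n in tree.internal_nodes()}
    ages = {}
    for (a, b), age in _HOST_AGES:
        if a == "golden_mole" and b == "rest":
            ages[tree.tip_set(tree.root)] = age
            continue
        if b == "rest":
            ages[tree.tip_set(tree.root.children[1])] = age
            continue
        anchors = {
            "primates": "aye_aye", "laurasiatheria": "horseshoe_bat",
            "anthropoids": "marmoset",
        }
        a = anchors.get(a, a)
        b = anchors.get(b, b)
        best = min(
            (ts for ts in tipsets.values() if {a, b} <= ts), key=len
        )
        ages[best] = age
    table = NodeAges(ages)
    table.validate(tree)
    return table
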