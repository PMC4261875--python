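"""Synthetic fixtures with the statistical structure the analyses assume.

Every generator is deterministic under its seed and produces objects (or
standard-format files) that the analysis modules consume unchanged:
protein-coding sequences with controllable codon usage and planted stop
codons, congruent host/virus tree pairs with a controllable number of host
switches, and branch-length/duration pairs following a linear relation with
Gaussian noise and planted gross outliers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .census import STANDARD_STOPS
from .codivergence import BranchPair
from .io import CodingSequence, TipAssociation
from .trees import PhyloTree, TreeNode

__all__ = [
    "CodonUsageProfile",
    "CophyloScenario",
    "make_coding_sequence",
    "make_cophylo_pair",
    "make_regression_pairs",
    "simulate_yule_tree",
]

_SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STANDARD_STOPS
)

# A generic globular-protein amino-acid composition (percent), used to build
# a retroviral-polymerase-like codon usage stand-in.  Chosen a priori; tests
# never depend on it matching any real sequence.
_AA_COMPOSITION = {
    "A": 7.4, "R": 4.2, "N": 4.4, "D": 5.9, "C": 3.3, "E": 5.8, "Q": 3.7,
    "G": 7.4, "H": 2.9, "I": 3.8, "L": 7.6, "K": 7.2, "M": 1.8, "F": 4.0,
    "P": 5.0, "S": 8.1, "T": 6.2, "W": 1.3, "Y": 3.3, "V": 6.8,
}


@dataclass
class CodonUsageProfile:
    """A probability distribution over the 61 sense codons."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        bad = set(self.probs) - set(_SENSE_CODONS)
        if bad:
            raise ValueError(
                f"profile may only contain sense codons; got {sorted(bad)}"
            )
        values = np.array(list(self.probs.values()))
        if (values < 0).any():
            raise ValueError("codon probabilities must be >= 0")
        if abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("codon probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "CodonUsageProfile":
        p = 1.0 / len(_SENSE_CODONS)
        return cls({c: p for c in _SENSE_CODONS})

    @classmethod
    def concentrated(cls, codon: str) -> "CodonUsageProfile":
        return cls({codon: 1.0})

    @classmethod
    def fv_pol_like(cls) -> "CodonUsageProfile":
        """A stand-in for retroviral pol codon usage.

        SYNTHETIC: built from a generic globular-protein amino-acid
        composition with uniform synonymous codon use, not from any real
        viral sequence.
        """
        from Bio.Data.CodonTable import standard_dna_table

        by_aa: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        total = sum(_AA_COMPOSITION.values())
        probs: dict[str, float] = {}
        for aa, weight in _AA_COMPOSITION.items():
            codons = by_aa[aa]
            for c in codons:
                probs[c] = weight / total / len(codons)
        return cls(probs)


def make_coding_sequence(n_codons: int,
                         usage: CodonUsageProfile | None = None,
                         n_stops_planted: int = 0,
                         seed=None,
                         id: str = "synthetic") -> CodingSequence:
    """A synthetic in-frame sequence with exactly *n_stops_planted* stops.

    Draws *n_codons* sense codons i.i.d. from *usage* (uniform by default),
    overwrites *n_stops_planted* random positions with stop codons, and
    appends a terminal stop, so a census with the default terminal exclusion
    reports exactly (n_stops_planted, n_codons).
    """
    if n_stops_planted > n_codons:
        raise ValueError("cannot plant more stops than codons")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    usage = usage or CodonUsageProfile.uniform()
    rng = np.random.default_rng(seed)
    codons_pool = list(usage.probs)
    weights = np.array([usage.probs[c] for c in codons_pool])
    codons = list(rng.choice(codons_pool, size=n_codons, p=weights))
    stops = sorted(STANDARD_STOPS)
    for pos in rng.choice(n_codons, size=n_stops_planted, replace=False):
        codons[pos] = stops[rng.integers(len(stops))]
    codons.append(stops[rng.integers(len(stops))])  # terminal stop
    return CodingSequence(id=id, bases="".join(codons))


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None,
                       prefix: str = "H") -> PhyloTree:
    """A pure-birth (Yule) ultrametric tree with labelled tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    root = TreeNode()
    active = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    born = {node: 0.0 for node in active}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.length = t - born[node]
        children = [node.add_child(TreeNode()), node.add_child(TreeNode())]
        for c in children:
            born[c] = t
        active.extend(children)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, tip in enumerate(active):
        tip.label = f"{prefix}{i + 1}"
        tip.length = t - born[tip]
    return PhyloTree(root)


@dataclass
class CophyloScenario:
    """Parameters of a simulated host/virus tree pair."""

    n_tips: int
    n_switches: int = 0
    birth_rate: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_switches <= self.n_tips - 1:
            raise ValueError("need 0 <= n_switches <= n_tips - 1")


def _tip_spr(tree: PhyloTree, tip_label: str, rng: np.random.Generator
             ) -> dict:
    """Prune *tip_label* and regraft it onto a random non-adjacent branch."""
    tip = tree.find_tip(tip_label)
    parent = tip.parent
    if parent is None:
        raise ValueError("cannot move the root")
    sibling = next(c for c in parent.children if c is not tip)
    old_sibling_clade = sorted(tree.tip_set(sibling))
    # remove tip, splice sibling into grandparent (or make it the root)
    grand = parent.parent
    if grand is None:
        sibling.parent = None
        sibling.length = None
        tree.root = sibling
    else:
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
        sibling.length = (sibling.length or 0.0) + (parent.length or 0.0)
    # candidate regraft edges: any non-root node except the old sibling spot
    candidates = [
        n for n in tree.postorder()
        if n.parent is not None and n is not sibling and n is not tip
    ]
    if not candidates:
        raise ValueError("no regraft position available")
    target = candidates[rng.integers(len(candidates))]
    new_parent = TreeNode(length=(target.length or 0.0) / 2.0)
    tgt_parent = target.parent
    tgt_parent.children[tgt_parent.children.index(target)] = new_parent
    new_parent.parent = tgt_parent
    target.length = (target.length or 0.0) / 2.0
    new_parent.add_child(target)
    new_parent.add_child(tip)
    return {
        "tip": tip_label,
        "old_sibling_clade": old_sibling_clade,
        "new_sibling_clade": sorted(tree.tip_set(target)),
    }


def make_cophylo_pair(scenario: CophyloScenario
                      ) -> tuple[PhyloTree, PhyloTree, TipAssociation, dict]:
    """A congruent host/virus tree pair with planted host switches.

    The host tree is a Yule simulation; the virus tree starts as an exact
    copy (host switching leaves the host tree untouched) and then receives
    ``n_switches`` tip subtree-prune-regraft moves, each recorded in the
    returned truth ledger.  Associations are the identity V_i <-> H_i.
    """
    rng = np.random.default_rng(scenario.seed)
    htree = simulate_yule_tree(
        scenario.n_tips, scenario.birth_rate, seed=rng, prefix="H"
    )
    vtree = htree.copy()
    for tip in vtree.tips():
        tip.label = "V" + tip.label[1:]
    moves = []
    if scenario.n_switches and scenario.n_tips < 4:
        raise ValueError("switches need at least 4 tips to change topology")
    moved: set[str] = set()
    for _ in range(scenario.n_switches):
        pool = [t for t in vtree.tip_labels() if t not in moved]
        label = pool[rng.integers(len(pool))]
        moves.append(_tip_spr(vtree, label, rng))
        moved.add(label)
    assoc = TipAssociation(
        {v: "H" + v[1:] for v in vtree.tip_labels()}
    )
    truth = {"n_switches": scenario.n_switches, "moves": moves}
    return vtree, htree, assoc, truth


def make_regression_pairs(n: int = 23,
                          slope: float = 0.007,
                          intercept: float = 0.001,
                          noise_sd: float = 0.01,
                          outliers: list[tuple[float, float]] | None = None,
                          x_range: tuple[float, float] = (1.0, 101.0),
                          seed=None) -> tuple[list[BranchPair], dict]:
    """Branch pairs on a noisy line, with optional verbatim outliers.

    Defaults emulate a mammal-scale codivergence scatter: host durations
    uniform over ~1-100 Myr and a virus divergence rate of 0.007 amino-acid
    substitutions/site per Myr.  Planted outliers are appended after the *n*
    regular points, so their indices are n, n+1, ... in the truth ledger.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.0)
    pairs = [
        BranchPair(
            virus_branch_length=float(yi),
            host_duration=float(xi),
            virus_label=f"sim{i}",
            host_label=f"sim{i}",
        )
        for i, (xi, yi) in enumerate(zip(x, y))
    ]
    outliers = outliers or []
    for j, (xo, yo) in enumerate(outliers):
        pairs.append(
            BranchPair(
                virus_branch_length=float(yo),
                host_duration=float(xo),
                virus_label=f"outlier{j}",
                host_label=f"outlier{j}",
            )
        )
    truth = {
        "slope": slope,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "outlier_indices": list(range(n, n + len(outliers))),
    }
    return pairs, truth
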