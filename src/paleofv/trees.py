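"""Rooted phylogenetic trees and host-node age tables.

Trees are kept in a deliberately small in-memory form (labelled nodes with
branch lengths) because the reconciliation solver needs fast parent/child and
ancestor queries on both trees.  Newick reading and writing is delegated to
dendropy so that quoting, comments and the usual dialect corner cases are
handled by a maintained parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["TreeNode", "PhyloTree", "NodeAges", "read_newick", "write_newick"]


class TreeNode:
    """A node of a rooted tree: optional label, branch length to parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class PhyloTree:
    """A rooted tree with unique tip labels.

    Virus trees carry branch lengths in amino-acid substitutions/site; host
    trees are used for topology, with dating supplied separately through
    :class:`NodeAges`.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [t.label for t in self.tips()]
        if any(l is None for l in labels):
            raise ValueError("every tip must be labelled")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from walk(c)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_tip]

    # -- queries -----------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def tip_set(self, node: TreeNode) -> frozenset[str]:
        return frozenset(
            t.label for t in (n for n in _subtree(node) if n.is_tip)
        )

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(label)

    def depths(self) -> dict[TreeNode, float]:
        """Sum of branch lengths from the root to each node (root depth 0)."""
        out: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # -- Newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=False,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(_from_dendropy(dtree.seed_node))

    def to_newick(self) -> str:
        dtree = dendropy.Tree()
        _to_dendropy(self.root, dtree.seed_node)
        s = dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree(n_tips={self.n_tips})"


def _subtree(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label, dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _to_dendropy(node: TreeNode, dnode) -> None:
    if node.is_tip:
        dnode.taxon = dendropy.Taxon(label=node.label)
    elif node.label:
        dnode.label = node.label
    dnode.edge.length = node.length
    for child in node.children:
        _to_dendropy(child, dnode.new_child())


def read_newick(path) -> PhyloTree:
    """Read a single-tree Newick file into a :class:`PhyloTree`."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty Newick file: {path}")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


@dataclass
class NodeAges:
    """Ages (Myr before present) of host clades, keyed by their tip sets.

    Published host timetrees report node ages rather than branch lengths, and
    the tip set is the stable identifier of a clade across re-drawings of the
    tree, so ages are carried in this table instead of being baked into
    branch lengths.  Tips default to age 0 (extant taxa).
    """

    ages: dict[frozenset[str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = {frozenset(k): float(v) for k, v in self.ages.items()}

    def age_of(self, tip_set: frozenset[str]) -> float:
        tip_set = frozenset(tip_set)
        if len(tip_set) == 1:
            return self.ages.get(tip_set, 0.0)
        if tip_set not in self.ages:
            raise KeyError(
                f"no age recorded for clade {{{', '.join(sorted(tip_set))}}}"
            )
        return self.ages[tip_set]

    def validate(self, tree: PhyloTree) -> None:
        """Check every internal node is dated and parents pre-date children."""
        tipsets = {n: tree.tip_set(n) for n in tree.postorder()}
        for node in tree.internal_nodes():
            age = self.age_of(tipsets[node])  # raises if missing
            for child in node.children:
                child_age = self.age_of(tipsets[child])
                if not age > child_age:
                    raise ValueError(
                        f"parent age {age} not greater than child age "
                        f"{child_age} for clade "
                        f"{{{', '.join(sorted(tipsets[child]))}}}"
                    )

    @classmethod
    def from_ultrametric(cls, tree: PhyloTree, root_age: float | None = None
                         ) -> "NodeAges":
        """Derive ages from an ultrametric tree's branch lengths.

        If *root_age* is given, depths are rescaled so the root has that age.
        """
        depths = tree.depths()
        tip_depth = max(depths[t] for t in tree.tips())
        scale = 1.0 if root_age is None else root_age / tip_depth
        ages = {}
        for node in tree.internal_nodes():
            ages[tree.tip_set(node)] = (tip_depth - depths[node]) * scale
        return cls(ages)

    # -- TSV round-trip (clade tips semicolon-joined, then age) ------------
    @classmethod
    def from_tsv(cls, path) -> "NodeAges":
        ages = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                try:
                    clade, age = line.split("\t")
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: expected two tab-separated "
                        f"columns"
                    ) from exc
                ages[frozenset(clade.split(";"))] = float(age)
        return cls(ages)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for clade in sorted(self.ages, key=lambda c: (len(c), sorted(c))):
                fh.write(f"{';'.join(sorted(clade))}\t{self.ages[clade]}\n")
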