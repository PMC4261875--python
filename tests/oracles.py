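"""Independent oracles used by the test suite.

These deliberately avoid the package's solver code paths: the reconciliation
oracle enumerates every embedding by brute force, and the regression oracle
solves the normal equations directly.
"""

from __future__ import annotations

import itertools

import numpy as np

from paleofv.cophylogeny import EventCosts
from paleofv.trees import PhyloTree, TreeNode


def all_rooted_topologies(labels: list[str]) -> list[PhyloTree]:
    """Every labelled rooted binary topology on *labels* (no lengths)."""

    def build(subset: tuple[str, ...]) -> list[TreeNode]:
        if len(subset) == 1:
            return [TreeNode(subset[0])]
        out = []
        first, rest = subset[0], subset[1:]
        # partition: first label anchored on the left to avoid mirror dupes
        for r in range(len(rest) + 1):
            for right in itertools.combinations(rest, r):
                if len(right) in (0, len(subset)):
                    continue
                left = (first,) + tuple(x for x in rest if x not in right)
                for lt in build(left):
                    for rt in build(tuple(right)):
                        node = TreeNode()
                        node.add_child(_clone(lt))
                        node.add_child(_clone(rt))
                        out.append(node)
        return out

    return [PhyloTree(root) for root in build(tuple(labels))]


def _clone(node: TreeNode) -> TreeNode:
    new = TreeNode(node.label, node.length)
    for c in node.children:
        new.add_child(_clone(c))
    return new


def brute_force_min_cost(vtree: PhyloTree, htree: PhyloTree,
                         pairs: dict[str, str],
                         costs: EventCosts = EventCosts()) -> float:
    """Minimum reconciliation cost by exhaustive enumeration.

    Every assignment of internal virus nodes to host nodes is enumerated;
    for each assignment the cheapest permissible event label is chosen per
    node (labels price independently, so scalar minimisation distributes):

    * cospeciation: children map into the two distinct child subtrees;
    * duplication: both children map at-or-below the node's host;
    * duplication & switch: exactly one child lands on a host that is
      neither the node's host nor one of its ancestors, the other stays
      at-or-below.

    A child on a strict ancestor of its parent's host is infeasible.
    """
    hnodes = list(htree.postorder())
    hidx = {n: i for i, n in enumerate(hnodes)}
    n_h = len(hnodes)
    desc = np.zeros((n_h, n_h), dtype=bool)   # desc[a, b]: b inside a's subtree
    for i, node in enumerate(hnodes):
        stack = [node]
        while stack:
            cur = stack.pop()
            desc[i, hidx[cur]] = True
            stack.extend(cur.children)
    strict_anc = desc.T & ~np.eye(n_h, dtype=bool)  # strict_anc[a,b]: b ancestor of a

    vpost = list(vtree.postorder())
    vinternal = [v for v in vpost if not v.is_tip]
    tip_pos = {v: hidx[htree.find_tip(pairs[v.label])]
               for v in vpost if v.is_tip}

    best = float("inf")
    for assign in itertools.product(range(n_h), repeat=len(vinternal)):
        pos = dict(tip_pos)
        for v, h in zip(vinternal, assign):
            pos[v] = h
        total = 0.0
        ok = True
        for v in vinternal:
            h = pos[v]
            c1, c2 = v.children
            p1, p2 = pos[c1], pos[c2]
            in1, in2 = desc[h, p1], desc[h, p2]
            anc1, anc2 = strict_anc[h, p1], strict_anc[h, p2]
            if anc1 or anc2:
                ok = False
                break
            options = []
            if in1 and in2:
                options.append(costs.duplication)
                kids = hnodes[h].children
                if kids:
                    l, r = hidx[kids[0]], hidx[kids[1]]
                    if (desc[l, p1] and desc[r, p2]) or \
                       (desc[r, p1] and desc[l, p2]):
                        options.append(costs.cospeciation)
            # switch: one child off to a non-ancestral, non-self host
            if in1 and p2 != h:
                options.append(costs.duplication_and_switch)
            if in2 and p1 != h:
                options.append(costs.duplication_and_switch)
            if not options:
                ok = False
                break
            total += min(options)
        if ok and total < best:
            best = total
    return best


def exact_tipmap_pvalue(vtree: PhyloTree, htree: PhyloTree,
                        observed: int,
                        costs: EventCosts = EventCosts()) -> float:
    """Exact P(cospeciations >= observed) over all tip bijections.

    Uses the brute-force cost minimiser, relying on the default costs where
    the cospeciation count is minus the total cost.
    """
    assert costs == EventCosts(), "exact enumeration assumes default costs"
    vtips = sorted(t.label for t in vtree.tips())
    htips = sorted(t.label for t in htree.tips())
    hits = total = 0
    for perm in itertools.permutations(htips):
        pairs = dict(zip(vtips, perm))
        ncosp = -brute_force_min_cost(vtree, htree, pairs, costs)
        hits += ncosp >= observed
        total += 1
    return hits / total


def ols_normal_equations(x: np.ndarray, y: np.ndarray
                         ) -> tuple[float, float]:
    """(intercept, slope) from the closed-form normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0]), float(beta[1])
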