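import numpy as np
import pytest

import paleofv as pf
from paleofv.cophylogeny import EventCosts, _Solver
from paleofv.trees import PhyloTree

from oracles import all_rooted_topologies, brute_force_min_cost, \
    exact_tipmap_pvalue


def _identity_assoc(vtree, htree):
    vtips = sorted(vtree.tip_labels())
    htips = sorted(htree.tip_labels())
    return pf.TipAssociation(dict(zip(vtips, htips)))


class TestReconcile:
    def test_congruent_ladder_full_cospeciation(self):
        v = PhyloTree.from_newick("(((A,B),C),D);")
        h = PhyloTree.from_newick("(((a,b),c),d);")
        assoc = pf.TipAssociation({"A": "a", "B": "b", "C": "c", "D": "d"})
        rec = pf.reconcile(v, h, assoc)
        assert rec.n_cospeciations == 3
        assert rec.total_cost == -3
        assert rec.n_switches == 0 and rec.n_losses == 0

    def test_study_trees_fourteen_cospeciations(self, study_trees):
        vtree, htree, assoc = study_trees
        rec = pf.reconcile(vtree, htree, assoc)
        assert rec.n_cospeciations == 14
        assert rec.total_cost == -14

    def test_upper_bound_and_congruence_attainment(self):
        for seed in range(4):
            v, h, assoc, _ = pf.make_cophylo_pair(
                pf.CophyloScenario(n_tips=8, n_switches=0, seed=seed)
            )
            rec = pf.reconcile(v, h, assoc)
            bound = min(len(v.internal_nodes()), len(h.internal_nodes()))
            assert rec.n_cospeciations == bound

    def test_switch_strictly_degrades_cost(self):
        base = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=8, n_switches=0, seed=5)
        )
        cost0 = pf.reconcile(base[0], base[1], base[2]).total_cost
        v, h, assoc, truth = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=8, n_switches=1, seed=5)
        )
        rec = pf.reconcile(v, h, assoc)
        assert truth["n_switches"] == 1
        assert rec.total_cost > cost0

    def test_consistent_relabeling_invariance(self, study_trees):
        vtree, htree, assoc = study_trees
        cost0 = pf.reconcile(vtree, htree, assoc).total_cost
        v2, h2 = vtree.copy(), htree.copy()
        ren_v = {lab: f"v_{i}" for i, lab in enumerate(sorted(v2.tip_labels()))}
        ren_h = {lab: f"h_{i}" for i, lab in enumerate(sorted(h2.tip_labels()))}
        for t in v2.tips():
            t.label = ren_v[t.label]
        for t in h2.tips():
            t.label = ren_h[t.label]
        assoc2 = pf.TipAssociation(
            {ren_v[v]: ren_h[h] for v, h in assoc.items()}
        )
        assert pf.reconcile(v2, h2, assoc2).total_cost == cost0

    def test_nonbinary_rejected(self):
        v = PhyloTree.from_newick("(A,B,C);")
        h = PhyloTree.from_newick("((a,b),c);")
        assoc = pf.TipAssociation({"A": "a", "B": "b", "C": "c"})
        with pytest.raises(ValueError, match="binary"):
            pf.reconcile(v, h, assoc)

    def test_oversized_input_rejected(self):
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=30, seed=1)
        )
        with pytest.raises(ValueError, match="envelope"):
            pf.reconcile(v, h, assoc)

    def test_nonzero_loss_cost_rejected(self):
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=4, seed=1)
        )
        with pytest.raises(ValueError, match="loss"):
            pf.reconcile(v, h, assoc, EventCosts(loss=1.0))


class TestBruteForceEquivalence:
    def test_exhaustive_four_tip_pairs(self):
        """DP cost equals exhaustive enumeration on all 4-tip tree pairs."""
        topologies = all_rooted_topologies(["A", "B", "C", "D"])
        assert len(topologies) == 15
        host_topologies = all_rooted_topologies(["a", "b", "c", "d"])
        pairs = {"A": "a", "B": "b", "C": "c", "D": "d"}
        assoc = pf.TipAssociation(pairs)
        for v in topologies:
            for h in host_topologies:
                dp = pf.reconcile(v, h, assoc)
                oracle = brute_force_min_cost(v, h, pairs)
                assert dp.total_cost == oracle, (v.to_newick(), h.to_newick())
                assert dp.n_cospeciations == -oracle

    @pytest.mark.parametrize("n_tips,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
    def test_random_larger_pairs_with_switches(self, n_tips, seed):
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=n_tips, n_switches=seed % 3, seed=seed)
        )
        dp = pf.reconcile(v, h, assoc)
        oracle = brute_force_min_cost(v, h, dict(assoc.pairs))
        assert dp.total_cost == oracle

    def test_nondefault_costs_against_oracle(self):
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=5, n_switches=1, seed=9)
        )
        costs = EventCosts(cospeciation=-2.0, duplication=0.5,
                           duplication_and_switch=1.5)
        dp = pf.reconcile(v, h, assoc, costs)
        oracle = brute_force_min_cost(v, h, dict(assoc.pairs), costs)
        assert dp.total_cost == pytest.approx(oracle)


class TestTipMapTest:
    def test_two_tip_trees_p_is_one(self):
        v = PhyloTree.from_newick("(A,B);")
        h = PhyloTree.from_newick("(a,b);")
        assoc = pf.TipAssociation({"A": "a", "B": "b"})
        res = pf.random_tip_mapping_test(v, h, assoc, n_perm=50, seed=0)
        assert res.observed == 1
        assert res.p_value == 1.0

    def test_four_tip_empirical_matches_exact_enumeration(self):
        v = PhyloTree.from_newick("(((A,B),C),D);")
        h = PhyloTree.from_newick("(((a,b),c),d);")
        assoc = pf.TipAssociation({"A": "a", "B": "b", "C": "c", "D": "d"})
        observed = 3
        exact = exact_tipmap_pvalue(v, h, observed)
        n_perm = 500
        res = pf.random_tip_mapping_test(v, h, assoc, n_perm=n_perm, seed=1,
                                         observed=observed)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        # add-one estimator vs exact enumeration over all 24 bijections
        assert abs(res.p_value - exact) <= 3 * se + 2 / n_perm

    def test_seed_determinism(self, study_trees):
        vtree, htree, assoc = study_trees
        a = pf.random_tip_mapping_test(vtree, htree, assoc, n_perm=20, seed=3)
        b = pf.random_tip_mapping_test(vtree, htree, assoc, n_perm=20, seed=3)
        assert a.null_counts == b.null_counts and a.p_value == b.p_value

    def test_p_value_superuniform_under_null(self):
        """P(p <= a) should not exceed a (plus noise) when the association
        itself is a uniform draw."""
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=6, seed=4)
        )
        solver = _Solver(v, h, EventCosts())
        rng = np.random.default_rng(5)
        htips = sorted(h.tip_labels())
        vtips = sorted(v.tip_labels())
        n_draws, n_perm = 150, 60
        pvals = []
        for _ in range(n_draws):
            perm = rng.permutation(len(htips))
            null_assoc = pf.TipAssociation(
                {v_: htips[perm[i]] for i, v_ in enumerate(vtips)}
            )
            res = pf.random_tip_mapping_test(
                v, h, null_assoc, n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / n_draws)
            assert (pvals <= alpha).mean() <= alpha + 3 * se
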