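import numpy as np
import pytest

import paleofv as pf
from paleofv.trees import NodeAges, PhyloTree

from oracles import ols_normal_equations


class TestExtractBranchPairs:
    def _congruent(self, n_tips, seed):
        v, h, assoc, _ = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=n_tips, n_switches=0, seed=seed)
        )
        ages = NodeAges.from_ultrametric(h)
        rec = pf.reconcile(v, h, assoc)
        return v, h, ages, rec

    def test_congruent_four_tips_six_pairs(self):
        v, h, ages, rec = self._congruent(4, seed=7)
        pairs = pf.extract_branch_pairs(rec, v, h, ages)
        assert len(pairs) == 6  # 4 terminal + 2 internal, root branch excluded

    def test_congruent_thirteen_tips_pair_count(self):
        v, h, ages, rec = self._congruent(13, seed=8)
        pairs = pf.extract_branch_pairs(rec, v, h, ages)
        assert len(pairs) == 2 * 13 - 2

    def test_durations_are_host_internode_gaps(self):
        v, h, ages, rec = self._congruent(6, seed=9)
        pairs = pf.extract_branch_pairs(rec, v, h, ages)
        tipsets = {n: h.tip_set(n) for n in h.postorder()}
        for p in pairs:
            # find the host child node by its recorded label
            want = frozenset(p.host_label.split(";"))
            child = next(n for n, ts in tipsets.items() if ts == want)
            gap = (ages.age_of(tipsets[child.parent])
                   - ages.age_of(tipsets[child]))
            assert p.host_duration == pytest.approx(gap)

    def test_root_to_tip_durations_sum_to_root_age(self):
        v, h, ages, rec = self._congruent(9, seed=10)
        pairs = pf.extract_branch_pairs(rec, v, h, ages)
        root_age = ages.age_of(h.tip_set(h.root))
        by_host = {p.host_label: p for p in pairs}
        for tip in h.tips():
            total, node = 0.0, tip
            while node.parent is not None:
                label = (node.label if node.is_tip
                         else ";".join(sorted(h.tip_set(node))))
                total += by_host[label].host_duration
                node = node.parent
            assert total == pytest.approx(root_age)

    def test_switched_tip_excluded(self):
        v, h, assoc, truth = pf.make_cophylo_pair(
            pf.CophyloScenario(n_tips=6, n_switches=1, seed=11)
        )
        ages = NodeAges.from_ultrametric(h)
        rec = pf.reconcile(v, h, assoc)
        congruent_count = 2 * 6 - 2
        pairs = pf.extract_branch_pairs(rec, v, h, ages)
        assert len(pairs) < congruent_count
        moved = truth["moves"][0]["tip"]
        assert all(p.virus_label != moved or ";" in p.virus_label
                   for p in pairs)

    def test_missing_age_names_clade(self):
        v, h, ages, rec = self._congruent(5, seed=12)
        incomplete = NodeAges(
            {k: v_ for k, v_ in list(ages.ages.items())[:-1]}
        )
        with pytest.raises(KeyError):
            pf.extract_branch_pairs(rec, v, h, incomplete)


class TestFitCodivergence:
    def test_exact_line_no_removals(self):
        pairs = [pf.BranchPair(2.0 * x, x) for x in (1.0, 2.0, 3.0, 4.0, 5.0)]
        fit = pf.fit_codivergence(pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.removed == []

    def test_matches_normal_equations_oracle(self):
        pairs, _ = pf.make_regression_pairs(n=30, seed=1)
        fit = pf.fit_codivergence(pairs, cook_factor=float("inf"))
        x = np.array([p.host_duration for p in pairs])
        y = np.array([p.virus_branch_length for p in pairs])
        b0, b1 = ols_normal_equations(x, y)
        assert fit.intercept == pytest.approx(b0, rel=1e-10, abs=1e-14)
        assert fit.slope == pytest.approx(b1, rel=1e-10)
        assert fit.n_used == 30

    def test_planted_gross_outliers_removed_first(self):
        pairs, truth = pf.make_regression_pairs(
            n=23, seed=2,
            outliers=[(30.0, 0.6), (60.0, 0.85), (90.0, 1.1)],
        )
        fit = pf.fit_codivergence(pairs)
        first_three = {p.virus_label for p, _ in fit.removed[:3]}
        assert first_three == {"outlier0", "outlier1", "outlier2"}

    def test_removal_ledger_accounting(self):
        pairs, _ = pf.make_regression_pairs(n=20, seed=3)
        fit = pf.fit_codivergence(pairs)
        assert len(fit.removed) + fit.n_used == len(pairs)
        assert fit.n_used >= 4

    def test_slope_ci_calibrated_without_pruning(self):
        """95% slope CI coverage at nominal level for the plain OLS fit."""
        hits = 0
        n_runs = 200
        from scipy import stats
        for seed in range(n_runs):
            pairs, truth = pf.make_regression_pairs(n=23, seed=seed)
            fit = pf.fit_codivergence(pairs, cook_factor=float("inf"))
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            lo = fit.slope - tcrit * fit.slope_se
            hi = fit.slope + tcrit * fit.slope_se
            hits += lo <= truth["slope"] <= hi
        assert hits / n_runs >= 0.91

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            pf.fit_codivergence([pf.BranchPair(1.0, 1.0)] * 3)

    def test_degenerate_predictor_rejected(self):
        pairs = [pf.BranchPair(float(i), 5.0) for i in range(6)]
        with pytest.raises(ValueError, match="variance"):
            pf.fit_codivergence(pairs)


class TestEstimateNodeDate:
    def _fit(self, slope, intercept=0.0):
        xs = (2.0, 5.0, 9.0, 14.0)
        return pf.fit_codivergence(
            [pf.BranchPair(intercept + slope * x, x) for x in xs]
        )

    def test_zero_branch_zero_intercept_returns_calibration(self):
        est = pf.estimate_node_date(self._fit(0.01), 0.0, 101.1)
        assert est.point == pytest.approx(101.1)

    def test_plain_arithmetic(self):
        est = pf.estimate_node_date(self._fit(0.01), 0.05, 100.0)
        assert est.point == pytest.approx(95.0)

    def test_inverse_prediction_identity(self):
        # a fit whose inverse prediction for 0.0564 subs/site is 7.758 Myr
        fit = self._fit(0.0564 / 7.758)
        est = pf.estimate_node_date(fit, 0.0564, 101.1)
        assert est.point == pytest.approx(93.342, abs=1e-9)
        lo, hi = est.ci95
        assert lo <= est.point <= hi

    def test_monotone_in_branch_length(self):
        fit = self._fit(0.007, intercept=0.001)
        dates = [
            pf.estimate_node_date(fit, b, 101.1).point
            for b in (0.0, 0.02, 0.05, 0.1, 0.3)
        ]
        assert all(b <= a for a, b in zip(dates, dates[1:]))

    def test_nonpositive_slope_rejected(self):
        fit = self._fit(0.01)
        fit.slope = -0.01
        with pytest.raises(ValueError, match="non-informative"):
            pf.estimate_node_date(fit, 0.05, 100.0)

    def test_ci_width_grows_with_noise(self):
        rng = np.random.default_rng(0)
        xs = np.linspace(1, 100, 23)
        out = []
        for sd in (0.005, 0.05):
            pairs = [
                pf.BranchPair(max(0.0, 0.007 * x + rng.normal(0, sd)), x)
                for x in xs
            ]
            fit = pf.fit_codivergence(pairs, cook_factor=float("inf"))
            est = pf.estimate_node_date(fit, 0.0564, 101.1)
            out.append(est.ci95[1] - est.ci95[0])
        assert out[1] > out[0]


def test_study_pipeline_extraction(study_trees, study_ages):
    """Branch pairs extract cleanly from the bundled study reconciliation."""
    vtree, htree, assoc = study_trees
    for tip in vtree.tips():
        tip.length = 0.01
    for node in vtree.internal_nodes():
        node.length = 0.01
    rec = pf.reconcile(vtree, htree, assoc)
    pairs = pf.extract_branch_pairs(rec, vtree, htree, study_ages)
    # 14 cospeciation parents bound the number of admissible branches
    assert len(pairs) >= 14
    assert all(p.host_duration > 0 for p in pairs)
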