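"""Virus-host codivergence regression and calibration dating.

Along lineages where virus and host demonstrably cospeciated, the virus
branch length (amino-acid substitutions/site) and the corresponding host
branch duration (Myr, from a dated host tree) should be proportional if
viral divergence accumulates in step with host divergence.  This module

* extracts those codivergent branch pairs from a reconciliation,
* fits the linear relation by ordinary least squares with iterative
  Cook's-distance outlier pruning (threshold: a factor times the mean of the
  observed Cook's distances, removing one point per refit), and
* dates a virus node by inverse prediction: the duration implied by a branch
  length is subtracted from a host calibration age.

The regression puts virus branch length on the response side so that node
dating is the classical calibration (inverse-prediction) problem; the
interval on a dated node propagates the regression's uncertainty for the
predicted mean response by the delta method, a first-order choice that is
robust at small sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cophylogeny import COSPECIATION, Reconciliation
from .trees import NodeAges, PhyloTree

__all__ = [
    "BranchPair",
    "CodivergenceFit",
    "NodeDateEstimate",
    "extract_branch_pairs",
    "fit_codivergence",
    "estimate_node_date",
]


@dataclass
class BranchPair:
    """One codivergent branch: virus length paired with host duration."""

    virus_branch_length: float   # amino-acid substitutions/site
    host_duration: float         # Myr
    virus_label: str = ""
    host_label: str = ""

    def __post_init__(self) -> None:
        if self.virus_branch_length < 0 or self.host_duration < 0:
            raise ValueError("branch lengths and durations must be >= 0")


def extract_branch_pairs(recon: Reconciliation, vtree: PhyloTree,
                         htree: PhyloTree, ages: NodeAges
                         ) -> list[BranchPair]:
    """Branch pairs representing virus-host co-evolutionary history.

    A virus branch contributes a pair when its parent node is a cospeciation
    event and its child end is either another cospeciation event or a tip;
    branches touching duplication or switch events do not track host time
    and are excluded, as is the virus root branch (no parent event).  The
    host duration is the age difference of the host nodes the two ends map
    to.  Zero-duration pairs are dropped with a warning.
    """
    tipset = {n: htree.tip_set(n) for n in htree.postorder()}
    pairs: list[BranchPair] = []
    for v in vtree.postorder():
        parent = v.parent
        if parent is None:
            continue
        if recon.events.get(parent) != COSPECIATION:
            continue
        if not v.is_tip and recon.events.get(v) != COSPECIATION:
            continue
        h_parent = recon.assignments[parent]
        h_child = recon.assignments[v]
        duration = ages.age_of(tipset[h_parent]) - ages.age_of(tipset[h_child])
        if duration == 0:
            warnings.warn(
                f"dropping zero-duration host branch under clade "
                f"{{{', '.join(sorted(tipset[h_parent]))}}}"
            )
            continue
        vlab = v.label if v.is_tip else ";".join(sorted(vtree.tip_set(v)))
        hlab = (h_child.label if h_child.is_tip
                else ";".join(sorted(tipset[h_child])))
        pairs.append(
            BranchPair(
                virus_branch_length=float(v.length or 0.0),
                host_duration=float(duration),
                virus_label=vlab,
                host_label=hlab,
            )
        )
    return pairs


@dataclass
class CodivergenceFit:
    """An OLS fit of virus branch length on host duration, after pruning."""

    slope: float                  # subs/site per Myr
    intercept: float              # subs/site
    r_squared: float
    p_value: float                # two-sided, for the slope
    n_used: int
    removed: list[tuple[BranchPair, float]]   # (pair, Cook's D) in order
    residual_variance: float
    slope_se: float
    intercept_se: float
    slope_intercept_cov: float
    df_resid: int
    pairs_used: list[BranchPair] = field(repr=False, default_factory=list)

    def predict(self, host_duration: float) -> float:
        return self.intercept + self.slope * host_duration

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "removed": [
                {"virus": p.virus_label, "host": p.host_label,
                 "cooks_distance": d}
                for p, d in self.removed
            ],
        }


def _ols(x: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(x)).fit()


def fit_codivergence(pairs: list[BranchPair],
                     cook_factor: float = 3.0) -> CodivergenceFit:
    """OLS of virus branch length on host duration with outlier pruning.

    Cook's distances are computed for every point of the current fit; while
    the largest exceeds ``cook_factor`` times their mean, that single point
    is removed and the model refitted.  The removal ledger records each
    pruned pair with its Cook's distance at removal.  ``cook_factor=inf``
    disables pruning and returns the plain OLS fit.

    Note that the threshold is scale-free: on clean Gaussian data the
    largest Cook's distance exceeds 3x the mean most of the time, so with
    the default factor the rule prunes aggressively (see the methods note).
    Pruning stops before the fit would drop below 4 points.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 branch pairs")
    x = np.array([p.host_duration for p in pairs])
    y = np.array([p.virus_branch_length for p in pairs])
    keep = list(range(len(pairs)))
    removed: list[tuple[BranchPair, float]] = []
    while True:
        if np.var(x[keep]) == 0:
            raise ValueError("degenerate predictor: zero variance in "
                             "host durations")
        res = _ols(x[keep], y[keep])
        if len(keep) <= 4 or not np.isfinite(cook_factor):
            break
        # (numerically) perfect fit: nothing sticks out
        if res.mse_resid <= 1e-20 * max(float(np.var(y[keep])), 1e-300):
            break
        cooks = res.get_influence().cooks_distance[0]
        if not np.all(np.isfinite(cooks)):
            break
        k = int(np.argmax(cooks))
        if cooks[k] > cook_factor * cooks.mean():
            removed.append((pairs[keep[k]], float(cooks[k])))
            del keep[k]
        else:
            break
    params = res.params
    bse = res.bse
    cov = res.cov_params()
    return CodivergenceFit(
        slope=float(params[1]),
        intercept=float(params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n_used=len(keep),
        removed=removed,
        residual_variance=float(res.mse_resid),
        slope_se=float(bse[1]),
        intercept_se=float(bse[0]),
        slope_intercept_cov=float(np.asarray(cov)[0, 1]),
        df_resid=int(res.df_resid),
        pairs_used=[pairs[i] for i in keep],
    )


@dataclass
class NodeDateEstimate:
    """A calibrated node date from inverse prediction."""

    branch_length: float          # subs/site
    calibration_age: float        # Myr
    predicted_duration: float     # Myr
    duration_se: float            # Myr
    point: float                  # Myr before present
    ci95: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "branch_length": self.branch_length,
            "calibration_age": self.calibration_age,
            "predicted_duration_myr": self.predicted_duration,
            "point_ma": self.point,
            "ci95_ma": list(self.ci95),
        }


def estimate_node_date(fit: CodivergenceFit, branch_length: float,
                       calibration_age: float) -> NodeDateEstimate:
    """Date a virus node by calibrated inverse prediction.

    The duration implied by *branch_length* is d = (length - intercept) /
    slope (clipped at 0); the node date is *calibration_age* - d.  The 95%
    interval propagates the regression's covariance through d by the delta
    method with a t(df) quantile, and maps through the same subtraction.
    """
    if fit.slope <= 0:
        raise ValueError("cannot invert non-informative fit (slope <= 0)")
    d_raw = (branch_length - fit.intercept) / fit.slope
    d = max(0.0, d_raw)
    # delta method on g(b0, b1) = (y0 - b0)/b1
    var_d = (fit.intercept_se ** 2
             + 2 * d_raw * fit.slope_intercept_cov
             + d_raw ** 2 * fit.slope_se ** 2) / fit.slope ** 2
    se = float(np.sqrt(max(var_d, 0.0)))
    tcrit = float(stats.t.ppf(0.975, fit.df_resid)) if fit.df_resid > 0 \
        else float("inf")
    point = calibration_age - d
    ci = (point - tcrit * se, point + tcrit * se)
    return NodeDateEstimate(
        branch_length=branch_length,
        calibration_age=calibration_age,
        predicted_duration=d,
        duration_se=se,
        point=point,
        ci95=ci,
    )
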