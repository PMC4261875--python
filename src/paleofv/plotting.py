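"""Optional matplotlib figures for the dating CDFs and the codivergence fit."""

from __future__ import annotations

from .codivergence import CodivergenceFit
from .dating import AgeCDF


def plot_age_cdfs(cdfs: list[AgeCDF], path=None, ax=None):
    """Step plot of exceedance CDFs of integration age, one per model."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for cdf in cdfs:
        ax.step(cdf.times, cdf.q, where="post", label=cdf.model_id)
    ax.set_xlabel("time since integration (Myr)")
    ax.set_ylabel("P(simulated stop frequency ≥ observed)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_codivergence_fit(fit: CodivergenceFit, path=None, ax=None):
    """Scatter of branch pairs with the fitted line; pruned points marked."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [p.host_duration for p in fit.pairs_used]
    ys = [p.virus_branch_length for p in fit.pairs_used]
    ax.scatter(xs, ys, s=18, label=f"used (n={fit.n_used})")
    if fit.removed:
        ax.scatter(
            [p.host_duration for p, _ in fit.removed],
            [p.virus_branch_length for p, _ in fit.removed],
            s=24, marker="x", color="crimson",
            label=f"pruned (n={len(fit.removed)})",
        )
    lo, hi = min(xs), max(xs)
    ax.plot([lo, hi], [fit.predict(lo), fit.predict(hi)], "r-",
            label=f"slope {fit.slope:.3g}/Myr, R² {fit.r_squared:.3f}")
    ax.set_xlabel("host branch duration (Myr)")
    ax.set_ylabel("virus branch length (subs/site)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
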