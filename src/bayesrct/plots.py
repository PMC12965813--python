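"""Figures: single-trial posterior with index shading, cohort panels.

Every number rendered comes from the report objects, never recomputed
here, so figures and CSV/JSON outputs cannot disagree.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes_glm import PosteriorDraws
from .cohort import TrialReport
from .indices import RopeInterval

__all__ = ["render_posterior_figure", "render_cohort_panels"]


def render_posterior_figure(
    report: TrialReport,
    draws: PosteriorDraws,
    rope: RopeInterval | None = None,
    path: str | Path = "posterior.png",
) -> Path:
    """Posterior density of the OR with pd and ROPE shading.

    Left panel: the posterior with the directional region (the side of
    the null matching the median's sign) shaded and pd annotated.
    Right panel: the same posterior with the ROPE band shaded and
    ROPE_full annotated.  Degenerate (single-valued) draw sets render
    as a vertical line rather than crashing.
    """
    rope = rope or RopeInterval()
    path = Path(path)
    or_draws = draws.or_draws
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    spread = np.ptp(or_draws)
    if spread == 0:
        for ax in axes:
            ax.axvline(or_draws[0], color="C0")
            ax.set_xlabel("odds ratio")
        axes[0].set_title("degenerate posterior (single value)")
    else:
        from scipy.stats import gaussian_kde

        # density estimated on the log scale, rendered on the OR scale
        log_draws = draws.log_or_draws
        kde = gaussian_kde(log_draws)
        grid_log = np.linspace(log_draws.min(), log_draws.max(), 512)
        dens = kde(grid_log) / np.exp(grid_log)
        grid = np.exp(grid_log)
        direction_up = report.bayes.median_or >= 1.0
        for ax in axes:
            ax.plot(grid, dens, color="black", lw=1)
            ax.axvline(1.0, color="grey", ls="--", lw=0.8)
            ax.set_xlabel("odds ratio")
            ax.set_yticks([])
        mask_pd = grid > 1.0 if direction_up else grid < 1.0
        axes[0].fill_between(grid, dens, where=mask_pd, color="tab:orange", alpha=0.6)
        mask_rope = (grid >= rope.or_low) & (grid <= rope.or_high)
        axes[1].fill_between(grid, dens, where=mask_rope, color="tab:blue", alpha=0.6)
    axes[0].set_title(f"probability of direction: {report.bayes.pd * 100:.1f}%")
    axes[1].set_title(
        f"ROPE_full: {report.bayes.rope_full * 100:.1f}%  "
        f"(OR {rope.or_low:g}–{rope.or_high:g})"
    )
    fig.suptitle(
        f"{report.trial_id}: median OR {report.bayes.median_or:.2f}, "
        f"{report.bayes.level:.0%} CrI {report.bayes.cri_low:.2f}–{report.bayes.cri_high:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def render_cohort_panels(
    reports: Sequence[TrialReport],
    path: str | Path = "cohort_panels.png",
) -> Path:
    """Three-panel cohort view: pd vs P (log scale), ROPE_full vs P, pd vs ROPE_full."""
    path = Path(path)
    p = np.array([r.freq.p_fisher for r in reports])
    pd_ = np.array([r.bayes.pd for r in reports]) * 100
    rope = np.array([r.bayes.rope_full for r in reports]) * 100
    n = np.array([r.n_total for r in reports], dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    p_plot = np.clip(p, 1e-6, 1.0)
    sc = axes[0].scatter(p_plot, pd_, c=n, cmap="viridis", s=25)
    axes[0].set_xscale("log")
    axes[0].set_xlabel("P value (Fisher, log scale)")
    axes[0].set_ylabel("probability of direction (%)")
    axes[1].scatter(p_plot, rope, c=n, cmap="viridis", s=25)
    axes[1].set_xscale("log")
    axes[1].set_xlabel("P value (Fisher, log scale)")
    axes[1].set_ylabel("ROPE_full (%)")
    axes[2].scatter(rope, pd_, c=n, cmap="viridis", s=25)
    axes[2].set_xlabel("ROPE_full (%)")
    axes[2].set_ylabel("probability of direction (%)")
    for ax in axes[:2]:
        ax.axvline(0.05, color="grey", ls="--", lw=0.8)
    fig.colorbar(sc, ax=axes, label="total sample size", shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
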