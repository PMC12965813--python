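"""Posterior indices of effect existence and practical significance.

Two summaries of the treatment-effect posterior, plus the equal-tailed
credible interval:

* **probability of direction (pd)** — the larger of Pr(log OR > 0) and
  Pr(log OR < 0) under the posterior; ranges 50–100% and corresponds
  approximately to the two-sided P value via P = 2 * (1 - pd).
* **ROPE_full** — the fraction of the posterior inside a region of
  practical equivalence, by convention odds ratios 0.84–1.20; small
  values indicate practical significance.

All functions accept either a :class:`~bayesrct.bayes_glm.PosteriorDraws`
or a bare array of log-odds-ratio draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

from .bayes_glm import PosteriorDraws

__all__ = [
    "RopeInterval",
    "IndexReport",
    "probability_of_direction",
    "rope_full",
    "equal_tailed_cri",
    "pd_to_p",
    "p_to_pd",
    "summarize_draws",
]


@dataclass(frozen=True)
class RopeInterval:
    """Region of practical equivalence on the odds-ratio scale.

    The default (0.84, 1.20) is the conventional negligible-effect band
    for odds ratios; it is a convention, not a clinical constant, and
    should be replaced by a context-specific equivalence margin where
    one exists.
    """

    or_low: float = 0.84
    or_high: float = 1.20

    def __post_init__(self) -> None:
        if not 0 < self.or_low < self.or_high:
            raise ValueError(
                f"ROPE must satisfy 0 < or_low < or_high, got ({self.or_low}, {self.or_high})"
            )

    @property
    def log_bounds(self) -> tuple[float, float]:
        return log(self.or_low), log(self.or_high)


@dataclass(frozen=True)
class IndexReport:
    """Bayesian block of a trial report (OR scale for intervals/median)."""

    pd: float
    rope_full: float
    cri_low: float
    cri_high: float
    median_or: float
    level: float = 0.95
    converged: bool = True


def _as_log_or(draws) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        arr = draws.log_or_draws
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("empty draw set")
    return arr.reshape(-1)


def probability_of_direction(draws) -> float:
    """Proportion of the posterior sharing the median's sign.

    Computed on the log-OR scale relative to 0 (equivalently the OR
    relative to 1) as max(Pr(>0), Pr(<0)); draws exactly at the null
    belong to neither tail.  Result is in [0.5, 1] up to draw-level
    granularity.
    """
    arr = _as_log_or(draws)
    n = arr.size
    return max(np.count_nonzero(arr > 0), np.count_nonzero(arr < 0)) / n


def rope_full(draws, rope: RopeInterval | None = None) -> float:
    """Fraction of the posterior inside the ROPE (closed interval)."""
    arr = _as_log_or(draws)
    lo, hi = (rope or RopeInterval()).log_bounds
    return float(np.count_nonzero((arr >= lo) & (arr <= hi)) / arr.size)


def equal_tailed_cri(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval on the odds-ratio scale.

    The ((1-level)/2, (1+level)/2) empirical percentiles of the log-OR
    draws, exponentiated; linear interpolation between order statistics.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    arr = _as_log_or(draws)
    lo, hi = np.quantile(arr, [(1 - level) / 2, (1 + level) / 2])
    return float(np.exp(lo)), float(np.exp(hi))


def pd_to_p(pd: float) -> float:
    """Two-sided P value corresponding to a probability of direction."""
    if not 0.5 <= pd <= 1.0:
        raise ValueError(f"pd must be in [0.5, 1], got {pd}")
    return 2.0 * (1.0 - pd)


def p_to_pd(p: float) -> float:
    """Probability of direction corresponding to a two-sided P value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return 1.0 - p / 2.0


def summarize_draws(
    draws: PosteriorDraws,
    rope: RopeInterval | None = None,
    level: float = 0.95,
) -> IndexReport:
    """All posterior indices for one draw set, as an :class:`IndexReport`."""
    arr = _as_log_or(draws)
    cri_low, cri_high = equal_tailed_cri(arr, level)
    converged = draws.converged if isinstance(draws, PosteriorDraws) else True
    return IndexReport(
        pd=probability_of_direction(arr),
        rope_full=rope_full(arr, rope),
        cri_low=cri_low,
        cri_high=cri_high,
        median_or=float(np.exp(np.median(arr))),
        level=level,
        converged=converged,
    )
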