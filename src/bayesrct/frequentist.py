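"""Frequentist analysis of a 2x2 trial table.

Sample odds ratio (cross-product estimator), two-sided Fisher's exact
test (probability-mass rule, as in R's ``fisher.test`` and scipy), and
confidence intervals for the odds ratio by either the Wald (log-OR
normal approximation) or the exact-conditional method (inversion of
noncentral-hypergeometric tail tests, the same conditional framework as
Fisher's test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .trial_data import TwoByTwoTrial

__all__ = [
    "CIMethod",
    "FrequentistReport",
    "ZeroCellError",
    "sample_odds_ratio",
    "fisher_exact_two_sided",
    "or_confidence_interval",
    "analyze_frequentist",
]

CIMethod = Literal["wald", "exact_conditional"]


class ZeroCellError(ValueError):
    """Wald interval requested for a table with an empty cell."""


@dataclass(frozen=True)
class FrequentistReport:
    """Frequentist summary of one trial."""

    or_hat: float
    p_fisher: float
    ci_low: float
    ci_high: float
    ci_method: CIMethod = "exact_conditional"
    level: float = 0.95


def sample_odds_ratio(trial: TwoByTwoTrial) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    Degenerate tables map to sentinels rather than raising: ``inf`` when
    only the denominator is zero, ``nan`` when numerator and denominator
    are both zero (the odds ratio is undefined).
    """
    a, b, c, d = trial.counts()
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def fisher_exact_two_sided(trial: TwoByTwoTrial) -> float:
    """Two-sided Fisher's exact P value.

    Probability-mass convention: the sum of hypergeometric probabilities
    of all tables with the observed margins that are at most as probable
    as the observed table.
    """
    a, b, c, d = trial.counts()
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def _wald_interval(trial: TwoByTwoTrial, level: float) -> tuple[float, float]:
    a, b, c, d = trial.counts()
    if min(a, b, c, d) == 0:
        raise ZeroCellError(
            f"trial {trial.trial_id!r} has an empty cell; the Wald interval is "
            "undefined — use method='exact_conditional'"
        )
    z = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def _exact_conditional_interval(trial: TwoByTwoTrial, level: float) -> tuple[float, float]:
    # Condition on all margins; the treatment-arm event count follows
    # Fisher's noncentral hypergeometric distribution with odds psi.
    a, b, c, d = trial.counts()
    n1, n2 = trial.n_treat, trial.n_ctrl
    M, n, N = n1 + n2, n1, a + c
    lo_support = max(0, N - n2)
    hi_support = min(N, n1)
    alpha = (1 - level) / 2

    def sf(log_psi: float) -> float:  # P(X >= a | psi), increasing in psi
        return stats.nchypergeom_fisher.sf(a - 1, M, n, N, math.exp(log_psi))

    def cdf(log_psi: float) -> float:  # P(X <= a | psi), decreasing in psi
        return stats.nchypergeom_fisher.cdf(a, M, n, N, math.exp(log_psi))

    lo_bound, hi_bound = -50.0, 50.0
    if a == lo_support:
        lower = 0.0
    else:
        lower = math.exp(optimize.brentq(lambda lg: sf(lg) - alpha, lo_bound, hi_bound))
    if a == hi_support:
        upper = math.inf
    else:
        upper = math.exp(optimize.brentq(lambda lg: cdf(lg) - alpha, lo_bound, hi_bound))
    return lower, upper


def or_confidence_interval(
    trial: TwoByTwoTrial,
    level: float = 0.95,
    method: CIMethod = "exact_conditional",
) -> tuple[float, float]:
    """Confidence interval for the odds ratio.

    ``wald``: exp(log OR-hat +/- z * sqrt(1/a + 1/b + 1/c + 1/d));
    requires all four cells positive.  ``exact_conditional``: inverts the
    one-sided noncentral-hypergeometric tail tests at (1 - level)/2 per
    side; handles zero cells (endpoints 0 or infinity at the support
    boundary).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if method == "wald":
        return _wald_interval(trial, level)
    if method == "exact_conditional":
        return _exact_conditional_interval(trial, level)
    raise ValueError(f"unknown CI method {method!r}")


def analyze_frequentist(
    trial: TwoByTwoTrial,
    level: float = 0.95,
    ci_method: CIMethod = "exact_conditional",
) -> FrequentistReport:
    """Full frequentist block for one trial.

    Degenerate tables never abort a cohort run: the odds ratio falls
    back to its sentinel values, and a Wald request on a zero-cell table
    silently falls back to the exact-conditional interval (recorded in
    ``ci_method``).
    """
    or_hat = sample_odds_ratio(trial)
    p = fisher_exact_two_sided(trial)
    method = ci_method
    try:
        lo, hi = or_confidence_interval(trial, level, method)
    except ZeroCellError:
        method = "exact_conditional"
        lo, hi = or_confidence_interval(trial, level, method)
    return FrequentistReport(
        or_hat=or_hat, p_fisher=p, ci_low=lo, ci_high=hi, ci_method=method, level=level
    )
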