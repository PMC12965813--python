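"""Cohort-level pipeline: per-trial joint reports and summaries.

Runs the frequentist block (sample OR, Fisher's exact P, CI) and the
Bayesian block (posterior indices) on every trial of a cohort, then
summarizes the distributions of P, pd and ROPE_full and their rank
associations, and cross-tabulates frequentist significance against the
Bayesian indices to expose near-threshold dichotomization artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_glm import PriorSpec, SamplerConfig, derive_seed, fit_posterior
from .frequentist import CIMethod, FrequentistReport, analyze_frequentist
from .indices import IndexReport, RopeInterval, pd_to_p, summarize_draws
from .trial_data import TrialCohort, TwoByTwoTrial

__all__ = [
    "TrialReport",
    "CohortSummary",
    "DichotomizationResult",
    "analyze_trial",
    "analyze_cohort",
    "summarize_cohort",
    "dichotomization_table",
    "reports_to_frame",
]


@dataclass(frozen=True)
class TrialReport:
    """Joint frequentist + Bayesian results for one treatment-effect estimate."""

    trial_id: str
    freq: FrequentistReport
    bayes: IndexReport
    n_total: int


@dataclass(frozen=True)
class CohortSummary:
    """Medians, IQRs and rank associations of P, pd and ROPE_full."""

    median_p: float
    iqr_p_low: float
    iqr_p_high: float
    median_pd: float
    iqr_pd_low: float
    iqr_pd_high: float
    median_rope: float
    iqr_rope_low: float
    iqr_rope_high: float
    spearman_pd_p: float
    spearman_rope_p: float
    spearman_pd_rope: float
    n_estimates: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class DichotomizationResult:
    """Cross-tabulations of significance against binned indices.

    ``by_pd`` bins pd at 97.5%; ``by_rope`` bins ROPE_full at 2.5% and
    97.5% (the conventional decision cut points for these indices).
    ``near_threshold`` lists trials with |P - alpha| < 0.02;
    ``discordant_pairs`` pairs them across the significance boundary
    when their pd values differ by at most one percentage point.
    """

    by_pd: pd.DataFrame
    by_rope: pd.DataFrame
    near_threshold: pd.DataFrame
    discordant_pairs: pd.DataFrame
    alpha: float


def analyze_trial(
    trial: TwoByTwoTrial,
    prior: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    rope: RopeInterval | None = None,
    level: float = 0.95,
    ci_method: CIMethod = "exact_conditional",
) -> TrialReport:
    """Joint report for one trial; deterministic given ``sampler.seed``."""
    freq = analyze_frequentist(trial, level=level, ci_method=ci_method)
    draws = fit_posterior(trial, prior=prior, sampler=sampler)
    bayes = summarize_draws(draws, rope=rope, level=level)
    return TrialReport(trial_id=trial.trial_id, freq=freq, bayes=bayes, n_total=trial.n_total)


def analyze_cohort(
    cohort: TrialCohort | Sequence[TwoByTwoTrial],
    prior: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    rope: RopeInterval | None = None,
    level: float = 0.95,
    ci_method: CIMethod = "exact_conditional",
    master_seed: int = 0,
) -> list[TrialReport]:
    """Per-trial reports for a whole cohort.

    Each trial's sampler seed is derived from (master_seed, trial_id),
    so results are reproducible and independent of cohort order.
    Non-convergent fits surface as ``bayes.converged=False``; no trial
    is dropped.
    """
    sampler = sampler or SamplerConfig()
    reports = []
    for trial in cohort:
        per_trial = SamplerConfig(
            n_draws=sampler.n_draws,
            n_chains=sampler.n_chains,
            warmup=sampler.warmup,
            seed=derive_seed(master_seed, trial.trial_id),
            rhat_tol=sampler.rhat_tol,
        )
        reports.append(
            analyze_trial(trial, prior=prior, sampler=per_trial, rope=rope,
                          level=level, ci_method=ci_method)
        )
    return reports


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(med), float(lo), float(hi)


def summarize_cohort(reports: Sequence[TrialReport]) -> CohortSummary:
    """Cohort-level medians, IQRs and Spearman rank correlations."""
    if len(reports) == 0:
        raise ValueError("summarize_cohort requires at least one report")
    return summarize_frame(reports_to_frame(reports))


def summarize_frame(df: pd.DataFrame) -> CohortSummary:
    """:func:`summarize_cohort` on a flattened report table.

    Accepts the CSV written by the reporting layer (columns
    ``p_fisher``, ``pd``, ``rope_full``), so a cohort analyzed
    elsewhere can be re-summarized without refitting.
    """
    if len(df) == 0:
        raise ValueError("summarize_frame requires at least one row")
    p = df["p_fisher"].to_numpy(float)
    pd_ = df["pd"].to_numpy(float)
    rope = df["rope_full"].to_numpy(float)
    med_p, lo_p, hi_p = _median_iqr(p)
    med_pd, lo_pd, hi_pd = _median_iqr(pd_)
    med_r, lo_r, hi_r = _median_iqr(rope)

    def spear(x, y):
        if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
            return float("nan")
        return float(stats.spearmanr(x, y).statistic)

    return CohortSummary(
        median_p=med_p, iqr_p_low=lo_p, iqr_p_high=hi_p,
        median_pd=med_pd, iqr_pd_low=lo_pd, iqr_pd_high=hi_pd,
        median_rope=med_r, iqr_rope_low=lo_r, iqr_rope_high=hi_r,
        spearman_pd_p=spear(pd_, p),
        spearman_rope_p=spear(rope, p),
        spearman_pd_rope=spear(pd_, rope),
        n_estimates=len(df),
    )


def dichotomization_table(
    reports: Sequence[TrialReport],
    alpha: float = 0.05,
    near_margin: float = 0.02,
    pd_pair_tol: float = 0.01,
) -> DichotomizationResult:
    """How a significance cut at ``alpha`` slices the Bayesian evidence.

    Cross-tabulates (P < alpha) against pd >= 97.5% and against binned
    ROPE_full, and flags *near-threshold discordant pairs*: trials whose
    P values sit within ``near_margin`` of alpha on opposite sides while
    their pd values differ by no more than ``pd_pair_tol`` — evidence
    the dichotomy separates trials with near-identical support.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = reports_to_frame(reports)
    df["significant"] = df["p_fisher"] < alpha
    pd_bin = np.where(df["pd"] >= 0.975, "pd>=97.5%", "pd<97.5%")
    rope_bin = np.select(
        [df["rope_full"] < 0.025, df["rope_full"] > 0.975],
        ["rope<2.5%", "rope>97.5%"],
        default="rope 2.5-97.5%",
    )
    by_pd = pd.crosstab(df["significant"], pd.Series(pd_bin, name="pd_bin", index=df.index))
    by_rope = pd.crosstab(df["significant"], pd.Series(rope_bin, name="rope_bin", index=df.index))
    near = df[np.abs(df["p_fisher"] - alpha) < near_margin][
        ["trial_id", "p_fisher", "pd", "rope_full", "significant"]
    ].reset_index(drop=True)
    pairs = []
    for i in range(len(near)):
        for j in range(i + 1, len(near)):
            ri, rj = near.iloc[i], near.iloc[j]
            if ri["significant"] != rj["significant"] and abs(ri["pd"] - rj["pd"]) <= pd_pair_tol:
                pairs.append(
                    {
                        "trial_id_a": ri["trial_id"], "p_a": ri["p_fisher"], "pd_a": ri["pd"],
                        "trial_id_b": rj["trial_id"], "p_b": rj["p_fisher"], "pd_b": rj["pd"],
                    }
                )
    pairs_df = pd.DataFrame(
        pairs, columns=["trial_id_a", "p_a", "pd_a", "trial_id_b", "p_b", "pd_b"]
    )
    return DichotomizationResult(
        by_pd=by_pd, by_rope=by_rope, near_threshold=near,
        discordant_pairs=pairs_df, alpha=alpha,
    )


def reports_to_frame(reports: Sequence[TrialReport]) -> pd.DataFrame:
    """Flatten reports to one row per treatment-effect estimate."""
    rows = []
    for r in reports:
        rows.append(
            {
                "trial_id": r.trial_id,
                "n_total": r.n_total,
                "or_hat": r.freq.or_hat,
                "p_fisher": r.freq.p_fisher,
                "ci_low": r.freq.ci_low,
                "ci_high": r.freq.ci_high,
                "ci_method": r.freq.ci_method,
                "median_or": r.bayes.median_or,
                "cri_low": r.bayes.cri_low,
                "cri_high": r.bayes.cri_high,
                "pd": r.bayes.pd,
                "rope_full": r.bayes.rope_full,
                "p_from_pd": pd_to_p(r.bayes.pd),
                "level": r.bayes.level,
                "converged": r.bayes.converged,
            }
        )
    return pd.DataFrame(rows)
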