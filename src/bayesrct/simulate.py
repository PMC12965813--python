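"""Synthetic cohorts of two-arm binomial trials.

Stands in for the multicenter-RCT cohorts the pipeline targets:
each trial draws a control-arm event probability, a true log odds
ratio, and per-arm sizes, then binomial event counts per arm.  The
defaults — 50–500 patients per arm, control rates uniform on
(0.2, 0.6), true log-OR ~ Normal(0, 0.35) — mix null-ish and modest
effects so cohorts span the full pd and ROPE_full ranges; they are
illustrative of anesthesiology-scale trials, not calibrated to any
particular published cohort.

Simulation is at the trial level (binomial arms given a true OR); the
analysis consumes only 2x2 counts, so patient-level structure is not
modeled.  Per-trial seeding is counter-based from the master seed, so
cohorts are reproducible and individual trials can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .trial_data import TrialCohort, TwoByTwoTrial

__all__ = ["CohortSpec", "generate_trial", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic trial cohort.

    ``n_per_arm`` is an inclusive (low, high) range sampled uniformly,
    or a fixed count; ``ctrl_rate_range`` is the uniform support of the
    control-arm event probability; ``true_log_or`` gives the (mean, sd)
    of the normal distribution of per-trial true log odds ratios.
    """

    n_trials: int = 56
    n_per_arm: tuple[int, int] | int = (50, 500)
    ctrl_rate_range: tuple[float, float] = (0.2, 0.6)
    true_log_or: tuple[float, float] = (0.0, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        lo, hi = self._arm_range()
        if lo < 2 or hi < lo:
            raise ValueError(f"n_per_arm range invalid: {self.n_per_arm}")
        rlo, rhi = self.ctrl_rate_range
        if not (0 < rlo <= rhi < 1):
            raise ValueError(f"ctrl_rate_range must lie in (0, 1): {self.ctrl_rate_range}")
        if self.true_log_or[1] < 0:
            raise ValueError("true_log_or sd must be >= 0")

    def _arm_range(self) -> tuple[int, int]:
        if isinstance(self.n_per_arm, int):
            return self.n_per_arm, self.n_per_arm
        return self.n_per_arm


def generate_trial(
    ctrl_rate: float,
    true_log_or: float,
    n_treat: int,
    n_ctrl: int,
    seed: int,
    trial_id: str = "synthetic",
) -> tuple[TwoByTwoTrial, float]:
    """One synthetic trial; returns (trial, true_log_or) for recovery tests.

    The control arm is Binomial(n_ctrl, ctrl_rate); the treatment rate
    is inverse-logit(logit(ctrl_rate) + true_log_or).  Deterministic
    given ``seed``.
    """
    if not 0 < ctrl_rate < 1:
        raise ValueError(f"ctrl_rate must be in (0, 1), got {ctrl_rate}")
    if n_treat < 2 or n_ctrl < 2:
        raise ValueError("arm sizes must be >= 2")
    rng = np.random.default_rng(seed)
    treat_rate = float(expit(logit(ctrl_rate) + true_log_or))
    events_ctrl = int(rng.binomial(n_ctrl, ctrl_rate))
    events_treat = int(rng.binomial(n_treat, treat_rate))
    trial = TwoByTwoTrial(
        trial_id=trial_id,
        events_treat=events_treat,
        n_treat=int(n_treat),
        events_ctrl=events_ctrl,
        n_ctrl=int(n_ctrl),
    )
    return trial, float(true_log_or)


def generate_cohort(spec: CohortSpec) -> tuple[TrialCohort, pd.DataFrame]:
    """A cohort per ``spec`` plus its truth table.

    The truth table has one row per trial_id with the drawn control
    rate, arm sizes and true log odds ratio, aligned with the cohort.
    """
    lo_n, hi_n = spec._arm_range()
    rows = []
    trials = []
    for i in range(spec.n_trials):
        # counter-based seeding: trial i is independent of cohort size/order
        ss = np.random.SeedSequence((spec.seed, i))
        param_rng = np.random.default_rng(ss.spawn(1)[0])
        ctrl_rate = float(param_rng.uniform(*spec.ctrl_rate_range))
        true_log_or = float(
            spec.true_log_or[0] + spec.true_log_or[1] * param_rng.standard_normal()
        )
        n_treat = int(param_rng.integers(lo_n, hi_n + 1))
        n_ctrl = int(param_rng.integers(lo_n, hi_n + 1))
        trial_seed = int(ss.generate_state(1)[0] % (2**31))
        trial, tlo = generate_trial(
            ctrl_rate, true_log_or, n_treat, n_ctrl, trial_seed, trial_id=f"synth-{i:03d}"
        )
        trials.append(trial)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "true_log_or": tlo,
                "ctrl_rate": ctrl_rate,
                "n_treat": n_treat,
                "n_ctrl": n_ctrl,
            }
        )
    cohort = TrialCohort(trials=tuple(trials), provenance="synthetic")
    return cohort, pd.DataFrame(rows)
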