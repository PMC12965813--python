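"""Domain types and I/O for two-arm binary-outcome trial data.

A trial is stored as event counts plus arm totals (``89 of 155`` style),
which is how multicenter RCT outcome tables are normally reported.  A
cohort is an ordered collection of such trials; one row of the canonical
CSV corresponds to one treatment-effect estimate (factorial designs or
coprimary outcomes contribute several rows per publication).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "TwoByTwoTrial",
    "TrialCohort",
    "TrialValidationError",
    "CohortFormatError",
    "CANONICAL_COLUMNS",
    "load_cohort",
    "save_cohort",
    "worked_example",
]

#: Canonical CSV header, in order.
CANONICAL_COLUMNS = ("trial_id", "events_treat", "n_treat", "events_ctrl", "n_ctrl")


class TrialValidationError(ValueError):
    """A trial row violates the count invariants (names trial and field)."""


class CohortFormatError(KeyError):
    """The cohort file is missing a required column."""


@dataclass(frozen=True)
class TwoByTwoTrial:
    """One trial's 2x2 outcome table.

    Parameters
    ----------
    trial_id
        Text label; unique within a cohort.
    events_treat, n_treat
        Events and total in the treatment (intervention) arm.
    events_ctrl, n_ctrl
        Events and total in the control arm.

    Zero-event arms are valid data at this layer; downstream estimators
    decide how to treat degenerate tables.
    """

    trial_id: str
    events_treat: int
    n_treat: int
    events_ctrl: int
    n_ctrl: int

    def __post_init__(self) -> None:
        for arm in ("treat", "ctrl"):
            events = getattr(self, f"events_{arm}")
            total = getattr(self, f"n_{arm}")
            if not isinstance(events, (int,)) or not isinstance(total, (int,)):
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: counts must be integers "
                    f"(events_{arm}={events!r}, n_{arm}={total!r})"
                )
            if total < 1:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: n_{arm} must be >= 1, got {total}"
                )
            if not 0 <= events <= total:
                raise TrialValidationError(
                    f"trial {self.trial_id!r}: events_{arm}={events} outside "
                    f"[0, n_{arm}={total}]"
                )

    @property
    def n_total(self) -> int:
        return self.n_treat + self.n_ctrl

    @property
    def rate_treat(self) -> float:
        return self.events_treat / self.n_treat

    @property
    def rate_ctrl(self) -> float:
        return self.events_ctrl / self.n_ctrl

    def counts(self) -> tuple[int, int, int, int]:
        """Cell counts (a, b, c, d): events/non-events by arm."""
        return (
            self.events_treat,
            self.n_treat - self.events_treat,
            self.events_ctrl,
            self.n_ctrl - self.events_ctrl,
        )

    def swapped_arms(self) -> "TwoByTwoTrial":
        """The same data with treatment and control labels exchanged."""
        return TwoByTwoTrial(
            trial_id=self.trial_id,
            events_treat=self.events_ctrl,
            n_treat=self.n_ctrl,
            events_ctrl=self.events_treat,
            n_ctrl=self.n_treat,
        )


@dataclass(frozen=True)
class TrialCohort:
    """An ordered collection of trials with unique ids."""

    trials: tuple[TwoByTwoTrial, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrialValidationError(f"duplicate trial_id values in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TwoByTwoTrial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> TwoByTwoTrial:
        return self.trials[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": t.trial_id,
                    "events_treat": t.events_treat,
                    "n_treat": t.n_treat,
                    "events_ctrl": t.events_ctrl,
                    "n_ctrl": t.n_ctrl,
                }
                for t in self.trials
            ],
            columns=list(CANONICAL_COLUMNS),
        )


def worked_example() -> TwoByTwoTrial:
    """The amisulpride postoperative nausea/vomiting prevention trial.

    318 adult surgical patients; 89 of 155 in the intervention arm and
    76 of 163 in the placebo arm experienced the positive outcome.
    """
    return TwoByTwoTrial(
        trial_id="amisulpride",
        events_treat=89,
        n_treat=155,
        events_ctrl=76,
        n_ctrl=163,
    )


def load_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TrialCohort:
    """Read a cohort CSV into a :class:`TrialCohort`.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Canonical column names
        are ``trial_id, events_treat, n_treat, events_ctrl, n_ctrl``.
    column_map
        Optional mapping from canonical name to the name used in the
        file, e.g. ``{"events_treat": "x1"}``.

    Raises
    ------
    CohortFormatError
        A required column is absent (after mapping).
    TrialValidationError
        A row violates the count invariants; the error names the
        trial_id and field rather than dropping the row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise CohortFormatError(
                f"cohort file {path} is missing required column {actual!r} "
                f"(for {canonical!r})"
            )
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TwoByTwoTrial(
                trial_id=str(row[colmap["trial_id"]]),
                events_treat=int(row[colmap["events_treat"]]),
                n_treat=int(row[colmap["n_treat"]]),
                events_ctrl=int(row[colmap["events_ctrl"]]),
                n_ctrl=int(row[colmap["n_ctrl"]]),
            )
        )
    return TrialCohort(trials=tuple(trials), provenance=str(path))


def save_cohort(cohort: TrialCohort | Sequence[TwoByTwoTrial], path: str | Path) -> Path:
    """Write a cohort to the canonical CSV; round-trips exactly."""
    if not isinstance(cohort, TrialCohort):
        cohort = TrialCohort(trials=tuple(cohort), provenance="in-memory")
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path
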