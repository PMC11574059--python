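"""Feeding-trial records and their tidy tabular representation.

A :class:`Trial` is one predation trial: one fish, one arena, a known
number of prey offered (``n_initial``), the number eaten (``n_eaten``)
and the trial duration in hours.  Group labels (sex, temperature, prey
size class, pregnancy stage, replicate) identify the experimental cell.

Mixed-prey trials additionally carry per-size-class offered/eaten counts
(``n_initial_small``/``n_eaten_small`` and the large-prey analogues); the
totals must be consistent with the per-class counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import TrialValidationError

__all__ = ["Trial", "TRIAL_COLUMNS", "MIXED_COLUMNS", "trials_to_frame", "frame_to_trials"]

TRIAL_COLUMNS = [
    "sex", "temperature_C", "prey_size", "pregnancy", "replicate",
    "n_initial", "n_eaten", "duration_h",
]
MIXED_COLUMNS = [
    "n_initial_small", "n_initial_large", "n_eaten_small", "n_eaten_large",
]

SEXES = {"female", "male"}
PREY_SIZES = {"small", "large", "mixed"}
PREGNANCY = {"none", "stage1", "stage2"}


@dataclass(frozen=True)
class Trial:
    sex: str = "female"
    temperature_C: float = 25.0
    prey_size: str = "small"
    pregnancy: str = "none"
    replicate: int = 1
    n_initial: int = 0
    n_eaten: int = 0
    duration_h: float = 1.0
    # per-class counts, present only for mixed-prey trials
    n_initial_small: int | None = None
    n_initial_large: int | None = None
    n_eaten_small: int | None = None
    n_eaten_large: int | None = None

    def __post_init__(self) -> None:
        if self.n_initial < 0 or self.n_eaten < 0:
            raise TrialValidationError("counts must be nonnegative")
        if self.n_eaten > self.n_initial:
            raise TrialValidationError(
                f"n_eaten ({self.n_eaten}) exceeds n_initial ({self.n_initial})"
            )
        if self.duration_h <= 0:
            raise TrialValidationError("duration_h must be positive")
        if self.is_mixed:
            s0, l0 = self.n_initial_small, self.n_initial_large
            se, le = self.n_eaten_small, self.n_eaten_large
            if None in (s0, l0, se, le):
                raise TrialValidationError("mixed trial is missing per-class counts")
            if se > s0 or le > l0 or min(s0, l0, se, le) < 0:
                raise TrialValidationError("per-class eaten counts exceed offered counts")
            if s0 + l0 != self.n_initial or se + le != self.n_eaten:
                raise TrialValidationError("per-class counts do not sum to totals")

    @property
    def is_mixed(self) -> bool:
        return self.n_initial_small is not None or self.n_eaten_small is not None

    @property
    def group(self) -> tuple:
        return (self.sex, self.temperature_C, self.prey_size, self.pregnancy)


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Tidy DataFrame in the documented column dialect (mixed columns
    included only when at least one trial is mixed)."""
    trials = list(trials)
    rows = []
    any_mixed = any(t.is_mixed for t in trials)
    cols = TRIAL_COLUMNS + (MIXED_COLUMNS if any_mixed else [])
    for t in trials:
        row = {c: getattr(t, c) for c in cols}
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    """Convert a validated tidy table back to Trial records."""
    mixed = all(c in df.columns for c in MIXED_COLUMNS)
    out: list[Trial] = []
    for _, r in df.iterrows():
        kwargs = dict(
            sex=str(r["sex"]),
            temperature_C=float(r["temperature_C"]),
            prey_size=str(r["prey_size"]),
            pregnancy=str(r["pregnancy"]),
            replicate=int(r["replicate"]),
            n_initial=int(r["n_initial"]),
            n_eaten=int(r["n_eaten"]),
            duration_h=float(r["duration_h"]),
        )
        if mixed and not pd.isna(r["n_initial_small"]):
            kwargs.update(
                n_initial_small=int(r["n_initial_small"]),
                n_initial_large=int(r["n_initial_large"]),
                n_eaten_small=int(r["n_eaten_small"]),
                n_eaten_large=int(r["n_eaten_large"]),
            )
        out.append(Trial(**kwargs))
    return out
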