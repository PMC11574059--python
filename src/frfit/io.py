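"""CSV readers/writers for the documented trial-table dialect.

Single-size tables carry the columns::

    sex, temperature_C, prey_size, pregnancy, replicate,
    n_initial, n_eaten, duration_h

Mixed-prey tables append ``n_initial_small, n_initial_large,
n_eaten_small, n_eaten_large``.  Rows violating the invariants (counts
integer, 0 <= eaten <= offered per class, duration_h > 0) are rejected
with their line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import TrialValidationError
from .trials import MIXED_COLUMNS, TRIAL_COLUMNS, Trial, frame_to_trials, trials_to_frame

__all__ = ["read_trials", "write_trials"]

_MAX_OFFENSES = 10


def _check_row(i: int, row: pd.Series, mixed: bool) -> list[tuple[int, str]]:
    line = i + 2  # 1-based, after the header line
    offenses = []
    try:
        n0, ne = float(row["n_initial"]), float(row["n_eaten"])
        if n0 != int(n0) or ne != int(ne):
            offenses.append((line, "counts must be integers"))
        if ne < 0 or n0 < 0:
            offenses.append((line, "counts must be nonnegative"))
        if ne > n0:
            offenses.append((line, f"n_eaten ({ne:g}) > n_initial ({n0:g})"))
        if float(row["duration_h"]) <= 0:
            offenses.append((line, "duration_h must be > 0"))
        if mixed and not pd.isna(row["n_initial_small"]):
            s0, l0 = float(row["n_initial_small"]), float(row["n_initial_large"])
            se, le = float(row["n_eaten_small"]), float(row["n_eaten_large"])
            if se > s0 or le > l0 or min(s0, l0, se, le) < 0:
                offenses.append((line, "per-class eaten exceeds offered"))
            elif s0 + l0 != n0 or se + le != ne:
                offenses.append((line, "per-class counts do not sum to totals"))
    except (ValueError, TypeError, KeyError) as exc:
        offenses.append((line, f"unparseable row: {exc}"))
    return offenses


def read_trials(path: str | Path) -> list[Trial]:
    """Read and validate a trial CSV; raises TrialValidationError listing
    the first offending lines on any invariant violation."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected header {TRIAL_COLUMNS}")
    mixed = all(c in df.columns for c in MIXED_COLUMNS)

    offenses: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        offenses.extend(_check_row(i, row, mixed))
        if len(offenses) >= _MAX_OFFENSES:
            break
    if offenses:
        listing = "; ".join(f"line {ln}: {msg}" for ln, msg in offenses[:_MAX_OFFENSES])
        raise TrialValidationError(f"{path.name}: invalid rows — {listing}", offenses)
    return frame_to_trials(df)


def write_trials(trials: Sequence[Trial], path: str | Path) -> None:
    """Write trials in the standard dialect (round-trips with read_trials)."""
    trials_to_frame(trials).to_csv(path, index=False)
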