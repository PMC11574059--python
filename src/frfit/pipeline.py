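"""End-to-end comparative functional-response workflow.

Orchestrates the full analysis over a trial table: per-group type
determination and Rogers MLE, pairwise parameter comparisons (sex with
temperatures pooled, temperature ladders per sex and prey size,
pregnancy stages), bootstrap confidence bands, and the prey-size
selection analysis on mixed-prey trials.  The report is a plain,
JSON-serializable dict; every stage's output is carried through
unmodified.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .comparison import bootstrap_fr, juliano_compare, pairwise_compare
from .errors import DegenerateDataError, FRFitError
from .inference import classify_fr_type, fit_rogers, summarize_fit
from .io import read_trials
from .selection import selection_report
from .simulate import simulate_study_design
from .trials import Trial

__all__ = ["PipelineConfig", "run_pipeline", "group_trials", "save_report"]

log = logging.getLogger("frfit")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``input_csv`` unset, a synthetic dataset with the default
    factorial design is simulated first (seeded).
    """

    input_csv: str | None = None
    seed: int = 1
    n_boot: int = 2000
    alpha: float = 0.05
    replicates: int = 3
    process: str = "binomial"
    include_mixed: bool = True
    compare_sexes: bool = True
    compare_temperatures: bool = True
    compare_pregnancy: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def group_trials(trials: Sequence[Trial]) -> dict[tuple, list[Trial]]:
    """Split trials by (sex, temperature, prey size, pregnancy)."""
    groups: dict[tuple, list[Trial]] = {}
    for t in trials:
        groups.setdefault(t.group, []).append(t)
    return groups


def _gkey(group: tuple) -> str:
    sex, temp, size, preg = group
    return f"{sex}|{temp:g}C|{size}|{preg}"


def _jsonable(obj):
    """Recursively coerce report values (numpy scalars, tuple keys) to
    JSON-compatible types."""
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else
             " vs ".join(map(str, k)) if isinstance(k, tuple) else str(k)):
            _jsonable(v) for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full comparative-FR analysis; returns the report dict.

    Deterministic given ``config.seed``: the same config reproduces the
    same report bit-for-bit.
    """
    log.info("pipeline start: seed=%d n_boot=%d alpha=%g",
             config.seed, config.n_boot, config.alpha)
    if config.input_csv:
        trials = read_trials(config.input_csv)
        log.info("read %d trials from %s", len(trials), config.input_csv)
    else:
        trials = simulate_study_design(
            seed=config.seed, replicates=config.replicates,
            process=config.process, include_mixed=config.include_mixed)
        log.info("simulated %d trials (default factorial design)", len(trials))

    groups = group_trials(trials)
    single = {g: ts for g, ts in groups.items() if g[2] in ("small", "large")}
    mixed = [t for ts in groups.values() for t in ts if t.is_mixed]

    report: dict = {
        "config": asdict(config),
        "groups": {},
        "comparisons": {},
        "bands": {},
        "selection": {},
        "log": {
            "seed": config.seed,
            "versions": {
                "python": platform.python_version(),
                "frfit": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "n_trials": len(trials),
            "dropped_bootstrap_replicates": {},
        },
    }

    # Stage 1–2: per-group type test and Rogers fit
    fits = {}
    for g, ts in sorted(single.items()):
        key = _gkey(g)
        entry: dict = {}
        try:
            tt = classify_fr_type(ts, alpha=config.alpha)
            entry["type_test"] = {
                "first_order_coef": tt.first_order_coef,
                "p_value": tt.p_value,
                "inferred_type": tt.inferred_type,
                "degree": tt.degree,
            }
        except DegenerateDataError as exc:
            entry["type_test"] = {"error": str(exc)}
        fit = fit_rogers(ts)
        fits[g] = (ts, fit)
        entry["fit"] = summarize_fit(fit)
        report["groups"][key] = entry
        log.info("group %s: a=%.4g h=%.4g", key, fit.params.a, fit.params.h)

    # Stage 3a: sex comparison on pooled temperatures, per prey size
    if config.compare_sexes:
        sex_cmp = {}
        for size in ("small", "large"):
            fem = [t for g, ts in single.items() for t in ts
                   if g[0] == "female" and g[2] == size and g[3] == "none"]
            mal = [t for g, ts in single.items() for t in ts
                   if g[0] == "male" and g[2] == size and g[3] == "none"]
            if fem and mal:
                cmp_ = juliano_compare(fem, mal, "female", "male")
                sex_cmp[size] = cmp_.to_dict()
        report["comparisons"]["sex_pooled_temperature"] = sex_cmp

    # Stage 3b: temperature ladders per (sex, prey size)
    if config.compare_temperatures:
        temp_cmp = {}
        for sex in ("female", "male"):
            for size in ("small", "large"):
                ladder = {f"{g[1]:g}C": ts for g, ts in sorted(single.items())
                          if g[0] == sex and g[2] == size and g[3] == "none"}
                if len(ladder) >= 2:
                    temp_cmp[f"{sex}|{size}"] = pairwise_compare(
                        ladder, alpha=config.alpha)
        report["comparisons"]["temperature"] = temp_cmp

    # Stage 3c: pregnancy stages (female, 25 C, small prey)
    if config.compare_pregnancy:
        stages = {g[3]: ts for g, ts in sorted(single.items())
                  if g[0] == "female" and g[2] == "small"
                  and (g[3] != "none" or g[1] == 25.0)}
        if len(stages) >= 2:
            report["comparisons"]["pregnancy"] = pairwise_compare(
                stages, alpha=config.alpha)

    # Bootstrap bands (optional stage)
    if config.n_boot >= 2:
        for g, (ts, fit) in sorted(fits.items()):
            band = bootstrap_fr(ts, n_boot=config.n_boot, seed=config.seed)
            report["bands"][_gkey(g)] = band.to_dict()
            if band.n_failed:
                report["log"]["dropped_bootstrap_replicates"][_gkey(g)] = band.n_failed

    # Prey-size selection on mixed trials, per sex
    if mixed:
        for sex in ("female", "male"):
            sub = [t for t in mixed if t.sex == sex]
            if sub:
                try:
                    report["selection"][sex] = selection_report(sub, alpha=config.alpha)
                except DegenerateDataError as exc:
                    report["selection"][sex] = {"error": str(exc)}

    log.info("pipeline done: %d groups, %d comparisons blocks",
             len(report["groups"]), len(report["comparisons"]))
    return _jsonable(report)


def save_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
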