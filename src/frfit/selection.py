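"""Prey-size-selection statistics for mixed-prey trials.

Consumption of small versus large prey is compared only at densities
where neither size class was completely depleted (ceiling-censored
counts would bias the means), using t statistics per temperature,
one-way ANOVA with Tukey pairwise comparisons across temperatures, and
count-to-biomass conversion with the class mean masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .letters import GREEK, LATIN, compact_letters
from .trials import Trial

__all__ = [
    "PreySizeClass", "SMALL_PREY", "LARGE_PREY", "nondepleted_filter",
    "small_vs_large_test", "temperature_anova", "biomass", "selection_report",
]


@dataclass(frozen=True)
class PreySizeClass:
    """A prey size class: chironomid larvae binned by body length, with
    the class mean individual mass used for biomass conversion."""

    label: str
    length_range_mm: tuple
    mean_mass_mg: float
    sd_mass_mg: float

    def __post_init__(self) -> None:
        if self.mean_mass_mg <= 0:
            raise ValueError("mean mass must be positive")


SMALL_PREY = PreySizeClass("small", (4.0, 6.0), 0.13, 0.03)
LARGE_PREY = PreySizeClass("large", (10.0, 12.0), 0.93, 0.2)
_DEFAULT_CLASSES = {"small": SMALL_PREY, "large": LARGE_PREY}


def nondepleted_filter(trials: Sequence[Trial]) -> list[Trial]:
    """Keep mixed-prey trials only at densities where no size class was
    fully consumed in any replicate of the same group.

    The rule is strict: one depleted replicate of either class excludes
    that (group, density) cell entirely, avoiding ceiling-censored
    counts.
    """
    trials = [t for t in trials if t.is_mixed]
    if not trials:
        raise DegenerateDataError("no mixed-prey trials to filter")
    bad: set = set()
    for t in trials:
        depleted = (t.n_eaten_small == t.n_initial_small
                    or t.n_eaten_large == t.n_initial_large)
        if depleted:
            bad.add((t.group, t.n_initial))
    kept = [t for t in trials if (t.group, t.n_initial) not in bad]
    if not kept:
        groups = sorted({str(t.group) for t in trials})
        raise DegenerateDataError(
            f"every density was depleted in some replicate for group(s) {groups}")
    return kept


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def small_vs_large_test(
    trials: Sequence[Trial],
    welch: bool = True,
    paired: bool = False,
    classes: Mapping[str, PreySizeClass] = _DEFAULT_CLASSES,
) -> dict:
    """Per-temperature comparison of mean small vs large prey consumed
    (counts and biomass) in non-depleted mixed trials.

    Welch's unequal-variance t is the default; set ``welch=False`` for
    the pooled-variance variant or ``paired=True`` to pair size classes
    within tanks.
    """
    out: dict = {}
    temps = sorted({t.temperature_C for t in trials})
    for temp in temps:
        sub = [t for t in trials if t.temperature_C == temp]
        if len(sub) < 2:
            raise DegenerateDataError(
                f"need >= 2 retained trials at {temp} C, got {len(sub)}")
        small = np.array([t.n_eaten_small for t in sub], dtype=float)
        large = np.array([t.n_eaten_large for t in sub], dtype=float)
        if small.std() == 0 and large.std() == 0 and small.mean() != large.mean():
            raise DegenerateDataError(f"zero variance in both samples at {temp} C")
        if paired:
            t_stat, p = stats.ttest_rel(small, large)
        else:
            t_stat, p = stats.ttest_ind(small, large, equal_var=not welch)
        bm_small = small * classes["small"].mean_mass_mg
        bm_large = large * classes["large"].mean_mass_mg
        if paired:
            tb, pb = stats.ttest_rel(bm_small, bm_large)
        else:
            tb, pb = stats.ttest_ind(bm_small, bm_large, equal_var=not welch)
        sem = lambda x: float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        out[temp] = {
            "n": len(sub),
            "mean_small": float(small.mean()), "se_small": sem(small),
            "mean_large": float(large.mean()), "se_large": sem(large),
            "t_counts": float(t_stat), "p_counts": float(p),
            "stars_counts": _stars(float(p)),
            "t_biomass": float(tb), "p_biomass": float(pb),
            "stars_biomass": _stars(float(pb)),
        }
    return out


def temperature_anova(
    by_temperature: Mapping[float, Sequence[float]],
    size_class: str = "small",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across temperatures plus Tukey HSD letters.

    Letters follow the figure convention of Latin letters for small prey
    and Greek letters for large prey; distinct letters mark pairs with
    Tukey-adjusted p < alpha.
    """
    temps = sorted(by_temperature)
    if len(temps) < 2:
        raise DegenerateDataError("ANOVA needs at least two temperature groups")
    samples = [np.asarray(by_temperature[t], dtype=float) for t in temps]
    if any(len(s) < 2 for s in samples):
        raise DegenerateDataError("each temperature needs >= 2 observations")

    alphabet = GREEK if size_class == "large" else LATIN
    if all(s.std() == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # no variance anywhere: degenerate, all groups alike
        return {"F": 0.0, "p": 1.0, "degenerate": True,
                "pairwise_p": {}, "letters": {t: alphabet[0] for t in temps}}

    F, p = stats.f_oneway(*samples)
    tuk = stats.tukey_hsd(*samples)
    pairwise = {}
    for i in range(len(temps)):
        for j in range(i + 1, len(temps)):
            pairwise[(temps[i], temps[j])] = float(tuk.pvalue[i, j])
    letters = compact_letters(temps, pairwise, alpha, alphabet)
    return {"F": float(F), "p": float(p), "degenerate": False,
            "pairwise_p": pairwise, "letters": letters}


def biomass(
    counts: Mapping[str, float],
    classes: Mapping[str, PreySizeClass] = _DEFAULT_CLASSES,
) -> float:
    """Total prey biomass in mg: count x class mean individual mass,
    summed over classes (0.13 mg small, 0.93 mg large by default)."""
    total = 0.0
    for label, count in counts.items():
        if label not in classes:
            raise KeyError(f"unknown prey size class {label!r}")
        if count < 0:
            raise ValueError("counts must be nonnegative")
        total += count * classes[label].mean_mass_mg
    return total


def selection_report(
    mixed_trials: Sequence[Trial],
    alpha: float = 0.05,
    classes: Mapping[str, PreySizeClass] = _DEFAULT_CLASSES,
) -> dict:
    """Full prey-size-selection analysis of a set of mixed-prey trials
    from one sex: non-depleted filtering, per-temperature small-vs-large
    tests, cross-temperature ANOVA + Tukey letters per class, biomass
    totals."""
    kept = nondepleted_filter(mixed_trials)
    per_temp = small_vs_large_test(kept, classes=classes)
    temps = sorted({t.temperature_C for t in kept})

    anova = {}
    for label, attr in (("small", "n_eaten_small"), ("large", "n_eaten_large")):
        by_temp = {tmp: [getattr(t, attr) for t in kept if t.temperature_C == tmp]
                   for tmp in temps}
        by_temp = {k: v for k, v in by_temp.items() if len(v) >= 2}
        if len(by_temp) >= 2:
            anova[label] = temperature_anova(by_temp, size_class=label, alpha=alpha)

    totals = {
        "count_small": sum(t.n_eaten_small for t in kept),
        "count_large": sum(t.n_eaten_large for t in kept),
    }
    totals["biomass_mg"] = biomass(
        {"small": totals["count_small"], "large": totals["count_large"]}, classes)
    return {
        "n_retained": len(kept),
        "retained_densities": sorted({t.n_initial for t in kept}),
        "per_temperature": per_temp,
        "anova": anova,
        "totals": totals,
    }
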