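"""Synthetic predation-trial generator.

Emulates a factorial guppy–chironomid feeding-trial design: 1-hour
no-replacement trials over doubling prey-density ladders, replicated
per cell of (sex x temperature x prey size x pregnancy stage).  Two
stochastic consumption processes are available:

* ``binomial`` — each trial draws ``Ne ~ Binomial(N0, Ne_hat/N0)`` with
  ``Ne_hat`` the Rogers expectation.  This matches the fitting
  likelihood exactly, so it is the clean process for parameter-recovery
  tests.
* ``mechanistic`` — a search/handle renewal simulation: waiting time to
  the next capture is exponential with rate ``a * N_remaining``, each
  capture is followed by a deterministic handling period ``h`` during
  which search stops, until the time budget ``T`` is spent.  This is
  model-independent of the fitting likelihood and serves as the
  robustness oracle.

Mixed-prey trials use two competing capture streams (class-specific a
and h) sharing one time budget: captures interleave in continuous time
and handling of either class blocks both streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import FRParams, rogers_expected
from .errors import FRFitError
from .trials import Trial

__all__ = [
    "SimConfig", "simulate_trials", "simulate_study_design",
    "default_group_map", "BASE_DENSITIES", "EXTENDED_DENSITIES",
]

BASE_DENSITIES = (2, 4, 8, 16, 32, 64)
EXTENDED_DENSITIES = (2, 4, 8, 16, 32, 64, 128, 256)
TEMPERATURES = (22.0, 25.0, 28.0)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a single-group simulation."""

    attack_rate: float
    handling_time: float
    duration: float = 1.0
    densities: tuple = BASE_DENSITIES
    replicates: int = 3
    process: str = "binomial"  # or "mechanistic"
    seed: int = 0
    sex: str = "female"
    temperature_C: float = 25.0
    prey_size: str = "small"
    pregnancy: str = "none"

    def __post_init__(self) -> None:
        d = tuple(self.densities)
        if not d or any(x <= 0 or int(x) != x for x in d) or list(d) != sorted(set(d)):
            raise ValueError("densities must be strictly increasing positive integers")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.process not in ("binomial", "mechanistic"):
            raise ValueError(f"unknown noise process {self.process!r}")
        FRParams(self.attack_rate, self.handling_time, self.duration)  # domain check

    @property
    def params(self) -> FRParams:
        return FRParams(self.attack_rate, self.handling_time, self.duration)


def _mechanistic_once(rng: np.random.Generator, n0: int, a: float, h: float,
                      T: float) -> int:
    """One renewal-process trial: exponential search, deterministic handling."""
    if a == 0.0 or n0 == 0:
        return 0
    t, remaining, eaten = 0.0, n0, 0
    while remaining > 0:
        t += rng.exponential(1.0 / (a * remaining))
        if t >= T:
            break
        eaten += 1
        remaining -= 1
        t += h  # handling blocks further search
    return eaten


def _mechanistic_mixed_once(
    rng: np.random.Generator, n_small: int, n_large: int,
    p_small: FRParams, p_large: FRParams, T: float,
) -> tuple[int, int]:
    """Two competing capture streams over a common time budget."""
    t = 0.0
    rem = {"small": n_small, "large": n_large}
    eaten = {"small": 0, "large": 0}
    pars = {"small": p_small, "large": p_large}
    while rem["small"] + rem["large"] > 0:
        rate = sum(pars[c].a * rem[c] for c in rem)
        if rate == 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= T:
            break
        w_small = pars["small"].a * rem["small"]
        cls = "small" if rng.random() < w_small / rate else "large"
        eaten[cls] += 1
        rem[cls] -= 1
        t += pars[cls].h
    return eaten["small"], eaten["large"]


def simulate_trials(config: SimConfig,
                    rng: np.random.Generator | None = None) -> list[Trial]:
    """Simulate one group's trials over its density ladder.

    Deterministic given ``config.seed`` (or the supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a, h, T = config.attack_rate, config.handling_time, config.duration
    out: list[Trial] = []
    for n0 in config.densities:
        if config.process == "binomial":
            p = rogers_expected(float(n0), config.params) / n0 if a > 0 else 0.0
            eaten = rng.binomial(n0, p, size=config.replicates)
        else:
            eaten = [_mechanistic_once(rng, n0, a, h, T)
                     for _ in range(config.replicates)]
        for rep, ne in enumerate(eaten, start=1):
            out.append(Trial(
                sex=config.sex, temperature_C=config.temperature_C,
                prey_size=config.prey_size, pregnancy=config.pregnancy,
                replicate=rep, n_initial=int(n0), n_eaten=int(ne),
                duration_h=T,
            ))
    return out


def default_group_map() -> dict:
    """Per-cell (attack rate, handling time) for the full factorial design.

    Keys are (sex, temperature_C, prey_size, pregnancy) with prey_size in
    {"small", "large"}; mixed-prey cells reuse the two single-size
    entries of the same (sex, temperature).  Values encode the
    qualitative structure of a strongly size-dimorphic larvivore:
    females handle prey roughly an order of magnitude faster than males,
    handling time falls with temperature on small prey but not large,
    and late pregnancy shortens female handling time further.
    """
    m: dict = {}
    # females, small prey: asymptote ~80 -> ~100 -> ~140 prey/h
    m[("female", 22.0, "small", "none")] = (3.0, 0.0125)
    m[("female", 25.0, "small", "none")] = (2.0, 0.0100)
    m[("female", 28.0, "small", "none")] = (2.0, 0.0072)
    # females, large prey: satiety-limited, no temperature trend in h,
    # attack rate peaks at the intermediate temperature
    m[("female", 22.0, "large", "none")] = (2.0, 0.070)
    m[("female", 25.0, "large", "none")] = (3.0, 0.070)
    m[("female", 28.0, "large", "none")] = (2.0, 0.070)
    # males, small prey: asymptote ~5 -> ~10 -> ~14 prey/h
    m[("male", 22.0, "small", "none")] = (1.5, 0.185)
    m[("male", 25.0, "small", "none")] = (1.5, 0.100)
    m[("male", 28.0, "small", "none")] = (1.5, 0.070)
    # males, large prey: ~2 prey/h, temperature-insensitive
    m[("male", 22.0, "large", "none")] = (1.0, 0.45)
    m[("male", 25.0, "large", "none")] = (1.0, 0.45)
    m[("male", 28.0, "large", "none")] = (1.0, 0.45)
    # pregnancy (25 C, small prey): handling time shrinks with stage
    m[("female", 25.0, "small", "stage1")] = (2.0, 0.0103)
    m[("female", 25.0, "small", "stage2")] = (2.0, 0.0084)
    return m


def _cell_params(group_map: Mapping, sex: str, temp: float, size: str,
                 pregnancy: str, T: float) -> FRParams:
    key = (sex, temp, size, pregnancy)
    if key not in group_map:
        raise FRFitError(f"group map is missing cell {key}")
    a, h = group_map[key]
    return FRParams(a, h, T)


def simulate_study_design(
    group_map: Mapping | None = None,
    seed: int = 1,
    replicates: int = 3,
    process: str = "binomial",
    duration: float = 1.0,
    include_mixed: bool = True,
) -> list[Trial]:
    """Simulate the full two-experiment factorial dataset.

    Experiment 1: 2 sexes x 3 temperatures (22, 25, 28 C) x densities
    2–64 doubling x {small, large} single-size treatments (females on
    small prey extended to 128 and 256) plus, optionally, mixed-size
    treatments offering small and large prey 1:1.  Experiment 2:
    non-pregnant ladder reused plus 2 pregnancy stages at 25 C on small
    prey over densities 2–256.  One tidy trial list, deterministic given
    ``seed``.
    """
    gm = default_group_map() if group_map is None else dict(group_map)
    rng = np.random.default_rng(seed)
    out: list[Trial] = []

    # Experiment 1 — single-size treatments
    for sex in ("female", "male"):
        for temp in TEMPERATURES:
            for size in ("small", "large"):
                dens = (EXTENDED_DENSITIES
                        if (sex == "female" and size == "small")
                        else BASE_DENSITIES)
                p = _cell_params(gm, sex, temp, size, "none", duration)
                cfg = SimConfig(
                    attack_rate=p.a, handling_time=p.h, duration=duration,
                    densities=dens, replicates=replicates, process=process,
                    sex=sex, temperature_C=temp, prey_size=size,
                )
                out.extend(simulate_trials(cfg, rng=rng))

    # Experiment 1 — mixed-size treatments (1:1 split, competing streams)
    if include_mixed:
        for sex in ("female", "male"):
            for temp in TEMPERATURES:
                ps = _cell_params(gm, sex, temp, "small", "none", duration)
                pl = _cell_params(gm, sex, temp, "large", "none", duration)
                for n0 in BASE_DENSITIES:
                    ns, nl = n0 // 2, n0 - n0 // 2
                    for rep in range(1, replicates + 1):
                        es, el = _mechanistic_mixed_once(rng, ns, nl, ps, pl,
                                                         duration)
                        out.append(Trial(
                            sex=sex, temperature_C=temp, prey_size="mixed",
                            pregnancy="none", replicate=rep,
                            n_initial=n0, n_eaten=es + el, duration_h=duration,
                            n_initial_small=ns, n_initial_large=nl,
                            n_eaten_small=es, n_eaten_large=el,
                        ))

    # Experiment 2 — pregnancy stages at 25 C, small prey, extended ladder
    for stage in ("stage1", "stage2"):
        p = _cell_params(gm, "female", 25.0, "small", stage, duration)
        cfg = SimConfig(
            attack_rate=p.a, handling_time=p.h, duration=duration,
            densities=EXTENDED_DENSITIES, replicates=replicates,
            process=process, sex="female", temperature_C=25.0,
            prey_size="small", pregnancy=stage,
        )
        out.extend(simulate_trials(cfg, rng=rng))

    return out
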