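"""Between-group comparison of functional-response parameters.

Two complementary tools:

* **Indicator-variable difference test** (Juliano's method): the two
  groups are fitted jointly with the parameterization

      a = a1 + Δa·j,   h = h1 + Δh·j,      j ∈ {0, 1},

  so Δa and Δh are the group-2 minus group-1 differences, and Wald Z
  tests of Δa = 0 and Δh = 0 ask directly whether attack rate or
  handling time differ between groups.

* **Non-parametric bootstrap bands**: trials (the independent
  experimental units — one fish per tank) are resampled with
  replacement, the Rogers model refitted per replicate, and pointwise
  2.5/97.5 percentile envelopes of the predicted consumption curve
  reported on a density grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core import FRParams, rogers_expected
from .errors import BootstrapInstabilityError, ConvergenceError, FRFitError
from .inference import FRFit, _design_arrays, _nll_factory, _numeric_hessian, fit_rogers
from .letters import compact_letters
from .trials import Trial

__all__ = [
    "ComparisonResult", "BootstrapBand", "juliano_compare", "bootstrap_fr",
    "overlap_verdict", "pairwise_compare",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Juliano indicator-variable differences (group 2 minus group 1)."""

    delta_a: float
    delta_h: float
    se_delta_a: float
    se_delta_h: float
    z_delta_a: float
    z_delta_h: float
    p_delta_a: float
    p_delta_h: float
    baseline: FRFit           # group-1 fit from the pooled model's (a1, h1)
    label_1: str
    label_2: str
    log_likelihood: float
    design_overlap: bool = True

    def to_dict(self) -> dict:
        return {
            "group_1": self.label_1,
            "group_2": self.label_2,
            "delta_a": self.delta_a, "se_delta_a": self.se_delta_a,
            "z_delta_a": self.z_delta_a, "p_delta_a": self.p_delta_a,
            "delta_h": self.delta_h, "se_delta_h": self.se_delta_h,
            "z_delta_h": self.z_delta_h, "p_delta_h": self.p_delta_h,
            "a_1": self.baseline.params.a, "h_1": self.baseline.params.h,
            "log_likelihood": self.log_likelihood,
            "design_overlap": self.design_overlap,
        }


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise 95% percentile envelope of bootstrap-refitted FR curves.

    Percentile bands of refits need not bracket the point-estimate
    curve; the guaranteed ordering is ``lower95 <= upper95`` pointwise.
    """

    grid: tuple
    mean_curve: tuple
    point_curve: tuple
    lower95: tuple
    upper95: tuple
    n_boot: int
    n_failed: int
    seed: int
    draws: tuple = field(default=(), repr=False)  # optional (a, h) per replicate

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {
            "grid": list(self.grid),
            "mean_curve": list(self.mean_curve),
            "point_curve": list(self.point_curve),
            "lower95": list(self.lower95),
            "upper95": list(self.upper95),
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }
        if include_draws:
            d["draws"] = [list(x) for x in self.draws]
        return d


def _pooled_nll(trials_1: Sequence[Trial], trials_2: Sequence[Trial]):
    nll1 = _nll_factory(trials_1)
    nll2 = _nll_factory(trials_2)

    def nll(theta: np.ndarray) -> float:
        a1, h1, da, dh = theta
        a2, h2 = a1 + da, h1 + dh
        if a1 <= 0 or h1 < 0 or a2 <= 0 or h2 < 0:
            return 1e12
        lh1 = math.log(max(h1, 1e-12))
        lh2 = math.log(max(h2, 1e-12))
        return nll1(np.array([math.log(a1), lh1])) + nll2(np.array([math.log(a2), lh2]))

    return nll


def juliano_compare(
    trials_1: Sequence[Trial],
    trials_2: Sequence[Trial],
    label_1: str = "group1",
    label_2: str = "group2",
) -> ComparisonResult:
    """Test for differences in attack rate and handling time between two
    groups by the pooled indicator-variable binomial MLE.

    Non-overlapping density designs are permitted (flagged in the
    result); an unfittable group propagates its fitting error.
    """
    fit1 = fit_rogers(trials_1)
    fit2 = fit_rogers(trials_2)

    d1 = {t.n_initial for t in trials_1}
    d2 = {t.n_initial for t in trials_2}
    overlap = bool(d1 & d2)

    nll = _pooled_nll(trials_1, trials_2)
    x0 = np.array([
        fit1.params.a, fit1.params.h,
        fit2.params.a - fit1.params.a, fit2.params.h - fit1.params.h,
    ])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 8000, "maxfev": 8000})
    # restart from the solution: a fresh simplex tightens Nelder-Mead's
    # terminal accuracy enough for swap-symmetry of the Wald tests
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-11,
                                     "maxiter": 8000, "maxfev": 8000})
    if not math.isfinite(res.fun) or res.fun >= 1e12:
        raise ConvergenceError("pooled indicator-variable fit failed",
                               details={"x": res.x})

    a1, h1, da, dh = res.x
    # step scales chosen symmetric under group swap so the Wald SEs (and
    # hence p-values) are invariant to the order of the two groups
    a_scale = max(1.0, abs(a1), abs(a1 + da))
    h_scale = max(abs(h1), abs(h1 + dh), 1e-3)
    scales = np.array([a_scale, h_scale, a_scale, h_scale])
    H = _numeric_hessian(nll, res.x, step=3e-4, scales=scales)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se_da = math.sqrt(abs(cov[2, 2]))
    se_dh = math.sqrt(abs(cov[3, 3]))
    z_da = da / se_da if se_da > 0 else math.inf
    z_dh = dh / se_dh if se_dh > 0 else math.inf

    dur = trials_1[0].duration_h
    baseline = FRFit(
        params=FRParams(a1, max(h1, 0.0), dur),
        se_a=math.sqrt(abs(cov[0, 0])), se_h=math.sqrt(abs(cov[1, 1])),
        z_a=math.nan, z_h=math.nan, p_a=math.nan, p_h=math.nan,
        log_likelihood=-res.fun, converged=True, boundary_h=h1 <= 1e-8,
        n_trials=len(trials_1) + len(trials_2), n_iter=res.nit,
        init=fit1.params, cov_log=((np.nan,) * 2,) * 2,
    )
    return ComparisonResult(
        delta_a=da, delta_h=dh, se_delta_a=se_da, se_delta_h=se_dh,
        z_delta_a=z_da, z_delta_h=z_dh,
        p_delta_a=2 * stats.norm.sf(abs(z_da)),
        p_delta_h=2 * stats.norm.sf(abs(z_dh)),
        baseline=baseline, label_1=label_1, label_2=label_2,
        log_likelihood=-res.fun, design_overlap=overlap,
    )


def pairwise_compare(
    groups: dict[str, Sequence[Trial]],
    alpha: float = 0.05,
    alphabet: str = "abcdefghijklmnopqrstuvwxyz",
) -> dict:
    """All pairwise Juliano comparisons across >2 groups.

    Returns raw and Holm-adjusted p-values for Δa and Δh plus compact
    letter displays (built from the Holm-adjusted values).
    """
    labels = list(groups)
    pairs = [(labels[i], labels[j]) for i in range(len(labels))
             for j in range(i + 1, len(labels))]
    results = {p: juliano_compare(groups[p[0]], groups[p[1]], *p) for p in pairs}
    out: dict = {"pairs": {}}
    for param in ("a", "h"):
        raw = [getattr(results[p], f"p_delta_{param}") for p in pairs]
        adj = list(multipletests(raw, method="holm")[1]) if pairs else []
        pmap = dict(zip(pairs, adj))
        out[f"letters_{param}"] = compact_letters(labels, pmap, alpha, alphabet)
        for p, r, a_ in zip(pairs, raw, adj):
            key = f"{p[0]} vs {p[1]}"
            out["pairs"].setdefault(key, results[p].to_dict())
            out["pairs"][key][f"p_delta_{param}_holm"] = a_
    return out


def bootstrap_fr(
    trials: Sequence[Trial],
    n_boot: int = 2000,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    keep_draws: bool = False,
    max_failure_frac: float = 0.2,
) -> BootstrapBand:
    """Non-parametric bootstrap band around the fitted FR curve.

    Whole trials are the resampling unit.  Replicate refits are
    warm-started from the full-data fit; replicates whose refit raises
    are dropped and counted (seed-determinism is preserved because no
    replacement draws are made).
    """
    trials = list(trials)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = fit_rogers(trials)
    if grid is None:
        grid = sorted({t.n_initial for t in trials})
    grid_arr = np.asarray(list(grid), dtype=float)

    rng = np.random.default_rng(seed)
    n = len(trials)
    idx = rng.integers(0, n, size=(n_boot, n))

    curves = np.full((n_boot, grid_arr.size), np.nan)
    draws = np.full((n_boot, 2), np.nan)
    n_failed = 0
    for b in range(n_boot):
        sample = [trials[i] for i in idx[b]]
        try:
            fit = fit_rogers(sample, init=base.params)
        except FRFitError:
            n_failed += 1
            continue
        draws[b] = (fit.params.a, fit.params.h)
        curves[b] = rogers_expected(grid_arr, fit.params)

    if n_failed > max_failure_frac * n_boot:
        raise BootstrapInstabilityError(
            f"{n_failed}/{n_boot} bootstrap refits failed "
            f"(> {max_failure_frac:.0%} allowed)", n_failed, n_boot)

    ok = ~np.isnan(curves[:, 0])
    lower = np.percentile(curves[ok], 2.5, axis=0)
    upper = np.percentile(curves[ok], 97.5, axis=0)
    mean = curves[ok].mean(axis=0)
    point = np.atleast_1d(rogers_expected(grid_arr, base.params))
    return BootstrapBand(
        grid=tuple(grid_arr), mean_curve=tuple(mean), point_curve=tuple(point),
        lower95=tuple(lower), upper95=tuple(upper),
        n_boot=n_boot, n_failed=n_failed, seed=seed,
        draws=tuple(map(tuple, draws[ok])) if keep_draws else (),
    )


def overlap_verdict(band_1: BootstrapBand, band_2: BootstrapBand) -> dict:
    """Per-density overlap of two 95% envelopes on a shared grid, plus
    the fraction of grid points where the envelopes separate."""
    if tuple(band_1.grid) != tuple(band_2.grid):
        raise ValueError("bands are on different density grids")
    flags = []
    for l1, u1, l2, u2 in zip(band_1.lower95, band_1.upper95,
                              band_2.lower95, band_2.upper95):
        flags.append(bool(max(l1, l2) <= min(u1, u2)))
    frac_sep = 1.0 - sum(flags) / len(flags)
    return {"grid": list(band_1.grid), "overlaps": flags,
            "fraction_non_overlapping": frac_sep}
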