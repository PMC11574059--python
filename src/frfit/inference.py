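"""FR type determination and maximum-likelihood fitting of the Rogers model.

The analysis follows the standard two-stage approach for no-replacement
feeding trials:

1. *Type determination.*  A binomial logistic regression of the
   proportion eaten on prey density: a significantly negative
   first-order coefficient indicates a Type-II (decelerating) response,
   a significantly positive one a Type-III (sigmoidal) response.

2. *Fitting.*  The Rogers random-predator equation is fitted by
   maximising the binomial likelihood of the eaten counts,

       L(a, h) = prod_i Binom(Ne_i | N0_i, p_i),   p_i = Ne_hat(N0_i; a, h, T_i) / N0_i,

   over (a, h) on a log scale (positivity enforced by construction),
   with a deterministic multi-start grid to avoid the a–h likelihood
   ridge.  Standard errors come from the inverse observed information at
   the optimum, transformed back to the natural scale by the delta
   method; Wald Z statistics and two-sided normal p-values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

from .core import FRParams, rogers_expected
from .errors import ConvergenceError, DegenerateDataError
from .trials import Trial

__all__ = [
    "TypeTestResult", "FRFit", "classify_fr_type", "fit_rogers",
    "summarize_fit", "binomial_loglik",
]

_H_BOUNDARY = 1e-8  # below this, handling time is treated as a boundary fit
_P_EPS = 1e-12


@dataclass(frozen=True)
class TypeTestResult:
    """Outcome of the logistic type-determination regression."""

    first_order_coef: float
    p_value: float
    inferred_type: str  # "TypeII" | "TypeIII" | "ambiguous"
    degree: int
    alpha: float
    coefficients: tuple = ()


@dataclass(frozen=True)
class FRFit:
    """A fitted Rogers Type-II functional response."""

    params: FRParams
    se_a: float
    se_h: float
    z_a: float
    z_h: float
    p_a: float
    p_h: float
    log_likelihood: float
    converged: bool
    boundary_h: bool
    n_trials: int
    n_iter: int
    init: FRParams
    cov_log: tuple = field(default=(), repr=False)  # 2x2 covariance of (log a, log h)

    def wald_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Wald confidence intervals for a and h, built on the log scale
        (where the sampling distribution is closer to normal) and
        back-transformed; always positive."""
        z = stats.norm.ppf(0.5 + level / 2)
        c = np.asarray(self.cov_log, dtype=float).reshape(2, 2)
        la, lh = math.log(self.params.a), math.log(max(self.params.h, _H_BOUNDARY))
        sa, sh = math.sqrt(max(c[0, 0], 0.0)), math.sqrt(max(c[1, 1], 0.0))
        return {
            "a": (math.exp(la - z * sa), math.exp(la + z * sa)),
            "h": (math.exp(lh - z * sh), math.exp(lh + z * sh)),
        }


def _design_arrays(trials: Sequence[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n0 = np.array([t.n_initial for t in trials], dtype=float)
    ne = np.array([t.n_eaten for t in trials], dtype=float)
    T = np.array([t.duration_h for t in trials], dtype=float)
    return n0, ne, T


def binomial_loglik(trials: Sequence[Trial], params: FRParams) -> float:
    """Binomial log-likelihood of the eaten counts under the Rogers model.

    Each trial contributes ``log C(N0, Ne) + Ne log p + (N0-Ne) log(1-p)``
    with ``p`` the model-predicted proportion eaten.  Success probability
    is strictly inside (0, 1) for a, h > 0, so complete-depletion trials
    remain informative.
    """
    n0, ne, T = _design_arrays(trials)
    durations = np.unique(T)
    total = 0.0
    for d in durations:
        m = T == d
        p = FRParams(params.a, params.h, float(d))
        pred = np.atleast_1d(rogers_expected(n0[m], p))
        prob = np.clip(pred / n0[m], _P_EPS, 1.0 - _P_EPS)
        total += float(np.sum(stats.binom.logpmf(ne[m], n0[m], prob)))
    return total


def _nll_factory(trials: Sequence[Trial]):
    # The model probability depends only on (duration, density), so the
    # likelihood collapses onto unique design cells — one Lambert-W
    # evaluation per cell per call, not per trial.
    n0, ne, T = _design_arrays(trials)
    const = float(np.sum(gammaln(n0 + 1) - gammaln(ne + 1) - gammaln(n0 - ne + 1)))
    key = np.stack([T, n0], axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    s_eaten = np.bincount(inv, weights=ne)
    s_missed = np.bincount(inv, weights=n0 - ne)
    u_T, u_n0 = uniq[:, 0], uniq[:, 1]
    durations = [(float(d), u_T == d) for d in np.unique(u_T)]

    def nll(theta: np.ndarray) -> float:
        a = math.exp(min(theta[0], 50.0))
        h = math.exp(min(theta[1], 50.0))
        pred = np.empty_like(u_n0)
        try:
            for d, m in durations:
                pred[m] = np.atleast_1d(rogers_expected(u_n0[m], FRParams(a, h, d)))
        except (OverflowError, FloatingPointError):
            return 1e12
        prob = np.clip(pred / u_n0, _P_EPS, 1.0 - _P_EPS)
        ll = const + float(np.sum(s_eaten * np.log(prob)
                                  + s_missed * np.log1p(-prob)))
        return -ll if math.isfinite(ll) else 1e12

    return nll


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4,
                     scales: np.ndarray | None = None) -> np.ndarray:
    """Central-difference Hessian; adequate for the smooth 2–4 parameter
    likelihoods used here.  ``scales`` overrides the default per-parameter
    magnitude ``max(1, |x_i|)``."""
    k = len(x)
    H = np.empty((k, k))
    if scales is None:
        scales = np.maximum(1.0, np.abs(x))
    hs = step * scales
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _start_grid(trials: Sequence[Trial]) -> list[tuple[float, float]]:
    n0, ne, T = _design_arrays(trials)
    h_cands = {1.0 / float(n0.max()), 0.1}
    if ne.max() > 0:
        # asymptote heuristic: max observed eaten ~ T/h
        h_cands.add(float(np.median(T)) / float(ne.max()))
    return [(a0, h0) for a0 in (0.1, 1.0, 10.0) for h0 in sorted(h_cands)]


def fit_rogers(
    trials: Sequence[Trial],
    init: FRParams | None = None,
    include_depleted: bool = True,
) -> FRFit:
    """Fit the Rogers random-predator model by binomial MLE.

    Parameters
    ----------
    trials : sequence of Trial
        Feeding trials from a single experimental group.
    init : FRParams, optional
        Warm start.  When given, only this start (plus one fallback) is
        used — the fast path for bootstrap refits; otherwise a
        deterministic multi-start grid is searched.
    include_depleted : bool
        Keep trials where all prey were eaten (default).  Set False for a
        sensitivity analysis excluding ceiling-censored trials.

    Raises
    ------
    DegenerateDataError
        Fewer than two distinct densities, no feeding at all, or complete
        depletion in every trial (h is then unidentifiable near 0).
    ConvergenceError
        Optimizer failure from every start.
    """
    trials = list(trials)
    if not include_depleted:
        trials = [t for t in trials if t.n_eaten < t.n_initial]
    if not trials:
        raise DegenerateDataError("no trials to fit")
    n0, ne, T = _design_arrays(trials)
    if len(np.unique(n0)) < 2:
        raise DegenerateDataError(
            "attack rate and handling time are not jointly identifiable "
            f"from a single prey density (N0 = {n0[0]:g} everywhere)"
        )
    if ne.max() == 0:
        raise DegenerateDataError("no prey were eaten in any trial; attack rate "
                                  "is indistinguishable from zero")
    if np.all(ne == n0):
        raise DegenerateDataError("all prey eaten in every trial; handling time "
                                  "is unidentifiable (boundary at h = 0)")

    nll = _nll_factory(trials)
    if init is not None:
        starts = [(init.a, max(init.h, _H_BOUNDARY)), (1.0, 0.1)]
    else:
        starts = _start_grid(trials)

    best = None
    total_iter = 0
    for a0, h0 in starts:
        theta0 = np.array([math.log(a0), math.log(h0)])
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-8,
                                         "maxiter": 2000})
        total_iter += res.nit
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if init is not None and res.success:
            break
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError("Rogers MLE failed from every start",
                               details={"best": None if best is None else best.x})

    theta = best.x
    a_hat, h_hat = math.exp(theta[0]), math.exp(theta[1])
    boundary = h_hat <= _H_BOUNDARY
    ll = -best.fun

    H = _numeric_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
        ok = np.all(np.diag(cov) > 0)
    except np.linalg.LinAlgError:
        cov, ok = np.full((2, 2), np.nan), False
    if not ok:
        cov = np.linalg.pinv(H)
        ok = np.all(np.diag(cov) > 0)

    if ok and not boundary:
        se_a = a_hat * math.sqrt(cov[0, 0])
        se_h = h_hat * math.sqrt(cov[1, 1])
        z_a = a_hat / se_a if se_a > 0 else math.inf
        z_h = h_hat / se_h if se_h > 0 else math.inf
        p_a = 2 * stats.norm.sf(abs(z_a))
        p_h = 2 * stats.norm.sf(abs(z_h))
    elif ok:  # boundary in h: a-side inference still meaningful
        se_a = a_hat * math.sqrt(cov[0, 0])
        z_a = a_hat / se_a if se_a > 0 else math.inf
        p_a = 2 * stats.norm.sf(abs(z_a))
        se_h = z_h = p_h = math.nan
    else:
        se_a = se_h = z_a = z_h = p_a = p_h = math.nan

    dur = float(T[0]) if len(np.unique(T)) == 1 else float(np.mean(T))
    return FRFit(
        params=FRParams(a_hat, h_hat, dur),
        se_a=se_a, se_h=se_h, z_a=z_a, z_h=z_h, p_a=p_a, p_h=p_h,
        log_likelihood=ll,
        converged=bool(ok and (best.success or best.fun < 1e12)),
        boundary_h=boundary,
        n_trials=len(trials),
        n_iter=total_iter,
        init=FRParams(*starts[0], dur),
        cov_log=tuple(map(tuple, cov)),
    )


def classify_fr_type(
    trials: Sequence[Trial],
    degree: int = 1,
    alpha: float = 0.05,
) -> TypeTestResult:
    """Determine FR type from the sign of the first-order density term.

    Fits a binomial GLM (logit link) of eaten-out-of-offered on a
    polynomial in initial density of the given degree (default 1).  The
    response is Type II if the first-order coefficient is negative and
    significant at ``alpha``, Type III if positive and significant, and
    ambiguous otherwise.
    """
    trials = list(trials)
    n0, ne, _ = _design_arrays(trials)
    if len(np.unique(n0)) < 2:
        raise DegenerateDataError("type test needs at least two distinct densities")
    if np.all(ne == n0) or np.all(ne == 0):
        grp = trials[0].group
        raise DegenerateDataError(
            f"complete separation in group {grp}: prey were "
            f"{'always' if ne.max() > 0 else 'never'} fully eaten"
        )
    if degree < 1:
        raise ValueError("polynomial degree must be >= 1")

    X = np.column_stack([n0 ** d for d in range(degree + 1)])
    endog = np.column_stack([ne, n0 - ne])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    fit = model.fit()
    coef1 = float(fit.params[1])
    p1 = float(fit.pvalues[1])

    if p1 < alpha and coef1 < 0:
        inferred = "TypeII"
    elif p1 < alpha and coef1 > 0:
        inferred = "TypeIII"
    else:
        inferred = "ambiguous"
    return TypeTestResult(
        first_order_coef=coef1, p_value=p1, inferred_type=inferred,
        degree=degree, alpha=alpha, coefficients=tuple(map(float, fit.params)),
    )


def summarize_fit(fit: FRFit) -> dict:
    """Serializable one-row summary: a, h, their p-values and the maximum
    feeding rate 1/(hT) (None when h sits on the zero boundary)."""
    if not fit.converged:
        raise ConvergenceError("cannot summarize a non-converged fit")
    mfr = None if fit.boundary_h else 1.0 / (fit.params.h * fit.params.T)
    return {
        "a": fit.params.a,
        "se_a": fit.se_a,
        "z_a": fit.z_a,
        "p_a": fit.p_a,
        "h": fit.params.h,
        "se_h": fit.se_h,
        "z_h": fit.z_h,
        "p_h": fit.p_h,
        "max_feeding_rate": mfr,
        "log_likelihood": fit.log_likelihood,
        "n_trials": fit.n_trials,
        "boundary_h": fit.boundary_h,
    }
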