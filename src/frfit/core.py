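"""Deterministic functional-response mathematics.

Two Type-II consumption models are provided:

* the Holling disc equation, which assumes prey density stays constant
  during a trial (prey are replaced as they are eaten), and
* the Rogers random-predator equation, which corrects for prey depletion
  when eaten prey are *not* replaced — the situation in typical 1-hour
  feeding trials.

The Rogers model is implicit in the number eaten,

    Ne = N0 * (1 - exp(a * (Ne * h - T))),

and is solved here in closed form with the principal branch of the
Lambert W function,

    Ne = N0 - W0(a * h * N0 * exp(-a * (T - h * N0))) / (a * h),

falling back to a bracketing root-finder when the W argument would
overflow.  W0 is the ecologically meaningful branch: it is the unique
root in [0, N0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

from .errors import ConvergenceError, ParameterDomainError

__all__ = ["FRParams", "holling_expected", "rogers_expected", "max_feeding_rate"]

# log of the Lambert-W argument above which we abandon the closed form
# and bisect the implicit equation instead (exp() overflows near 709).
_LOG_ARG_OVERFLOW = 700.0


@dataclass(frozen=True)
class FRParams:
    """Type-II functional-response parameters.

    Attributes
    ----------
    attack_rate : float
        Instantaneous search efficiency ``a`` (per unit search time, per
        arena).  Counts are per fixed arena, so ``a`` is arena-specific.
    handling_time : float
        Time ``h`` to capture, consume and digest one prey item, in the
        same time units as ``duration``.
    duration : float
        Trial duration ``T`` (hours by convention; default 1).
    """

    attack_rate: float
    handling_time: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        a, h, T = self.attack_rate, self.handling_time, self.duration
        for name, v in (("attack_rate", a), ("handling_time", h), ("duration", T)):
            if not math.isfinite(v):
                raise ParameterDomainError(f"{name} must be finite, got {v!r}")
        if a < 0:
            raise ParameterDomainError(f"attack_rate must be >= 0, got {a}")
        if h < 0:
            raise ParameterDomainError(f"handling_time must be >= 0, got {h}")
        if T <= 0:
            raise ParameterDomainError(f"duration must be > 0, got {T}")

    @property
    def a(self) -> float:
        return self.attack_rate

    @property
    def h(self) -> float:
        return self.handling_time

    @property
    def T(self) -> float:
        return self.duration


def holling_expected(n_density, params: FRParams):
    """Expected number eaten under the Holling disc equation (replacement).

    ``Ne = a*N*T / (1 + a*h*N)`` at constant prey density ``N``.  Because
    prey are assumed replaced, the result is not bounded by ``N``.

    Accepts a scalar or array density; returns the same shape.
    """
    n = np.asarray(n_density, dtype=float)
    if np.any(n < 0):
        raise ParameterDomainError("prey density must be >= 0")
    a, h, T = params.a, params.h, params.T
    out = a * n * T / (1.0 + a * h * n)
    return out if out.shape else float(out)


def _rogers_residual(ne: float, n0: float, a: float, h: float, T: float) -> float:
    # clamp the exponent: beyond ~700 exp() overflows a double, and the
    # residual is unambiguously positive there anyway
    x = min(a * (ne * h - T), 700.0)
    return ne - n0 * (1.0 - math.exp(x))


def _rogers_bracket(n0: float, a: float, h: float, T: float) -> float:
    """Solve the implicit equation by Brent bracketing on [0, N0]."""
    try:
        return brentq(_rogers_residual, 0.0, n0, args=(n0, a, h, T),
                      xtol=1e-12, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - brentq is robust on this bracket
        raise ConvergenceError(
            f"root bracketing failed for N0={n0}, a={a}, h={h}, T={T}",
            details={"residual_at_mid": _rogers_residual(n0 / 2, n0, a, h, T)},
        ) from exc


def _rogers_scalar(n0: float, a: float, h: float, T: float) -> float:
    if n0 == 0.0 or a == 0.0:
        return 0.0
    if h == 0.0:
        # no handling: pure exponential depletion over the trial
        return n0 * (1.0 - math.exp(-a * T))
    log_arg = math.log(a * h * n0) - a * (T - h * n0)
    if log_arg > _LOG_ARG_OVERFLOW:
        return _rogers_bracket(n0, a, h, T)
    w = lambertw(math.exp(log_arg), k=0).real
    ne = n0 - w / (a * h)
    # clamp tiny negative round-off; re-solve if meaningfully off-bracket
    if ne < 0.0:
        if ne > -1e-9:
            return 0.0
        return _rogers_bracket(n0, a, h, T)
    return min(ne, n0)


def rogers_expected(n_initial, params: FRParams):
    """Expected number eaten under the Rogers random-predator equation.

    Solves ``Ne = N0 * (1 - exp(a * (Ne*h - T)))`` for the unique root in
    ``[0, N0)`` via the Lambert-W closed form (principal branch), with a
    bracketing fallback that keeps the evaluation stable for large
    ``a*h*N0``.  ``N0`` may be non-integer so likelihood gradients are
    smooth.

    Accepts a scalar or array ``n_initial``; returns the same shape.
    """
    n0 = np.asarray(n_initial, dtype=float)
    if np.any(n0 < 0):
        raise ParameterDomainError("initial prey count must be >= 0")
    a, h, T = params.a, params.h, params.T

    if n0.shape == ():
        return _rogers_scalar(float(n0), a, h, T)

    out = np.zeros_like(n0)
    if a == 0.0:
        return out
    if h == 0.0:
        return n0 * (1.0 - math.exp(-a * T))

    nz = n0 > 0
    n = n0[nz]
    log_arg = np.log(a * h * n) - a * (T - h * n)
    safe = log_arg <= _LOG_ARG_OVERFLOW
    ne = np.empty_like(n)
    if np.any(safe):
        w = lambertw(np.exp(log_arg[safe]), k=0).real
        ne[safe] = n[safe] - w / (a * h)
    for i in np.flatnonzero(~safe):
        ne[i] = _rogers_bracket(float(n[i]), a, h, T)
    np.clip(ne, 0.0, n, out=ne)
    out[nz] = ne
    return out


def max_feeding_rate(params: FRParams) -> float:
    """Maximum feeding rate ``1/(h*T)``: the Type-II asymptote in prey per
    trial duration.

    Raises
    ------
    ParameterDomainError
        If ``h == 0`` (the asymptote is undefined rather than silently
        infinite).
    """
    if params.h == 0.0:
        raise ParameterDomainError(
            "maximum feeding rate 1/(h*T) is undefined for handling_time = 0"
        )
    return 1.0 / (params.h * params.T)
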