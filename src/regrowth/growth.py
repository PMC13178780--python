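"""Tumor growth laws and viability-threshold regrowth dynamics.

The state variable is the viable tumor burden ``B`` (cc).  An intrinsic
growth law ``f(V)`` — exponential, logistic, or Gompertz — is modulated by
an Allee-type minimum-viability factor so that the net dynamics are

    dB/dt = f(B) * (B/eps_V - 1)

Burdens below the viability threshold ``eps_V`` decay deterministically to
zero (cure); burdens above it regrow until they cross the clinical
detection threshold ``omega_d`` (recurrence).  With the exponential law the
net equation is a Bernoulli ODE with an exact solution, used throughout as
the oracle for the numerical path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, DomainError, IntegrationError

__all__ = [
    "GrowthLaw",
    "GrowthLawParams",
    "RegrowthModel",
    "Trajectory",
    "growth_rate",
    "net_rate",
    "simulate_trajectory",
    "exponential_burden_at",
    "exponential_blowup_time",
    "exponential_recurrence_time",
]

# Floor for the Gompertz log argument; no trajectory needs values below this
# before being classified cured, it only guards against overflow at B -> 0.
_GOMPERTZ_FLOOR = 1e-30

# Integration ceiling for the exponential law (which blows up in finite
# time above eps_V); bounded laws use 10*K instead.
_EXPONENTIAL_CEILING = 1e4

# Solver tolerances: recurrence times must be grid-independent, so the
# integration is run tight and threshold crossings use event detection.
_RTOL = 1e-8
_ATOL = 1e-12


class GrowthLaw(str, Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"


@dataclass(frozen=True)
class GrowthLawParams:
    """Intrinsic (untreated) growth law ``f(V)``.

    Parameters
    ----------
    law : GrowthLaw
        Functional form: exponential ``lam*V``, logistic ``lam*V*(1-V/K)``,
        or Gompertz ``lam*V*ln(K/V)``.
    lambda_ : float
        Intrinsic growth rate, per day, > 0.
    K : float, optional
        Carrying capacity, cc; required (and > 0) for logistic and
        Gompertz, ignored for exponential.
    """

    law: GrowthLaw
    lambda_: float
    K: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "law", GrowthLaw(self.law))
        if not (self.lambda_ > 0 and math.isfinite(self.lambda_)):
            raise ConfigurationError(f"lambda_ must be finite and > 0, got {self.lambda_}")
        if self.law is not GrowthLaw.EXPONENTIAL:
            if self.K is None or not (self.K > 0 and math.isfinite(self.K)):
                raise ConfigurationError(
                    f"{self.law.value} growth requires a finite carrying capacity K > 0, got {self.K}"
                )


@dataclass(frozen=True)
class RegrowthModel:
    """One patient's regrowth dynamics: growth law plus thresholds.

    ``viability_term_enabled=False`` drops the Allee factor and integrates
    the plain growth law, in which case every positive burden eventually
    becomes detectable.
    """

    growth: GrowthLawParams
    eps_V: float
    omega_d: float
    viability_term_enabled: bool = True

    def __post_init__(self):
        if not (0 <= self.eps_V < self.omega_d):
            raise ConfigurationError(
                f"thresholds must satisfy 0 <= eps_V < omega_d, got eps_V={self.eps_V}, omega_d={self.omega_d}"
            )
        if not math.isfinite(self.omega_d):
            raise ConfigurationError("omega_d must be finite")
        if self.growth.law is not GrowthLaw.EXPONENTIAL and self.omega_d >= self.growth.K:
            raise ConfigurationError(
                f"omega_d={self.omega_d} must lie below the carrying capacity K={self.growth.K}"
            )

    def with_growth(self, **kwargs) -> "RegrowthModel":
        """Return a copy with replaced growth-law parameters."""
        g = self.growth
        params = {"law": g.law, "lambda_": g.lambda_, "K": g.K}
        params.update(kwargs)
        return RegrowthModel(
            growth=GrowthLawParams(**params),
            eps_V=self.eps_V,
            omega_d=self.omega_d,
            viability_term_enabled=self.viability_term_enabled,
        )

    def replace(self, **kwargs) -> "RegrowthModel":
        """Return a copy with replaced threshold/flag fields."""
        params = {
            "growth": self.growth,
            "eps_V": self.eps_V,
            "omega_d": self.omega_d,
            "viability_term_enabled": self.viability_term_enabled,
        }
        params.update(kwargs)
        return RegrowthModel(**params)


@dataclass
class Trajectory:
    """A simulated burden time course ``B(t)``.

    ``truncated`` is set when integration was halted at the blow-up
    ceiling; the final stored point is the terminal state at the ceiling.
    """

    times: np.ndarray
    burdens: np.ndarray
    truncated: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.burdens = np.asarray(self.burdens, dtype=float)
        if self.times.shape != self.burdens.shape:
            raise DomainError("times and burdens must have equal length")
        if self.times.size and self.times[0] != 0.0:
            raise DomainError("trajectory must start at t=0")
        if not np.all(np.isfinite(self.burdens)):
            raise DomainError("trajectory burdens must be finite")


def growth_rate(params: GrowthLawParams, V):
    """Evaluate the intrinsic growth law ``f(V)`` (cc/day).

    Accepts a scalar or array of volumes; ``V = 0`` maps to exactly 0 for
    every law (extinction fixed point, the continuous Gompertz limit).
    Negative volumes are a domain error; Gompertz with ``V > K`` is allowed
    and yields a negative rate.
    """
    V_arr = np.asarray(V, dtype=float)
    if np.any(V_arr < 0):
        raise DomainError("volume must be >= 0")
    lam = params.lambda_
    if params.law is GrowthLaw.EXPONENTIAL:
        out = lam * V_arr
    elif params.law is GrowthLaw.LOGISTIC:
        out = lam * V_arr * (1.0 - V_arr / params.K)
    else:  # Gompertz: lam*V*ln(K/V), continuous limit 0 at V=0
        safe_V = np.maximum(V_arr, _GOMPERTZ_FLOOR)
        out = np.where(V_arr == 0.0, 0.0, lam * V_arr * np.log(params.K / safe_V))
    return out if isinstance(V, np.ndarray) else float(out)


def net_rate(model: RegrowthModel, B):
    """Net burden derivative dB/dt at burden ``B``.

    With the viability term on this is ``f(B)*(B/eps_V - 1)``: negative for
    0 < B < eps_V, zero at B in {0, eps_V}, positive above eps_V.  With the
    term off it is the plain growth law.
    """
    if not model.viability_term_enabled:
        return growth_rate(model.growth, B)
    if model.eps_V == 0:
        raise ConfigurationError(
            "eps_V = 0 makes the viability factor (B/eps_V - 1) undefined; "
            "disable the viability term instead (the eps_V -> 0 limit is plain growth)"
        )
    f = growth_rate(model.growth, B)
    factor = np.asarray(B, dtype=float) / model.eps_V - 1.0
    out = f * factor
    return out if isinstance(B, np.ndarray) else float(out)


def _ceiling(model: RegrowthModel) -> float:
    if model.growth.law is GrowthLaw.EXPONENTIAL:
        return _EXPONENTIAL_CEILING
    return 10.0 * model.growth.K


def simulate_trajectory(model: RegrowthModel, B0: float, t_grid) -> Trajectory:
    """Integrate the net dynamics from ``B0`` over ``t_grid`` (days).

    Adaptive Runge-Kutta (RK45, rtol 1e-8, atol 1e-12 cc).  If the burden
    reaches the blow-up ceiling — the exponential-law dynamics diverge in
    finite time above ``eps_V`` — the trajectory is truncated there and
    flagged, with the terminal ceiling point appended.
    """
    if not (np.isfinite(B0) and B0 > 0):
        raise DomainError(f"B0 must be finite and > 0, got {B0}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must start at 0 and be strictly increasing")

    ceiling = _ceiling(model)

    def rhs(t, y):
        return [net_rate(model, max(y[0], 0.0))]

    def hit_ceiling(t, y):
        return y[0] - ceiling

    hit_ceiling.terminal = True
    hit_ceiling.direction = 1

    sol = solve_ivp(
        rhs,
        (0.0, t_grid[-1]),
        [B0],
        t_eval=t_grid,
        events=hit_ceiling,
        method="RK45",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if sol.status == -1:
        last_t = sol.t[-1] if sol.t.size else None
        last_b = sol.y[0, -1] if sol.t.size else None
        raise IntegrationError(sol.message, last_time=last_t, last_burden=last_b)

    times = sol.t
    burdens = np.clip(sol.y[0], 0.0, None)
    truncated = sol.status == 1
    if truncated and sol.t_events[0].size:
        t_ev = sol.t_events[0][0]
        if times.size == 0 or t_ev > times[-1]:
            times = np.append(times, t_ev)
            burdens = np.append(burdens, ceiling)
    if times.size == 0 or times[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        burdens = np.insert(burdens, 0, B0)
    return Trajectory(times=times, burdens=burdens, truncated=truncated)


def exponential_blowup_time(B0: float, lambda_: float, eps_V: float) -> float:
    """Finite blow-up time of the exponential-law net dynamics for B0 > eps_V."""
    if B0 <= eps_V:
        return math.inf
    return (1.0 / lambda_) * math.log((1.0 / eps_V) / (1.0 / eps_V - 1.0 / B0))


def exponential_burden_at(B0: float, lambda_: float, eps_V: float, t) -> float | np.ndarray:
    """Exact Bernoulli solution of ``dB/dt = lambda*B*(B/eps_V - 1)``.

    Returns ``1 / [1/eps_V + (1/B0 - 1/eps_V) * exp(lambda*t)]``, valid for
    ``t`` below the finite blow-up time when ``B0 > eps_V``.
    """
    if not (B0 > 0 and eps_V > 0):
        raise DomainError("B0 and eps_V must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    denom = 1.0 / eps_V + (1.0 / B0 - 1.0 / eps_V) * np.exp(lambda_ * t_arr)
    if np.any(denom <= 0):
        t_star = exponential_blowup_time(B0, lambda_, eps_V)
        raise DomainError(
            f"t at or beyond the finite blow-up time {t_star:.6g} d for B0={B0}, eps_V={eps_V}"
        )
    out = 1.0 / denom
    return out if isinstance(t, np.ndarray) else float(out)


def exponential_recurrence_time(
    B0: float, lambda_: float, eps_V: float, omega_d: float
) -> float | None:
    """Closed-form time at which an exponential-law patient crosses omega_d.

    Returns 0 for already-detectable burdens (B0 >= omega_d), ``None`` for
    cured patients (B0 <= eps_V), and otherwise the strictly positive,
    finite crossing time of the Bernoulli solution.
    """
    if not (B0 > 0):
        raise DomainError(f"B0 must be > 0, got {B0}")
    if not (0 < eps_V < omega_d):
        raise DomainError("thresholds must satisfy 0 < eps_V < omega_d")
    if B0 >= omega_d:
        return 0.0
    if B0 <= eps_V:
        return None
    return (1.0 / lambda_) * math.log(
        (1.0 / eps_V - 1.0 / omega_d) / (1.0 / eps_V - 1.0 / B0)
    )
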