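"""Calibration of (lambda, omega_d, eps_V) to observed event-free curves.

The forward model maps a fixed burden distribution through the regrowth
dynamics to a replicate-averaged event-free curve; calibration minimizes
the unweighted least-squares distance between that mean curve and the
observed event-free fractions at their time points, summed across arms
that share global parameters.

Because the burden samples do not depend on the fitted parameters, all
replicate cohorts are drawn once up front and reused for every candidate
(common random numbers): the loss surface is exactly deterministic under a
fixed seed.  Minimization is derivative-free (Nelder-Mead) in a transformed
space — (ln lambda, ln omega_d, logit(eps_V/omega_d)) — which enforces
positivity and the ordering eps_V < omega_d by construction.  The
exponential growth law is used, for which recurrence times are closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohort import BurdenDistribution, sample_burdens
from .errors import ConfigurationError, DomainError
from .survival import RecurrenceCurve, default_grid

__all__ = [
    "ObservedCurve",
    "CalibrationSettings",
    "CalibrationResult",
    "curve_loss",
    "mean_survival_at",
    "fit_parameters",
]


@dataclass
class ObservedCurve:
    """An observed event-free (e.g. locoregional-control) curve."""

    times: np.ndarray
    event_free_fraction: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.event_free_fraction = np.asarray(self.event_free_fraction, dtype=float)
        if self.times.size < 3:
            raise DomainError("observed curve needs at least 3 points")
        if self.times.shape != self.event_free_fraction.shape:
            raise DomainError("times and fractions must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be >= 0 and strictly increasing")
        f = self.event_free_fraction
        if np.any((f < 0) | (f > 1)) or np.any(np.diff(f) > 0):
            raise DomainError("event-free fractions must be nonincreasing within [0, 1]")


@dataclass(frozen=True)
class CalibrationSettings:
    """Optimizer and replication configuration.

    ``n_reps`` replicate cohorts of ``n_per_arm`` patients are averaged for
    each loss evaluation; 100 replicates of 265 patients mirror the trial
    scale the model was built around.
    """

    n_per_arm: int = 265
    n_reps: int = 100
    max_iter: int = 500
    loss_tol: float = 1e-6


@dataclass
class CalibrationResult:
    lambda_: float
    omega_d: float
    eps_V: float
    loss: float
    n_reps: int
    converged: bool
    n_iterations: int
    mean_curves: list[RecurrenceCurve] = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.eps_V < self.omega_d):
            raise ConfigurationError("fitted parameters must satisfy 0 < eps_V < omega_d")


def curve_loss(simulated: RecurrenceCurve, observed: ObservedCurve) -> float:
    """Sum of squared differences at the observed time points.

    The simulated mean survival is linearly interpolated to the observed
    times; an observed time beyond the simulation grid is a domain error.
    """
    if observed.times[-1] > simulated.t_grid[-1]:
        raise DomainError(
            f"observed time {observed.times[-1]} exceeds simulation horizon {simulated.t_grid[-1]}"
        )
    sim = np.interp(observed.times, simulated.t_grid, simulated.survival)
    return float(np.sum((sim - observed.event_free_fraction) ** 2))


def mean_survival_at(
    burdens: np.ndarray, lambda_: float, omega_d: float, eps_V: float, times: np.ndarray
) -> np.ndarray:
    """Replicate-mean event-free fraction at ``times``, closed form.

    ``burdens`` has shape (n_reps, n_patients).  Cures map to an infinite
    recurrence time; detectable burdens to zero.
    """
    t_R = np.full(burdens.shape, np.inf)
    detect = burdens >= omega_d
    t_R[detect] = 0.0
    prog = (burdens > eps_V) & ~detect
    t_R[prog] = (1.0 / lambda_) * np.log(
        (1.0 / eps_V - 1.0 / omega_d) / (1.0 / eps_V - 1.0 / burdens[prog])
    )
    # R(t) per replicate, then mean over replicates
    recurred = t_R[:, :, None] <= times[None, None, :]
    return 1.0 - recurred.mean(axis=(0, 1))


def _pack(lambda_: float, omega_d: float, eps_V: float) -> np.ndarray:
    return np.array([math.log(lambda_), math.log(omega_d), logit(eps_V / omega_d)])


def _unpack(x: np.ndarray) -> tuple[float, float, float]:
    lam = math.exp(x[0])
    omega = math.exp(x[1])
    eps = omega * float(expit(x[2]))
    return lam, omega, eps


def fit_parameters(
    observed: list[ObservedCurve],
    dists: list[BurdenDistribution],
    init: tuple[float, float, float],
    settings: CalibrationSettings = CalibrationSettings(),
    seed: int = 0,
) -> CalibrationResult:
    """Fit global (lambda, omega_d, eps_V) to one or more observed arms.

    Parameters
    ----------
    observed, dists
        Matching lists: each observed curve is paired with the burden
        distribution of its arm; all arms share the fitted parameters.
    init
        Starting (lambda_, omega_d, eps_V), constraint-satisfying.
    """
    if len(observed) != len(dists) or not observed:
        raise ConfigurationError("each observed curve needs a matching burden distribution")
    lam0, omega0, eps0 = init
    if not (0 < eps0 < omega0 and lam0 > 0):
        raise ConfigurationError("init must satisfy lambda > 0 and 0 < eps_V < omega_d")

    # Common random numbers: one set of replicate cohorts per arm, reused
    # for every candidate parameter evaluation.
    rng = np.random.default_rng(seed)
    arm_burdens = [
        np.stack(
            [
                sample_burdens(d, settings.n_per_arm, int(s))
                for s in rng.integers(0, 2**31, size=settings.n_reps)
            ]
        )
        for d in dists
    ]

    def loss_fn(x: np.ndarray) -> float:
        lam, omega, eps = _unpack(x)
        total = 0.0
        for burdens, obs in zip(arm_burdens, observed):
            sim = mean_survival_at(burdens, lam, omega, eps, obs.times)
            total += float(np.sum((sim - obs.event_free_fraction) ** 2))
        return total

    res = minimize(
        loss_fn,
        _pack(lam0, omega0, eps0),
        method="Nelder-Mead",
        options={
            "maxiter": settings.max_iter,
            "fatol": settings.loss_tol,
            "xatol": 1e-6,
        },
    )
    lam, omega, eps = _unpack(res.x)

    horizon = max(o.times[-1] for o in observed)
    grid = default_grid(horizon=float(horizon), step=max(1.0, horizon / 2000))
    mean_curves = []
    for burdens in arm_burdens:
        surv = mean_survival_at(burdens, lam, omega, eps, grid)
        mean_curves.append(
            RecurrenceCurve(t_grid=grid, recurrence=np.maximum.accumulate(1.0 - surv),
                            n_patients=settings.n_per_arm)
        )
    return CalibrationResult(
        lambda_=lam,
        omega_d=omega,
        eps_V=eps,
        loss=float(res.fun),
        n_reps=settings.n_reps,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        mean_curves=mean_curves,
    )
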