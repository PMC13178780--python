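"""Per-patient outcome classification and recurrence times.

A patient with initial viable burden ``B0`` is classified against the two
thresholds: already detectable (``B0 >= omega_d``, recurrence at t = 0),
cured (``B0 <= eps_V``, the burden decays to zero and never recurs), or
progressing (``eps_V < B0 < omega_d``), in which case the recurrence time
is the first crossing of the detection threshold.  Exponential-law times
come from the closed form; logistic and Gompertz use ODE event detection.

The per-patient recurrence indicator R_i(t) is the right-continuous step
0 -> 1 at the recurrence time, with the crossing itself inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from . import growth as g
from .errors import DomainError, IntegrationError

__all__ = [
    "Outcome",
    "Method",
    "OutcomeRecord",
    "DEFAULT_HORIZON",
    "classify_patient",
    "patient_recurrence_time",
    "cohort_outcomes",
    "recurrence_indicator",
]

#: Default follow-up horizon: 20 years in days.
DEFAULT_HORIZON = 7300.0


class Outcome(str, Enum):
    CURE = "cure"
    PROGRESSION = "progression"
    DETECTABLE_AT_T0 = "detectable_at_t0"


class Method(str, Enum):
    CLOSED_FORM = "closed_form"
    ODE_EVENT = "ode_event"


@dataclass
class OutcomeRecord:
    """Outcome of one virtual patient.

    ``t_R`` is None for cures and for beyond-horizon progressions; the
    latter carry ``beyond_horizon=True`` so aggregation can distinguish a
    true cure (asymptote) from an event merely outside follow-up.
    """

    B0: float
    outcome: Outcome
    t_R: float | None
    method: Method
    beyond_horizon: bool = False
    K: float | None = None

    def __post_init__(self):
        if self.outcome is Outcome.CURE and self.t_R is not None:
            raise DomainError("cure implies t_R is None")
        if self.outcome is Outcome.DETECTABLE_AT_T0 and self.t_R != 0.0:
            raise DomainError("detectable_at_t0 implies t_R = 0")


def classify_patient(B0: float, eps_V: float, omega_d: float) -> Outcome:
    """Partition (0, inf) into the three outcome classes.

    Boundary tie-breaks: ``B0 = omega_d`` is detectable at t = 0 (the
    detection inequality is inclusive); ``B0 = eps_V`` is a cure — it sits
    on an unstable equilibrium below the detection threshold and never
    crosses it.
    """
    if not (B0 > 0):
        raise DomainError(f"B0 must be > 0, got {B0}")
    if not (0 <= eps_V < omega_d):
        raise DomainError("need 0 <= eps_V < omega_d")
    if B0 >= omega_d:
        return Outcome.DETECTABLE_AT_T0
    if B0 <= eps_V:
        return Outcome.CURE
    return Outcome.PROGRESSION


def recurrence_indicator(t_R: float | None, t: float) -> int:
    """R_i(t): 1 iff the patient has recurred by time ``t`` (inclusive)."""
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    return int(t_R is not None and t >= t_R)


def _ode_crossing_time(model: g.RegrowthModel, B0: float, horizon: float) -> float | None:
    """First time B(t) reaches omega_d, by event detection; None if not
    reached within the horizon."""

    def rhs(t, y):
        return [g.net_rate(model, max(y[0], 0.0))]

    def crossing(t, y):
        return y[0] - model.omega_d

    crossing.terminal = True
    crossing.direction = 1

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [B0],
        events=crossing,
        method="RK45",
        rtol=1e-8,
        atol=1e-12,
        dense_output=False,
    )
    if sol.status == -1:
        last_t = sol.t[-1] if sol.t.size else None
        last_b = sol.y[0, -1] if sol.t.size else None
        raise IntegrationError(sol.message, last_time=last_t, last_burden=last_b)
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return None


def patient_recurrence_time(
    B0: float,
    model: g.RegrowthModel,
    horizon: float = DEFAULT_HORIZON,
    K: float | None = None,
) -> OutcomeRecord:
    """Classify one patient and compute their recurrence time.

    ``K`` overrides the model's carrying capacity for patient-specific
    capacity sampling.  With the viability term disabled every patient with
    positive burden eventually recurs; an event past the horizon is flagged
    ``beyond_horizon`` rather than silently treated as a cure.
    """
    if horizon <= 0:
        raise DomainError("horizon must be > 0")
    if K is not None:
        model = model.with_growth(K=K)
    law = model.growth.law
    lam = model.growth.lambda_

    if B0 >= model.omega_d:
        return OutcomeRecord(B0, Outcome.DETECTABLE_AT_T0, 0.0, Method.CLOSED_FORM, K=K)

    if model.viability_term_enabled:
        outcome = classify_patient(B0, model.eps_V, model.omega_d)
        if outcome is Outcome.CURE:
            return OutcomeRecord(B0, outcome, None, Method.CLOSED_FORM, K=K)
        if law is g.GrowthLaw.EXPONENTIAL:
            t_R = g.exponential_recurrence_time(B0, lam, model.eps_V, model.omega_d)
            method = Method.CLOSED_FORM
        else:
            t_R = _ode_crossing_time(model, B0, horizon)
            method = Method.ODE_EVENT
    else:
        # Plain growth: monotone increase toward omega_d for any B0 > 0.
        if not (B0 > 0):
            raise DomainError(f"B0 must be > 0, got {B0}")
        outcome = Outcome.PROGRESSION
        if law is g.GrowthLaw.EXPONENTIAL:
            t_R = np.log(model.omega_d / B0) / lam
            method = Method.CLOSED_FORM
        else:
            t_R = _ode_crossing_time(model, B0, horizon)
            method = Method.ODE_EVENT

    if t_R is None or t_R > horizon:
        return OutcomeRecord(B0, outcome, None, method, beyond_horizon=True, K=K)
    return OutcomeRecord(B0, outcome, float(t_R), method, K=K)


def cohort_outcomes(
    burdens: np.ndarray,
    model: g.RegrowthModel,
    horizon: float = DEFAULT_HORIZON,
    Ks: np.ndarray | None = None,
) -> list[OutcomeRecord]:
    """Recurrence outcomes for a whole cohort.

    The exponential law is evaluated vectorized through the closed form;
    bounded laws fall back to per-patient ODE event detection (optionally
    with per-patient carrying capacities ``Ks``).
    """
    burdens = np.asarray(burdens, dtype=float)
    if Ks is not None:
        Ks = np.asarray(Ks, dtype=float)
        if Ks.shape != burdens.shape:
            raise DomainError("Ks must match burdens in length")
        return [
            patient_recurrence_time(float(b), model, horizon, K=float(k))
            for b, k in zip(burdens, Ks)
        ]
    if model.growth.law is g.GrowthLaw.EXPONENTIAL:
        return _exponential_cohort(burdens, model, horizon)
    return [patient_recurrence_time(float(b), model, horizon) for b in burdens]


def _exponential_cohort(
    burdens: np.ndarray, model: g.RegrowthModel, horizon: float
) -> list[OutcomeRecord]:
    lam = model.growth.lambda_
    eps_V, omega_d = model.eps_V, model.omega_d
    records: list[OutcomeRecord] = []
    with np.errstate(divide="ignore"):
        if model.viability_term_enabled:
            prog = (burdens > eps_V) & (burdens < omega_d)
            t = np.full_like(burdens, np.nan)
            t[prog] = (1.0 / lam) * np.log(
                (1.0 / eps_V - 1.0 / omega_d) / (1.0 / eps_V - 1.0 / burdens[prog])
            )
        else:
            t = np.log(omega_d / np.maximum(burdens, 1e-300)) / lam
    for b, ti in zip(burdens, t):
        if b >= omega_d:
            records.append(OutcomeRecord(float(b), Outcome.DETECTABLE_AT_T0, 0.0, Method.CLOSED_FORM))
        elif model.viability_term_enabled and b <= eps_V:
            records.append(OutcomeRecord(float(b), Outcome.CURE, None, Method.CLOSED_FORM))
        elif ti > horizon:
            records.append(
                OutcomeRecord(float(b), Outcome.PROGRESSION, None, Method.CLOSED_FORM, beyond_horizon=True)
            )
        else:
            records.append(OutcomeRecord(float(b), Outcome.PROGRESSION, float(ti), Method.CLOSED_FORM))
    return records
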