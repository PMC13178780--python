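"""Virtual-cohort sampling of residual burden and carrying capacity.

Residual viable burden across a treated population is modeled as lognormal.
Two parameterization conventions appear in practice and are deliberately
explicit here, never inferred:

* ``log_space`` — ``(mu, sigma)`` are the location and scale of ``ln(B)``,
  the convention used when distributions are fitted in log space.
* ``arithmetic`` — ``(mean, sd)`` are the arithmetic mean and standard
  deviation of ``B`` itself (both in cc).

The cure fraction of a cohort is the probability mass of its burden
distribution below the viability threshold; ``fraction_below`` evaluates it
exactly from the lognormal CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError

__all__ = [
    "Convention",
    "BurdenDistribution",
    "VirtualPatient",
    "sample_burdens",
    "sample_carrying_capacities",
    "quantile_spaced_sample",
    "fraction_below",
]


class Convention(str, Enum):
    LOG_SPACE = "log_space"
    ARITHMETIC = "arithmetic"


@dataclass(frozen=True)
class BurdenDistribution:
    """A lognormal specification for burden (or carrying capacity) in cc.

    ``param1``/``param2`` are interpreted per ``convention`` (see module
    docstring).  The two conventions are exactly interconvertible.
    """

    convention: Convention
    param1: float
    param2: float
    family: str = "lognormal"

    def __post_init__(self):
        object.__setattr__(self, "convention", Convention(self.convention))
        if self.family != "lognormal":
            raise ConfigurationError(f"only the lognormal family is supported, got {self.family!r}")
        if not (self.param2 > 0 and math.isfinite(self.param2)):
            raise ConfigurationError(f"scale parameter must be finite and > 0, got {self.param2}")
        if not math.isfinite(self.param1):
            raise ConfigurationError(f"location parameter must be finite, got {self.param1}")
        if self.convention is Convention.ARITHMETIC and self.param1 <= 0:
            raise ConfigurationError(
                f"arithmetic convention requires mean > 0, got {self.param1}"
            )

    # -- convention conversions ------------------------------------------

    @property
    def mu(self) -> float:
        """Location of ln(B)."""
        if self.convention is Convention.LOG_SPACE:
            return self.param1
        m, s = self.param1, self.param2
        sigma2 = math.log1p((s / m) ** 2)
        return math.log(m) - sigma2 / 2.0

    @property
    def sigma(self) -> float:
        """Scale of ln(B)."""
        if self.convention is Convention.LOG_SPACE:
            return self.param2
        m, s = self.param1, self.param2
        return math.sqrt(math.log1p((s / m) ** 2))

    @property
    def arithmetic_mean(self) -> float:
        return math.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def arithmetic_sd(self) -> float:
        s2 = self.sigma**2
        return self.arithmetic_mean * math.sqrt(math.expm1(s2))

    def to_log_space(self) -> "BurdenDistribution":
        return BurdenDistribution(Convention.LOG_SPACE, self.mu, self.sigma)

    def to_arithmetic(self) -> "BurdenDistribution":
        return BurdenDistribution(Convention.ARITHMETIC, self.arithmetic_mean, self.arithmetic_sd)

    @classmethod
    def from_arithmetic_mean_log_sigma(cls, mean: float, log_sigma: float) -> "BurdenDistribution":
        """Mixed spec: arithmetic mean with an ln-space scale.

        Used for carrying-capacity distributions quoted as "mean = 13.8 cc,
        sd = 0.5" where 0.5 is only consistent as the ln-space scale.
        """
        if mean <= 0:
            raise ConfigurationError(f"mean must be > 0, got {mean}")
        mu = math.log(mean) - log_sigma**2 / 2.0
        return cls(Convention.LOG_SPACE, mu, log_sigma)

    # -- distribution functions ------------------------------------------

    def _frozen(self):
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))

    def cdf(self, x) -> float | np.ndarray:
        return self._frozen().cdf(x)

    def ppf(self, q) -> float | np.ndarray:
        return self._frozen().ppf(q)

    @property
    def median(self) -> float:
        return math.exp(self.mu)


@dataclass
class VirtualPatient:
    """One sampled patient: initial burden, optional capacity, outcome slot.

    ``outcome``/``t_R`` are filled by the recurrence layer; the invariants
    (cure iff t_R is None; detectable_at_t0 iff t_R == 0) are enforced
    there.
    """

    B0: float
    K: float | None = None
    outcome: str | None = None
    t_R: float | None = None


def sample_burdens(dist: BurdenDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` independent lognormal burdens, reproducibly.

    The stream is prefix-stable: the first ``k`` draws do not depend on
    ``n``, so growing a cohort never reshuffles earlier patients.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    return np.exp(dist.mu + dist.sigma * z)


def sample_carrying_capacities(dist: BurdenDistribution, n: int, seed: int) -> np.ndarray:
    """Draw per-patient carrying capacities; paired with burdens by index."""
    return sample_burdens(dist, n, seed)


def quantile_spaced_sample(
    dist: BurdenDistribution, n: int, q_lo: float = 0.05, q_hi: float = 0.95
) -> np.ndarray:
    """Deterministic burdens at ``n`` equally spaced quantiles on [q_lo, q_hi].

    Implements "equally spaced virtual patients" reproducibly: equal spacing
    in probability, spanning the body of the distribution.
    """
    if not (0 < q_lo < q_hi < 1):
        raise DomainError("need 0 < q_lo < q_hi < 1")
    if n < 2:
        raise DomainError("need n >= 2")
    qs = np.linspace(q_lo, q_hi, n)
    return np.asarray(dist.ppf(qs), dtype=float)


def fraction_below(dist: BurdenDistribution, threshold: float) -> float:
    """Exact lognormal CDF at ``threshold`` — the cure fraction when the
    threshold is the minimum viability burden eps_V."""
    if not (threshold > 0):
        raise DomainError(f"threshold must be > 0, got {threshold}")
    if math.isinf(threshold):
        return 1.0
    return float(dist.cdf(threshold))
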