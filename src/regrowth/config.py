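"""Scenario configuration: YAML loading, validation, built-in scenarios.

A scenario bundles everything one simulation run needs: the growth law and
rate, the viability and detection thresholds, one or more arms (each a
burden distribution plus cohort size), an optional carrying-capacity
distribution, replication, seed, horizon, and grid step.  Unknown keys are
rejected — a silently ignored typo in a parameter name would corrupt
scientific output — and every error message carries the offending key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import BurdenDistribution, Convention
from .errors import ConfigurationError
from .growth import GrowthLaw, GrowthLawParams, RegrowthModel
from .survival import ArmSpec

__all__ = ["ArmConfig", "ScenarioConfig", "load_config", "builtin_scenario", "BUILTIN_SCENARIOS"]


@dataclass(frozen=True)
class ArmConfig:
    label: str
    dist: BurdenDistribution
    n: int


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    arms: tuple[ArmConfig, ...]
    law: GrowthLaw
    lambda_: float
    eps_V: float
    omega_d: float
    K: float | None = None
    K_dist: BurdenDistribution | None = None
    viability_term_enabled: bool = True
    n_reps: int = 1
    seed: int = 0
    horizon_days: float = 7300.0
    grid_step_days: float = 1.0

    def model(self) -> RegrowthModel:
        K = self.K
        if K is None and self.K_dist is not None:
            K = self.K_dist.arithmetic_mean
        return RegrowthModel(
            growth=GrowthLawParams(law=self.law, lambda_=self.lambda_, K=K),
            eps_V=self.eps_V,
            omega_d=self.omega_d,
            viability_term_enabled=self.viability_term_enabled,
        )

    def arm_specs(self) -> list[ArmSpec]:
        m = self.model()
        return [ArmSpec(dist=a.dist, model=m, n=a.n) for a in self.arms]


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigurationError(f"{path}.{key}: required key missing")
    return mapping[key]


def _check_unknown(mapping: dict, allowed: set[str], path: str):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _parse_dist(block: dict, path: str) -> BurdenDistribution:
    if not isinstance(block, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    _check_unknown(block, {"family", "convention", "param1", "param2"}, path)
    family = block.get("family", "lognormal")
    conv = _require(block, "convention", path)
    p1 = float(_require(block, "param1", path))
    p2 = float(_require(block, "param2", path))
    try:
        if conv == "arithmetic_mean_log_sigma":
            return BurdenDistribution.from_arithmetic_mean_log_sigma(p1, p2)
        return BurdenDistribution(convention=Convention(conv), param1=p1, param2=p2, family=family)
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


_TOP_KEYS = {
    "name", "growth", "thresholds", "viability_term", "cohort",
    "arms", "K_distribution", "horizon_days", "grid_step_days",
}


def parse_scenario(raw: dict, name_default: str = "scenario") -> ScenarioConfig:
    """Validate a raw scenario mapping into a ScenarioConfig."""
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario: top level must be a mapping")
    _check_unknown(raw, _TOP_KEYS, "scenario")

    growth = _require(raw, "growth", "scenario")
    _check_unknown(growth, {"law", "lambda_", "K"}, "scenario.growth")
    try:
        law = GrowthLaw(_require(growth, "law", "scenario.growth"))
    except ValueError as exc:
        raise ConfigurationError(f"scenario.growth.law: {exc}") from exc
    lambda_ = float(_require(growth, "lambda_", "scenario.growth"))
    K = growth.get("K")

    thr = _require(raw, "thresholds", "scenario")
    _check_unknown(thr, {"eps_V", "omega_d"}, "scenario.thresholds")
    eps_V = float(_require(thr, "eps_V", "scenario.thresholds"))
    omega_d = float(_require(thr, "omega_d", "scenario.thresholds"))
    if not (0 <= eps_V < omega_d):
        raise ConfigurationError(
            f"scenario.thresholds: need eps_V < omega_d, got eps_V={eps_V}, omega_d={omega_d}"
        )

    cohort = raw.get("cohort", {})
    _check_unknown(cohort, {"n", "seed", "n_reps"}, "scenario.cohort")
    n_default = int(cohort.get("n", 100))
    seed = int(cohort.get("seed", 0))
    n_reps = int(cohort.get("n_reps", 1))

    arms_raw = _require(raw, "arms", "scenario")
    if not isinstance(arms_raw, list) or not arms_raw:
        raise ConfigurationError("scenario.arms: expected a nonempty list")
    arms = []
    for i, a in enumerate(arms_raw):
        path = f"scenario.arms[{i}]"
        _check_unknown(a, {"label", "distribution", "n"}, path)
        arms.append(
            ArmConfig(
                label=str(a.get("label", f"arm{i + 1}")),
                dist=_parse_dist(_require(a, "distribution", path), f"{path}.distribution"),
                n=int(a.get("n", n_default)),
            )
        )

    K_dist = None
    if "K_distribution" in raw:
        K_dist = _parse_dist(raw["K_distribution"], "scenario.K_distribution")

    cfg = ScenarioConfig(
        name=str(raw.get("name", name_default)),
        arms=tuple(arms),
        law=law,
        lambda_=lambda_,
        eps_V=eps_V,
        omega_d=omega_d,
        K=None if K is None else float(K),
        K_dist=K_dist,
        viability_term_enabled=bool(raw.get("viability_term", True)),
        n_reps=n_reps,
        seed=seed,
        horizon_days=float(raw.get("horizon_days", 7300.0)),
        grid_step_days=float(raw.get("grid_step_days", 1.0)),
    )
    cfg.model()  # surfaces cross-constraint violations (e.g. omega_d >= K) at load time
    return cfg


def load_config(path) -> ScenarioConfig:
    """Load and fully validate a scenario YAML file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: YAML parse error: {exc}") from exc
    if raw is None:
        raise ConfigurationError(f"{path}: empty config file")
    return parse_scenario(raw, name_default=path.stem)


# -- built-in scenarios (parameter sets from the demonstration figures) ----

BUILTIN_SCENARIOS: dict[str, dict] = {
    # Single-arm workflow demo: lognormal(mean 0.05 cc, sd 0.06 cc) burdens,
    # slow regrowth, 50 patients.
    "fig2_workflow": {
        "growth": {"law": "exponential", "lambda_": 0.0008},
        "thresholds": {"eps_V": 0.01, "omega_d": 0.056},
        "cohort": {"n": 50},
        "arms": [
            {
                "label": "cohort",
                "distribution": {"convention": "arithmetic", "param1": 0.05, "param2": 0.06},
            }
        ],
    },
    # Parameter-effect baseline: same burden distribution, n = 1,000.
    "fig3_baseline": {
        "growth": {"law": "exponential", "lambda_": 0.0015},
        "thresholds": {"eps_V": 0.01, "omega_d": 0.056},
        "cohort": {"n": 1000},
        "arms": [
            {
                "label": "baseline",
                "distribution": {"convention": "arithmetic", "param1": 0.05, "param2": 0.06},
            }
        ],
    },
    # Two-arm trial demo: arm means 0.03 vs 0.05 cc at equal shape.  The
    # ln-space scale is a free parameter (no published value); 0.8 gives a
    # plausible long-tailed unimodal shape.
    "fig4_trial": {
        "growth": {"law": "exponential", "lambda_": 0.0015},
        "thresholds": {"eps_V": 0.01, "omega_d": 0.056},
        "cohort": {"n": 200},
        "arms": [
            {
                "label": "arm1",
                "distribution": {"convention": "arithmetic_mean_log_sigma", "param1": 0.03, "param2": 0.8},
            },
            {
                "label": "arm2",
                "distribution": {"convention": "arithmetic_mean_log_sigma", "param1": 0.05, "param2": 0.8},
            },
        ],
    },
    # Growth-law comparison: burden lognormal (arithmetic mean 0.02 cc,
    # ln-scale 0.5); patient-specific K ~ lognormal (arithmetic mean
    # 13.8 cc, ln-scale 0.5).
    "fig5_growthlaws": {
        "growth": {"law": "exponential", "lambda_": 0.0009},
        "thresholds": {"eps_V": 0.015, "omega_d": 0.056},
        "cohort": {"n": 50},
        "arms": [
            {
                "label": "cohort",
                "distribution": {"convention": "arithmetic_mean_log_sigma", "param1": 0.02, "param2": 0.5},
            }
        ],
        "K_distribution": {"convention": "arithmetic_mean_log_sigma", "param1": 13.8, "param2": 0.5},
    },
    # RTOG 9003-like two-arm scenario: standard vs hyperfractionated RT
    # residual-burden distributions with the fitted global thresholds.
    "rtog9003_like": {
        "growth": {"law": "exponential", "lambda_": 0.005},
        "thresholds": {"eps_V": 2.5e-4, "omega_d": 0.4},
        "cohort": {"n": 265, "n_reps": 100},
        "arms": [
            {
                "label": "standard",
                "distribution": {"convention": "log_space", "param1": -8.0, "param2": 6.8},
            },
            {
                "label": "hyperfractionation",
                "distribution": {"convention": "log_space", "param1": -10.0, "param2": 7.6},
            },
        ],
    },
}


def builtin_scenario(name: str) -> ScenarioConfig:
    """Return a validated built-in scenario by name."""
    if name not in BUILTIN_SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}"
        )
    return parse_scenario(BUILTIN_SCENARIOS[name], name_default=name)
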