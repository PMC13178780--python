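"""CSV input/output and the fixture generator.

Curve CSV dialect: header row mandatory, UTF-8, "." decimal separator,
columns ``time_days, survival, recurrence_fraction`` (bands add
``lower95, upper95, n_reps``).  Observed curves are read from
``time_days, event_free_fraction`` files (``survival`` is accepted as a
column alias so written curves round-trip).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import ObservedCurve
from .cohort import sample_burdens, sample_carrying_capacities
from .config import ScenarioConfig, builtin_scenario
from .errors import CurveFormatError
from .growth import GrowthLaw
from .recurrence import cohort_outcomes
from .survival import RecurrenceCurve, ReplicateBand, cohort_curve, default_grid

__all__ = ["write_curve", "read_observed_curve", "generate_fixture"]

_FLOAT_FMT = "%.12g"


def write_curve(curve: RecurrenceCurve, path, band: ReplicateBand | None = None) -> None:
    """Write a curve (optionally with its replicate band) to CSV."""
    data = {
        "time_days": curve.t_grid,
        "survival": curve.survival,
        "recurrence_fraction": curve.recurrence,
    }
    if band is not None:
        data["lower95"] = band.lower
        data["upper95"] = band.upper
        data["n_reps"] = np.full(curve.t_grid.size, band.n_reps, dtype=int)
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_observed_curve(path, label: str | None = None) -> ObservedCurve:
    """Read an observed event-free curve, with row-numbered errors.

    Rejects empty files, malformed rows, and non-monotone (increasing)
    event-free fractions, naming the offending data row.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if not rows:
        raise CurveFormatError(f"{path}: empty file, expected a header and data rows")
    header = [c.strip() for c in rows[0]]
    try:
        t_col = header.index("time_days")
    except ValueError:
        raise CurveFormatError(f"{path}: header must contain 'time_days', got {header}")
    f_col = None
    for name in ("event_free_fraction", "survival"):
        if name in header:
            f_col = header.index(name)
            break
    if f_col is None:
        raise CurveFormatError(
            f"{path}: header must contain 'event_free_fraction' (or 'survival'), got {header}"
        )
    times, fracs = [], []
    for k, row in enumerate(rows[1:], start=2):  # 1-based file rows, row 1 is the header
        try:
            t = float(row[t_col])
            f = float(row[f_col])
        except (ValueError, IndexError) as exc:
            raise CurveFormatError(f"{path}: row {k}: malformed row {row!r}") from exc
        if not (0.0 <= f <= 1.0):
            raise CurveFormatError(f"{path}: row {k}: fraction {f} outside [0, 1]")
        if times and t <= times[-1]:
            raise CurveFormatError(f"{path}: row {k}: time {t} not strictly increasing")
        if fracs and f > fracs[-1]:
            raise CurveFormatError(
                f"{path}: row {k}: event-free fraction increases ({fracs[-1]} -> {f})"
            )
        times.append(t)
        fracs.append(f)
    if len(times) < 3:
        raise CurveFormatError(f"{path}: need at least 3 data rows, got {len(times)}")
    return ObservedCurve(
        times=np.array(times), event_free_fraction=np.array(fracs),
        label=label if label is not None else path.stem,
    )


def generate_fixture(scenario: str | ScenarioConfig, out_dir, seed: int) -> list[Path]:
    """Simulate a scenario and write cohort/curve CSVs plus metadata.

    Per arm: ``<label>_cohort.csv`` (patient, B0, outcome, t_R_days) and
    ``<label>_curve.csv``; plus ``metadata.yaml`` recording every
    generating parameter and the seed.  Byte-identical under a fixed seed.
    """
    cfg = builtin_scenario(scenario) if isinstance(scenario, str) else scenario
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = cfg.model()
    grid = default_grid(cfg.horizon_days, cfg.grid_step_days)
    written: list[Path] = []
    for arm in cfg.arms:
        burdens = sample_burdens(arm.dist, arm.n, seed)
        Ks = None
        if cfg.K_dist is not None and cfg.law is not GrowthLaw.EXPONENTIAL:
            Ks = sample_carrying_capacities(cfg.K_dist, arm.n, seed + 1)
        outcomes = cohort_outcomes(burdens, model, horizon=cfg.horizon_days, Ks=Ks)
        cohort_path = out_dir / f"{arm.label}_cohort.csv"
        pd.DataFrame(
            {
                "patient": np.arange(arm.n),
                "B0": burdens,
                "outcome": [o.outcome.value for o in outcomes],
                "t_R_days": [("" if o.t_R is None else o.t_R) for o in outcomes],
            }
        ).to_csv(cohort_path, index=False, float_format=_FLOAT_FMT)
        curve_path = out_dir / f"{arm.label}_curve.csv"
        write_curve(cohort_curve(outcomes, grid), curve_path)
        written += [cohort_path, curve_path]

    meta = {
        "scenario": cfg.name,
        "seed": seed,
        "package_version": __version__,
        "growth": {"law": cfg.law.value, "lambda_": cfg.lambda_, "K": cfg.K},
        "thresholds": {"eps_V": cfg.eps_V, "omega_d": cfg.omega_d},
        "viability_term": cfg.viability_term_enabled,
        "horizon_days": cfg.horizon_days,
        "grid_step_days": cfg.grid_step_days,
        "arms": [
            {
                "label": a.label,
                "n": a.n,
                "distribution": {
                    "convention": a.dist.convention.value,
                    "param1": a.dist.param1,
                    "param2": a.dist.param2,
                },
            }
            for a in cfg.arms
        ],
    }
    if cfg.K_dist is not None:
        meta["K_distribution"] = {
            "convention": cfg.K_dist.convention.value,
            "param1": cfg.K_dist.param1,
            "param2": cfg.K_dist.param2,
        }
    if cfg.name == "rtog9003_like":
        # Both published regrowth-rate values for this scenario; the fixture
        # uses the fitted text value 0.005/d.
        meta["reported_lambda_alternatives"] = [0.005, 0.009]
    meta_path = out_dir / "metadata.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(meta_path)
    return written
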