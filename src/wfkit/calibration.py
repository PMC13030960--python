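"""PSD95-benchmarked volume-cutoff calibration.

Appositions dual-labeled with a postsynaptic marker (PSD95) benchmark the
volume filter: for each candidate cutoff, prediction accuracy is the
PSD95+ share of surviving appositions and true-positive retention is the
share of PSD95+ appositions kept.  Ordinary least-squares lines are fitted
to both curves over the cutoff grid, and the crossing of the two lines is
the calibrated cutoff — the volume at which accuracy is gained at the
smallest cost in retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class CalibrationError(RuntimeError):
    """Raised when the calibration cannot produce a crossing."""


@dataclass(frozen=True)
class BenchmarkApposition:
    """One apposition volume with its postsynaptic co-label flag."""

    volume_um3: float
    psd95_positive: bool

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("apposition volume must be > 0")


@dataclass
class CalibrationResult:
    cutoff_um3: float
    accuracy_at_cutoff: float
    retention_at_cutoff: float
    r2_accuracy: float
    r2_retention: float
    accuracy_slope: float
    accuracy_intercept: float
    retention_slope: float
    retention_intercept: float
    grid: list[tuple[float, float | None, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cutoff_um3": self.cutoff_um3,
            "accuracy_at_cutoff": self.accuracy_at_cutoff,
            "retention_at_cutoff": self.retention_at_cutoff,
            "r2_accuracy": self.r2_accuracy,
            "r2_retention": self.r2_retention,
            "grid": [
                {"cutoff": c, "accuracy": a, "retention": r} for c, a, r in self.grid
            ],
        }


def prediction_accuracy(data: Sequence[BenchmarkApposition], cutoff: float) -> float:
    """100 x PSD95+ survivors / all survivors at the given volume cutoff."""
    kept = [d for d in data if d.volume_um3 >= cutoff]
    if not kept:
        raise CalibrationError(f"no appositions survive cutoff {cutoff}")
    positive = sum(d.psd95_positive for d in kept)
    return 100.0 * positive / len(kept)


def true_positive_retention(data: Sequence[BenchmarkApposition], cutoff: float) -> float:
    """100 x PSD95+ kept at cutoff / PSD95+ total (retention(0) = 100)."""
    total_pos = sum(d.psd95_positive for d in data)
    if total_pos == 0:
        raise CalibrationError("no PSD95+ appositions in the benchmark")
    kept_pos = sum(d.psd95_positive and d.volume_um3 >= cutoff for d in data)
    return 100.0 * kept_pos / total_pos


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y ~ x; returns (slope, intercept, R^2)."""
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def calibrate_cutoff(
    data: Sequence[BenchmarkApposition],
    cutoff_range: tuple[float, float] = (0.0, 0.5),
    n_points: int = 21,
) -> CalibrationResult:
    """Calibrate the volume cutoff from accuracy/retention regression lines.

    Both metrics are evaluated at ``n_points`` evenly spaced cutoffs over
    ``cutoff_range``; grid points with an empty survivor set contribute no
    accuracy value.  OLS lines are fitted to each metric against cutoff and
    their intersection (clipped to the range) is the calibrated cutoff.
    Parallel lines raise :class:`CalibrationError` ("no crossing").
    """
    if not any(d.psd95_positive for d in data) or all(d.psd95_positive for d in data):
        raise CalibrationError("benchmark must contain both PSD95+ and PSD95- appositions")
    lo, hi = cutoff_range
    if not (hi > lo >= 0.0) or n_points < 2:
        raise CalibrationError("invalid cutoff range or grid size")
    cutoffs = np.linspace(lo, hi, n_points)

    grid: list[tuple[float, float | None, float]] = []
    acc_x, acc_y, ret_x, ret_y = [], [], [], []
    for c in cutoffs:
        retention = true_positive_retention(data, c)
        ret_x.append(c)
        ret_y.append(retention)
        try:
            accuracy = prediction_accuracy(data, c)
        except CalibrationError:
            grid.append((float(c), None, retention))
            continue
        acc_x.append(c)
        acc_y.append(accuracy)
        grid.append((float(c), accuracy, retention))

    if len(acc_x) < 2 or len(ret_x) < 2:
        raise CalibrationError("fewer than 2 valid grid points for a metric")

    a_slope, a_int, a_r2 = _ols(np.array(acc_x), np.array(acc_y))
    r_slope, r_int, r_r2 = _ols(np.array(ret_x), np.array(ret_y))
    denom = a_slope - r_slope
    if abs(denom) < 1e-12:
        raise CalibrationError("no crossing: regression lines are parallel")
    x_star = float(np.clip((r_int - a_int) / denom, lo, hi))
    return CalibrationResult(
        cutoff_um3=x_star,
        accuracy_at_cutoff=float(a_slope * x_star + a_int),
        retention_at_cutoff=float(r_slope * x_star + r_int),
        r2_accuracy=a_r2,
        r2_retention=r_r2,
        accuracy_slope=a_slope,
        accuracy_intercept=a_int,
        retention_slope=r_slope,
        retention_intercept=r_int,
        grid=grid,
    )


# --- CSV I/O ---


def read_benchmark_csv(path: str | Path) -> list[BenchmarkApposition]:
    """Read a benchmark table with columns volume_um3, psd95_positive."""
    df = pd.read_csv(path)
    missing = {"volume_um3", "psd95_positive"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        BenchmarkApposition(
            volume_um3=float(row.volume_um3),
            psd95_positive=bool(int(row.psd95_positive)),
        )
        for row in df.itertuples()
    ]


def write_benchmark_csv(data: Sequence[BenchmarkApposition], path: str | Path) -> None:
    pd.DataFrame(
        {
            "volume_um3": [d.volume_um3 for d in data],
            "psd95_positive": [int(d.psd95_positive) for d in data],
        }
    ).to_csv(path, index=False)
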