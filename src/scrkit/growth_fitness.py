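"""Growth-curve analysis: instantaneous doubling time, carrying capacity, fitness.

The burden a codon-reassigning system places on its host shows up in growth:
a slower instantaneous doubling time and a reduced carrying capacity relative
to an "empty"-machinery control.  The instantaneous doubling time is taken as
the fastest sustained exponential stretch of the curve: a fixed-width window
slides over ln(OD600), a line is fitted in each window, and

    t_d = ln(2) / max slope.

Relative system fitness between a control and a test system is the doubling
time ratio ``100 * t_ref / t_test`` — slower growth gives < 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "GrowthCurve",
    "DoublingTimeFit",
    "FitnessResult",
    "NonGrowingError",
    "instantaneous_doubling_time",
    "relative_fitness",
    "carrying_capacity",
    "doubling_time_replicates",
    "read_growth_table",
    "fitness_from_table",
    "DEFAULT_WINDOW_POINTS",
    "DEFAULT_OD_FLOOR",
]

#: Sliding-window width (samples) for the log-linear fit.  Nine points at a
#: typical 5-10 min read interval span roughly one to two doublings, wide
#: enough that read-to-read noise does not dominate the fitted slope.
DEFAULT_WINDOW_POINTS = 9

#: OD values are floored here before taking logs so blank-level noise cannot
#: produce spurious steep slopes.
DEFAULT_OD_FLOOR = 0.005


class NonGrowingError(ValueError):
    """Raised when no window of the curve shows a positive growth slope."""


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 versus time (minutes) for one well/culture."""

    time_min: np.ndarray
    od600: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if len(t) != len(od):
            raise ValueError(f"{self.label!r}: time and OD lengths differ")
        if len(t) < 5:
            raise ValueError(f"{self.label!r}: need at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.label!r}: time points must be strictly increasing")
        if np.any(od < 0):
            raise ValueError(f"{self.label!r}: negative OD readings")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class DoublingTimeFit:
    """Winning window of the sliding log-linear fit."""

    doubling_time_min: float
    slope_per_min: float        # d ln(OD) / dt in the winning window
    window_start_min: float
    window_end_min: float

    def __str__(self) -> str:
        return (
            f"t_d = {self.doubling_time_min:.1f} min "
            f"(window {self.window_start_min:.0f}-{self.window_end_min:.0f} min)"
        )


@dataclass(frozen=True)
class FitnessResult:
    """Doubling time of a test system against a named reference."""

    doubling_time_min: float
    doubling_time_sd_min: float
    reference_doubling_time_min: float
    relative_fitness_pct: float
    carrying_capacity: float
    n_replicates: int

    @property
    def relative_fitness_rounded(self) -> int:
        return int(round(self.relative_fitness_pct))


def instantaneous_doubling_time(
    curve: GrowthCurve,
    window_points: int = DEFAULT_WINDOW_POINTS,
    *,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> DoublingTimeFit:
    """Doubling time from the steepest sliding-window log-linear fit.

    Exact on noiseless exponentials for any window width >= 3.  Invariant to
    rescaling OD by a positive constant (a constant shift in log space).
    Raises :class:`NonGrowingError` when no window has a positive slope.
    """
    if window_points < 3:
        raise ValueError("window must contain at least 3 points")
    t, od = curve.time_min, curve.od600
    if len(t) < window_points:
        raise ValueError(
            f"curve has {len(t)} points, fewer than the {window_points}-point window"
        )
    y = np.log(np.maximum(od, od_floor))
    best_slope = -np.inf
    best_i = 0
    for i in range(len(t) - window_points + 1):
        tw = t[i : i + window_points]
        yw = y[i : i + window_points]
        slope = np.polyfit(tw, yw, 1)[0]
        if slope > best_slope:
            best_slope = slope
            best_i = i
    # slopes at rounding-noise level (doubling times of ~1e12 min) are not growth
    if best_slope <= 1e-12:
        raise NonGrowingError(f"{curve.label!r}: no window with a positive growth slope")
    return DoublingTimeFit(
        doubling_time_min=float(np.log(2.0) / best_slope),
        slope_per_min=float(best_slope),
        window_start_min=float(t[best_i]),
        window_end_min=float(t[best_i + window_points - 1]),
    )


def relative_fitness(t_ref_min: float, t_test_min: float) -> float:
    """Relative system fitness, percent: ``100 * t_ref / t_test``.

    Defined control-over-test so that a slower-growing test system scores
    below 100% and a faster one above; present rounded to the nearest integer
    (e.g. 40.0 vs 45.8 min -> 87.3 -> "~87%").
    """
    if t_ref_min <= 0 or t_test_min <= 0:
        raise ValueError("doubling times must be positive")
    return 100.0 * t_ref_min / t_test_min


def carrying_capacity(curve: GrowthCurve, smoothing_points: int = 5) -> float:
    """Plateau OD: maximum of the moving-median-smoothed curve.

    The median filter discards isolated spikes (bubbles, condensation) that a
    plain maximum would report.
    """
    if smoothing_points < 1:
        raise ValueError("smoothing window must be positive")
    k = min(smoothing_points, len(curve.od600))
    if k % 2 == 0:
        k -= 1
    smoothed = medfilt(curve.od600, kernel_size=k) if k >= 3 else curve.od600
    return float(np.max(smoothed))


def doubling_time_replicates(
    curves: Sequence[GrowthCurve],
    window_points: int = DEFAULT_WINDOW_POINTS,
    *,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> tuple[float, float, int]:
    """Mean, sample SD, and count of doubling times across replicate curves.

    Error bars come from biological replicates, not single-fit standard
    errors, matching how replicate doubling times are conventionally quoted.
    """
    fits = [
        instantaneous_doubling_time(c, window_points, od_floor=od_floor).doubling_time_min
        for c in curves
    ]
    arr = np.asarray(fits)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(np.mean(arr)), sd, len(arr)


# -- CSV workflow -----------------------------------------------------------

GROWTH_COLUMNS = ("time_min", "well", "od600")


def read_growth_table(path: str | Path) -> pd.DataFrame:
    """Long-format growth CSV with columns time_min, well, od600."""
    df = pd.read_csv(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def fitness_from_table(
    reads: pd.DataFrame,
    sample_map: pd.DataFrame,
    *,
    reference: str,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> pd.DataFrame:
    """Per-sample doubling time, carrying capacity, and fitness vs a reference.

    ``sample_map`` needs columns well, sample; ``reference`` names the sample
    whose mean doubling time anchors relative fitness.
    """
    for col in ("well", "sample"):
        if col not in sample_map.columns:
            raise ValueError(f"sample map: missing required column(s): {col}")
    curves_by_sample: dict[str, list[GrowthCurve]] = {}
    well_to_sample = dict(
        zip(sample_map["well"].astype(str), sample_map["sample"].astype(str))
    )
    for well, grp in reads.groupby("well"):
        sample = well_to_sample.get(str(well))
        if sample is None:
            continue
        grp = grp.sort_values("time_min")
        curves_by_sample.setdefault(sample, []).append(
            GrowthCurve(grp["time_min"].to_numpy(), grp["od600"].to_numpy(), label=str(well))
        )
    if reference not in curves_by_sample:
        raise ValueError(f"reference sample {reference!r} not present in the sample map")

    stats = {
        s: doubling_time_replicates(cs, window_points, od_floor=od_floor)
        for s, cs in curves_by_sample.items()
    }
    t_ref = stats[reference][0]
    rows = []
    for sample, curves in sorted(curves_by_sample.items()):
        mean_td, sd_td, n = stats[sample]
        rows.append(
            {
                "sample": sample,
                "doubling_time_min": mean_td,
                "doubling_time_sd_min": sd_td,
                "n": n,
                "carrying_capacity": float(np.mean([carrying_capacity(c) for c in curves])),
                "relative_fitness_pct": relative_fitness(t_ref, mean_td),
            }
        )
    return pd.DataFrame(rows)
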