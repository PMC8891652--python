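"""Reassignment-efficiency quantification and multi-site incorporation modeling.

The fluorescence screen places the target codon at the fluorophore position of
a GFP reporter: only translation events inserting tyrosine (or a fluorogenic
noncanonical amino acid) yield a mature fluorophore, so reporter fluorescence
is proportional to the fraction of reassigned translation events.  Efficiency
is quantified by bracketing the test signal between two references measured on
the same plate:

    E_i = 100 * (S_i - S_0) / (S_100 - S_0)

where ``S_100`` comes from a reporter with a tyrosine codon at the fluorophore
(full signal) and ``S_0`` from a reporter with a non-tyrosine codon there (no
fluorophore).  Signals are optical-density-corrected fluorescence averaged
over a growth window, which removes biases from differing growth profiles.
The same normalization applies to fluorescence-per-protein measurements on
clarified lysates, with an optional brightness correction when the test
chromophore differs photophysically from the reference.

Multi-site incorporation is modeled as independent Bernoulli incorporation per
target codon: the fully-substituted yield is ``p**n`` and the species mixture
over the number of occupied sites is binomial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTimeSeries",
    "ReferenceSet",
    "EfficiencyEstimate",
    "YieldModel",
    "DEFAULT_DETECTION_LIMIT_PCT",
    "window_signal",
    "reassignment_efficiency",
    "lysate_efficiency",
    "below_detection",
    "multi_site_yield",
    "species_distribution",
    "fold_improvement",
    "read_plate_reader",
    "read_sample_map",
    "screen_from_plate",
]

#: Detection limit of the fluorescence screen, percent (2 of every 1000
#: incorporation events at the target codon).
DEFAULT_DETECTION_LIMIT_PCT = 0.2


@dataclass(frozen=True)
class FluorescenceTimeSeries:
    """Per-well plate-reader record: time (minutes), OD600, fluorescence."""

    label: str
    time_min: np.ndarray
    od600: np.ndarray
    fluor: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        fl = np.asarray(self.fluor, dtype=float)
        if not (len(t) == len(od) == len(fl)):
            raise ValueError(f"{self.label!r}: time/OD/fluorescence lengths differ")
        if len(t) < 2:
            raise ValueError(f"{self.label!r}: need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.label!r}: time points must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od600", od)
        object.__setattr__(self, "fluor", fl)


@dataclass(frozen=True)
class ReferenceSet:
    """Plate-matched reference signals bracketing the normalization.

    ``s100``: signal of the 100% reference (tyrosine codon at the fluorophore,
    or pure-ncAA protein from amber suppression for lysate measurements).
    ``s0``: signal of the 0% reference (non-tyrosine codon at the fluorophore).
    """

    s100: float
    s0: float

    def __post_init__(self):
        if not (self.s100 > self.s0):
            raise ValueError(
                f"degenerate normalization: 100% reference ({self.s100}) must exceed "
                f"0% reference ({self.s0})"
            )


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Mean +/- sample SD reassignment efficiency (percent) over replicates.

    Values outside [0, 100] are reported as-is (measurement noise), never
    clipped; ``out_of_range`` flags them.
    """

    mean_pct: float
    sd_pct: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one replicate")
        if self.sd_pct < 0:
            raise ValueError("standard deviation cannot be negative")

    @property
    def out_of_range(self) -> bool:
        return not (0.0 <= self.mean_pct <= 100.0)

    def __str__(self) -> str:
        return f"{self.mean_pct:.1f} +/- {self.sd_pct:.1f}% (n={self.n})"


def window_signal(
    series: FluorescenceTimeSeries,
    start_min: float = 0.0,
    end_min: float = 240.0,
) -> float:
    """Time-averaged OD-corrected fluorescence over a window.

    Computes the pointwise ratio F/OD at every sampled time inside
    ``[start_min, end_min]`` and averages it by trapezoidal integration divided
    by the spanned time.  The default 4 h window follows the screen's readout
    convention; averaging the *ratio* makes the statistic insensitive to when
    each culture happens to enter exponential phase.
    """
    t, od, fl = series.time_min, series.od600, series.fluor
    if start_min < t[0] or end_min > t[-1]:
        raise ValueError(
            f"{series.label!r}: window [{start_min}, {end_min}] min outside sampled "
            f"range [{t[0]}, {t[-1]}]"
        )
    mask = (t >= start_min) & (t <= end_min)
    if mask.sum() < 2:
        raise ValueError(f"{series.label!r}: fewer than 2 samples in the window")
    if np.any(od[mask] <= 0):
        raise ValueError(f"{series.label!r}: non-positive OD inside the window")
    tw = t[mask]
    ratio = fl[mask] / od[mask]
    return float(np.trapezoid(ratio, tw) / (tw[-1] - tw[0]))


def _estimate(per_replicate_pct: np.ndarray) -> EfficiencyEstimate:
    e = np.asarray(per_replicate_pct, dtype=float)
    sd = float(np.std(e, ddof=1)) if len(e) > 1 else 0.0
    return EfficiencyEstimate(mean_pct=float(np.mean(e)), sd_pct=sd, n=len(e))


def reassignment_efficiency(
    test_signals: Sequence[float],
    refs: ReferenceSet,
) -> EfficiencyEstimate:
    """Two-reference normalized efficiency, mean +/- SD over replicates.

    Affine-invariant: rescaling and shifting all signals together leaves the
    estimate unchanged, so the 0% reference absorbs instrument background.
    """
    s = np.asarray(list(test_signals), dtype=float)
    if s.size < 1:
        raise ValueError("need at least one test replicate")
    e = 100.0 * (s - refs.s0) / (refs.s100 - refs.s0)
    return _estimate(e)


def lysate_efficiency(
    fluor: Sequence[float],
    protein: Sequence[float],
    refs: ReferenceSet,
    *,
    brightness_correction: float = 1.0,
) -> EfficiencyEstimate:
    """Efficiency from clarified-lysate fluorescence normalized per protein.

    ``refs`` must hold fluorescence-*per-protein* reference values.
    ``brightness_correction`` rescales the 100% reference when the reporter
    chromophore of the test protein differs from the reference chromophore
    (e.g. ~0.1 apparent brightness for an azide-substituted fluorophore); with
    a correction of 1 this is exactly :func:`reassignment_efficiency` applied
    to per-protein ratios.
    """
    f = np.asarray(list(fluor), dtype=float)
    p = np.asarray(list(protein), dtype=float)
    if f.shape != p.shape:
        raise ValueError("fluorescence and protein arrays must have equal length")
    if np.any(p <= 0):
        raise ValueError("protein amounts must be positive")
    if brightness_correction <= 0:
        raise ValueError("brightness correction must be positive")
    corrected = ReferenceSet(s100=refs.s100 * brightness_correction, s0=refs.s0)
    return reassignment_efficiency(f / p, corrected)


def below_detection(
    estimate: EfficiencyEstimate | float,
    limit_pct: float = DEFAULT_DETECTION_LIMIT_PCT,
) -> bool:
    """True iff the mean efficiency is strictly below the screen's detection limit.

    Boundary equality counts as detectable (strict ``<``).
    """
    if limit_pct <= 0:
        raise ValueError("detection limit must be positive")
    mean = estimate.mean_pct if isinstance(estimate, EfficiencyEstimate) else float(estimate)
    return mean < limit_pct


def fold_improvement(efficiency_new_pct: float, efficiency_old_pct: float) -> float:
    """Ratio of two efficiencies (e.g. evolved over parent pair)."""
    if efficiency_old_pct <= 0 or efficiency_new_pct <= 0:
        raise ValueError("efficiencies must be positive")
    return efficiency_new_pct / efficiency_old_pct


# -- multi-site incorporation ----------------------------------------------


@dataclass(frozen=True)
class YieldModel:
    """Independent per-site incorporation: efficiency ``p`` at each of ``n`` codons."""

    p: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("single-site efficiency p must lie in [0, 1]")
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError("site count n must be a non-negative integer")
        object.__setattr__(self, "n", int(self.n))

    def yield_fraction(self) -> float:
        return multi_site_yield(self)

    def distribution(self) -> np.ndarray:
        return species_distribution(self)


def multi_site_yield(model: YieldModel) -> float:
    """Expected fraction of protein with the intended amino acid at *all* sites.

    With independent incorporation the fully-substituted yield drops as the
    n-th power of the single-site efficiency: p=0.5 at n=3 sites gives 0.125.
    """
    return model.p ** model.n


def species_distribution(model: YieldModel) -> np.ndarray:
    """Binomial mixture over k = number of substituted sites, k = 0..n.

    Fractional reassignment of a sense codon yields full-length protein either
    way, so the product is a heterogeneous mixture of 2**n sequence species;
    grouping by occupancy count k gives P(k) = C(n,k) p^k (1-p)^(n-k).
    ``P(n)`` equals :func:`multi_site_yield`.
    """
    p, n = model.p, model.n
    return np.array([math.comb(n, k) * p**k * (1.0 - p) ** (n - k) for k in range(n + 1)])


# -- plate-reader CSV workflow ---------------------------------------------

PLATE_COLUMNS = ("time_min", "well", "od600", "fluor")
MAP_COLUMNS = ("well", "sample", "role")
ROLES = ("test", "ref100", "ref0", "blank")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_plate_reader(path: str | Path) -> pd.DataFrame:
    """Long-format plate-reader CSV with columns time_min, well, od600, fluor."""
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    return df


def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Well-to-role map CSV with columns well, sample, role.

    Roles: ``test`` (one sample may span several replicate wells), ``ref100``,
    ``ref0`` (averaged within the plate), ``blank`` (ignored by the
    efficiency statistic).
    """
    df = pd.read_csv(path)
    _require_columns(df, MAP_COLUMNS, path)
    bad = sorted(set(df["role"]) - set(ROLES))
    if bad:
        raise ValueError(f"{path}: unknown role(s) {bad}; expected one of {ROLES}")
    return df


def _series_by_well(reads: pd.DataFrame) -> dict[str, FluorescenceTimeSeries]:
    out = {}
    for well, grp in reads.groupby("well"):
        grp = grp.sort_values("time_min")
        out[str(well)] = FluorescenceTimeSeries(
            label=str(well),
            time_min=grp["time_min"].to_numpy(),
            od600=grp["od600"].to_numpy(),
            fluor=grp["fluor"].to_numpy(),
        )
    return out


def screen_from_plate(
    reads: pd.DataFrame,
    sample_map: pd.DataFrame,
    *,
    window: tuple[float, float] = (0.0, 240.0),
    detection_limit_pct: float = DEFAULT_DETECTION_LIMIT_PCT,
) -> pd.DataFrame:
    """Full plate workflow: window signals, reference averaging, per-sample stats.

    Returns one row per test sample with mean/sd/n efficiency and flags.
    """
    wells = _series_by_well(reads)
    unknown = sorted(set(sample_map["well"].astype(str)) - set(wells))
    if unknown:
        raise ValueError(f"sample map references well(s) absent from reads: {unknown}")

    signals = {
        w: window_signal(series, *window) for w, series in wells.items()
    }

    def role_wells(role: str) -> list[str]:
        return list(sample_map.loc[sample_map["role"] == role, "well"].astype(str))

    ref100_wells = role_wells("ref100")
    ref0_wells = role_wells("ref0")
    if not ref100_wells or not ref0_wells:
        raise ValueError("sample map must assign at least one ref100 and one ref0 well")
    refs = ReferenceSet(
        s100=float(np.mean([signals[w] for w in ref100_wells])),
        s0=float(np.mean([signals[w] for w in ref0_wells])),
    )

    rows = []
    tests = sample_map[sample_map["role"] == "test"]
    for sample, grp in tests.groupby("sample"):
        est = reassignment_efficiency(
            [signals[str(w)] for w in grp["well"]], refs
        )
        rows.append(
            {
                "sample": sample,
                "mean_pct": est.mean_pct,
                "sd_pct": est.sd_pct,
                "n": est.n,
                "below_detection": below_detection(est, detection_limit_pct),
                "out_of_range": est.out_of_range,
            }
        )
    return pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)
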