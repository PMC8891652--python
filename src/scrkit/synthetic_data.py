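"""Synthetic instrument data with known ground truth for every pipeline stage.

Three generators emulate the raw inputs the analysis modules consume:

* logistic OD600 growth curves with a known doubling time and carrying
  capacity (multiplicative lognormal read noise),
* plate-reader fluorescence time series for a two-reference efficiency screen
  — reference wells at the 100% and 0% signal scales and test wells whose
  signal-per-OD is linear in the true efficiency E (exactly the linearity the
  two-reference normalization assumes),
* deconvoluted intact-mass spectra as sums of Gaussian peaks at known species
  masses with known abundances on a regular mass grid.

Noise defaults: multiplicative lognormal for OD and fluorescence (instrument
noise keeps positive quantities positive), a per-well lognormal expression
factor for biological replicate scatter, and additive Gaussian baseline noise
for spectra.  The defaults put the replicate-to-replicate spread of recovered
efficiencies in the low-single-digit percentage-point range typical of
plate-based biological replicates.

Every generator takes its seed from its config: same config, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth_fitness import GrowthCurve
from .screen_quant import FluorescenceTimeSeries

__all__ = [
    "GrowthConfig",
    "ScreenConfig",
    "SpectrumConfig",
    "ScreenDataset",
    "gen_growth_curve",
    "gen_screen_series",
    "gen_spectrum",
    "screen_dataset_to_frames",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _logistic_od(
    t: np.ndarray, od0: float, doubling_time_min: float, capacity: float, lag_min: float
) -> np.ndarray:
    r = np.log(2.0) / doubling_time_min
    tt = np.maximum(t - lag_min, 0.0)
    return capacity / (1.0 + (capacity - od0) / od0 * np.exp(-r * tt))


# -- growth curves ----------------------------------------------------------


@dataclass(frozen=True)
class GrowthConfig:
    """Logistic growth regime; defaults mirror a moderately burdened E. coli
    culture (t_d 40 min, plateau OD 1.2) read every 10 min for 10 h."""

    seed: int = 0
    initial_od: float = 0.01
    doubling_time_min: float = 40.0
    carrying_capacity: float = 1.2
    lag_min: float = 0.0
    noise_cv: float = 0.02
    t_max_min: float = 600.0
    dt_min: float = 10.0

    def __post_init__(self):
        if min(self.initial_od, self.doubling_time_min, self.carrying_capacity,
               self.t_max_min, self.dt_min) <= 0:
            raise ValueError("growth scales must be positive")
        if self.noise_cv < 0 or self.lag_min < 0:
            raise ValueError("noise CV and lag must be non-negative")
        if self.initial_od >= self.carrying_capacity:
            raise ValueError("initial OD must lie below the carrying capacity")


def gen_growth_curve(config: GrowthConfig, label: str = "synthetic") -> GrowthCurve:
    """One noisy logistic OD600 trajectory; ground truth lives in the config."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.t_max_min + config.dt_min / 2, config.dt_min)
    od = _logistic_od(t, config.initial_od, config.doubling_time_min,
                      config.carrying_capacity, config.lag_min)
    od = od * _lognormal_factor(rng, config.noise_cv, t.size)
    return GrowthCurve(time_min=t, od600=od, label=label)


# -- fluorescence screen ----------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """Two-reference screen regime.

    ``true_efficiency`` is the ground-truth reassigned fraction of the test
    system; test-well signal-per-OD is ``s0 + E * (s100 - s0)``.  Instrument
    noise (``noise_cv``) applies per time point; ``replicate_cv`` is a per-well
    lognormal expression factor capturing biological replicate scatter.
    """

    seed: int = 0
    true_efficiency: float = 0.569
    n_replicates: int = 12
    n_reference_wells: int = 12
    s100_per_od: float = 1000.0
    s0_per_od: float = 10.0
    noise_cv: float = 0.05
    replicate_cv: float = 0.03
    initial_od: float = 0.05
    doubling_time_min: float = 40.0
    carrying_capacity: float = 1.2
    t_max_min: float = 240.0
    dt_min: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.true_efficiency <= 1.2):
            raise ValueError("true efficiency must lie in [0, 1.2]")
        if self.s100_per_od <= self.s0_per_od:
            raise ValueError("100% signal scale must exceed the 0% scale")
        if self.n_replicates < 1 or self.n_reference_wells < 1:
            raise ValueError("need at least one test replicate and one reference well")
        if min(self.noise_cv, self.replicate_cv) < 0:
            raise ValueError("noise CVs must be non-negative")


@dataclass(frozen=True)
class ScreenDataset:
    """Generated wells by role, plus the ground truth that produced them."""

    test: tuple[FluorescenceTimeSeries, ...]
    ref100: tuple[FluorescenceTimeSeries, ...]
    ref0: tuple[FluorescenceTimeSeries, ...]
    true_efficiency: float


def _screen_well(
    rng: np.random.Generator,
    config: ScreenConfig,
    label: str,
    signal_per_od: float,
) -> FluorescenceTimeSeries:
    t = np.arange(0.0, config.t_max_min + config.dt_min / 2, config.dt_min)
    od_true = _logistic_od(t, config.initial_od, config.doubling_time_min,
                           config.carrying_capacity, 0.0)
    od = od_true * _lognormal_factor(rng, config.noise_cv, t.size)
    well_factor = float(_lognormal_factor(rng, config.replicate_cv, 1)[0])
    fluor = (signal_per_od * well_factor) * od_true \
        * _lognormal_factor(rng, config.noise_cv, t.size)
    return FluorescenceTimeSeries(label=label, time_min=t, od600=od, fluor=fluor)


def gen_screen_series(config: ScreenConfig) -> ScreenDataset:
    """Replicated test wells plus 100%/0% reference wells, with ground truth.

    The per-well expression factor multiplies the whole fluorescence channel
    (a bright-vs-dim culture), while instrument noise varies point to point;
    OD and fluorescence carry independent instrument noise.
    """
    rng = np.random.default_rng(config.seed)
    e = config.true_efficiency
    s_test = config.s0_per_od + e * (config.s100_per_od - config.s0_per_od)
    test = tuple(
        _screen_well(rng, config, f"test_{i + 1}", s_test)
        for i in range(config.n_replicates)
    )
    ref100 = tuple(
        _screen_well(rng, config, f"ref100_{i + 1}", config.s100_per_od)
        for i in range(config.n_reference_wells)
    )
    ref0 = tuple(
        _screen_well(rng, config, f"ref0_{i + 1}", config.s0_per_od)
        for i in range(config.n_reference_wells)
    )
    return ScreenDataset(test=test, ref100=ref100, ref0=ref0, true_efficiency=e)


def screen_dataset_to_frames(ds: ScreenDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a dataset into the plate-reader reads + sample-map CSV dialect."""
    read_rows = []
    map_rows = []
    for role, wells in (("test", ds.test), ("ref100", ds.ref100), ("ref0", ds.ref0)):
        for ts in wells:
            map_rows.append({"well": ts.label, "sample": role if role != "test" else "test",
                             "role": role})
            for t, od, fl in zip(ts.time_min, ts.od600, ts.fluor):
                read_rows.append(
                    {"time_min": t, "well": ts.label, "od600": od, "fluor": fl}
                )
    return pd.DataFrame(read_rows), pd.DataFrame(map_rows)


# -- mass spectra -----------------------------------------------------------


@dataclass(frozen=True)
class SpectrumConfig:
    """Gaussian-peak profile spectrum on a regular mass grid.

    Default species mirror a ~8.3 kDa single-site reporter: the canonical
    (arginine) species, its +7 Da substitution product, and the +14 Da
    methylated form of each.
    """

    seed: int = 0
    species_masses: tuple[float, ...] = (8308.0, 8315.0, 8322.0, 8329.0)
    abundances: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    peak_width_da: float = 1.0       # Gaussian sigma
    baseline_noise: float = 0.01     # additive Gaussian SD, relative to base peak
    grid_step_da: float = 0.5
    pad_da: float = 20.0
    intensity_scale: float = 1.0e5

    def __post_init__(self):
        if len(self.species_masses) != len(self.abundances):
            raise ValueError("species masses and abundances must have equal length")
        if len(set(self.species_masses)) != len(self.species_masses):
            raise ValueError("species masses must be distinct")
        if any(a < 0 for a in self.abundances) or sum(self.abundances) <= 0:
            raise ValueError("abundances must be non-negative with positive total")
        if min(self.peak_width_da, self.grid_step_da, self.intensity_scale) <= 0:
            raise ValueError("peak width, grid step and intensity scale must be positive")
        if self.baseline_noise < 0:
            raise ValueError("baseline noise must be non-negative")


def gen_spectrum(config: SpectrumConfig):
    """Profile spectrum: sum of Gaussians plus baseline noise, clipped at zero."""
    from .mass_analysis import DeconvolutedSpectrum  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    lo = min(config.species_masses) - config.pad_da
    hi = max(config.species_masses) + config.pad_da
    grid = np.arange(lo, hi + config.grid_step_da / 2, config.grid_step_da)
    total = sum(config.abundances)
    inten = np.zeros_like(grid)
    for m, a in zip(config.species_masses, config.abundances):
        inten += (a / total) * np.exp(-0.5 * ((grid - m) / config.peak_width_da) ** 2)
    inten *= config.intensity_scale
    if config.baseline_noise > 0:
        inten += rng.normal(0.0, config.baseline_noise * inten.max(), size=grid.size)
    inten = np.clip(inten, 0.0, None)
    return DeconvolutedSpectrum(mass_da=grid, intensity=inten)
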