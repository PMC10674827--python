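"""Synthetic drought field trial with known ground truth.

Emulates a randomized-block tomato trial with three irrigation treatments
(100 / 80 / 40 % plant available water, PAW) and replicate plots, producing
every data stream the multiscale pipeline consumes:

* per-plot 4-band reflectance rasters and canopy-temperature rasters for a
  set of imaging dates (DAT, days after transplant);
* per-plot sRGB canopy photos with controlled green / yellow-green hue
  fractions;
* continuous bioristor current traces with a 24-h diurnal component,
  additive rain/irrigation transients, and a multiplicative drought decline
  that starts at a configurable onset DAT in the deficit treatment;
* hourly meteorology (air temperature, relative humidity, rainfall);
* physiological covariates (RWC, SPAD) and a replicate yield table.

The generator's central latent variable is the per-treatment stress
severity s(t) in [0, 1].  All channels are monotone in s: canopy
temperature rises with s (placed between the CWSI baselines, so plots
rendered at severity s recover CWSI = s under zero noise), green fractions
and the bioristor response fall with s.  For cross-scale correlation
studies, the thermal and bioristor channels can receive independent
Gaussian "channel noise" whose SD is derived analytically from the
empirical severity variance so that the latent channel correlation equals
a configured target (``cross_corr_target``).

Every distribution parameter is exposed on :class:`SimConfig`; with all
noise SDs at zero each downstream index equals its generating parameter
exactly up to pixel quantization (fractional pixel counts are tie-broken
by deterministic raster-order fill).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .containers import BandRaster, BioristorTrace, PlotGeometry, ThermalRaster
from .errors import ConfigurationError, ValidationError
from .thermal import (CWSIBaseline, DEFAULT_BASELINE_A, DEFAULT_BASELINE_B,
                      baseline_limits, vapor_pressure_deficit,
                      vapor_pressure_gradient)

__all__ = [
    "SimConfig",
    "SimTruth",
    "FieldDataset",
    "simulate_field",
    "render_multispectral_plot",
    "render_rgb_canopy",
    "simulate_bioristor_trace",
    "simulate_meteo",
    "simulate_yield",
    "TABLE1_YIELD_MEANS",
    "TABLE1_YIELD_CV",
]

#: per-treatment yield-component means, t/ha (field-trial reference values)
TABLE1_YIELD_MEANS = {
    100: {"marketable": 73.0, "unripen": 23.2, "rotten": 3.9},
    80: {"marketable": 68.2, "unripen": 19.6, "rotten": 6.4},
    40: {"marketable": 50.4, "unripen": 11.4, "rotten": 13.1},
}
#: experimental coefficients of variation (%) per yield component
TABLE1_YIELD_CV = {"marketable": 8.86, "unripen": 17.49, "rotten": 32.82}

_DEFAULT_EVENTS = (
    (38, "rain", 8.0),
    (45, "rain", 12.0),
    (48, "irrigation", 10.0),
    (52, "rain", 5.0),
    (58, "rain", 15.0),
    (62, "irrigation", 10.0),
    (70, "rain", 6.0),
    (76, "irrigation", 10.0),
)


@dataclass
class SimConfig:
    """Study-design and noise parameters for one synthetic trial."""

    treatments: tuple[int, ...] = (100, 80, 40)       # % PAW
    plots_per_treatment: int = 3
    raster_shape: tuple[int, int] = (24, 24)          # pixels per plot patch
    rgb_shape: tuple[int, int] = (48, 48)
    dates: tuple[int, ...] = (43, 47, 50, 56, 62, 66, 74, 81, 89)  # imaging DATs
    trace_start_dat: int = 30
    trace_days: int = 60
    sampling_interval_min: int = 15
    transplant_date: str = "2019-05-01"
    seed: int = 0

    # latent stress-severity model: s = base + amplitude * ramp(DAT)
    base_severity: float = 0.1
    onset_dat: int = 65                                # deficit decline onset
    ramp_days: int = 20
    severity_amplitude: dict = field(
        default_factory=lambda: {100: 0.0, 80: 0.1, 40: 0.8})

    # optional cross-channel coupling (thermal vs bioristor latent corr target)
    cross_corr_target: Optional[float] = None

    # canopy green-fraction trajectories
    green_fraction_max: float = 0.92
    green_fraction_drop: float = 0.35                  # per unit severity
    greener_ratio_max: float = 0.85
    greener_ratio_drop: float = 0.45

    # multispectral / thermal rendering
    veg_reflectance: dict = field(default_factory=lambda: {
        "green": 0.08, "red": 0.05, "red_edge": 0.18, "nir": 0.45})
    soil_reflectance: dict = field(default_factory=lambda: {
        "green": 0.12, "red": 0.20, "red_edge": 0.22, "nir": 0.25})
    reflectance_noise_sd: float = 0.02
    soil_temp_offset: float = 8.0                      # degC above air at flight
    baseline_a: float = DEFAULT_BASELINE_A
    baseline_b: float = DEFAULT_BASELINE_B

    # bioristor trace model
    monitored: str = "paper"                           # "paper" | "all"
    traces_per_plot: int = 5
    r_baseline: float = 1.0
    r_decline_frac: float = 0.75
    diurnal_amplitude: float = 0.12
    trace_noise_sd: float = 0.01
    device_offset_sd: float = 0.015
    ids0_ampere: float = -10e-6
    event_gain: float = 0.02                           # Delta-R per mm
    event_decay_hours: float = 6.0
    events: tuple = _DEFAULT_EVENTS

    # meteorology
    ta_mean: float = 24.0
    ta_diurnal_amplitude: float = 6.0
    rh_mean: float = 62.0
    rh_diurnal_amplitude: float = 18.0
    meteo_noise_sd: float = 0.8

    # physiology covariates
    rwc_max: float = 95.0
    rwc_drop: float = 25.0
    rwc_noise_sd: float = 1.5
    spad_max: float = 50.0
    spad_drop: float = 6.0
    spad_noise_sd: float = 1.5

    # yield
    yield_means: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in TABLE1_YIELD_MEANS.items()})
    yield_cv: dict = field(default_factory=lambda: dict(TABLE1_YIELD_CV))
    yield_replicates: int = 3
    yield_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        def bad(name, why):
            raise ConfigurationError(f"SimConfig.{name}: {why}")

        if self.plots_per_treatment < 2:
            bad("plots_per_treatment", "must be >= 2")
        if list(self.dates) != sorted(set(self.dates)):
            bad("dates", "must be strictly increasing")
        lo, hi = self.trace_start_dat, self.trace_start_dat + self.trace_days
        if self.dates and not (lo <= self.dates[0] and self.dates[-1] <= hi):
            bad("dates", f"imaging dates must lie within the monitored window "
                         f"[{lo}, {hi}] DAT")
        for name in ("base_severity", "green_fraction_max", "green_fraction_drop",
                     "greener_ratio_max", "greener_ratio_drop"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                bad(name, f"fraction parameter {v} outside [0, 1]")
        for name in ("reflectance_noise_sd", "trace_noise_sd", "device_offset_sd",
                     "meteo_noise_sd", "rwc_noise_sd", "spad_noise_sd",
                     "yield_noise_scale"):
            if getattr(self, name) < 0:
                bad(name, "noise SD must be >= 0")
        for t in self.treatments:
            if t not in self.severity_amplitude:
                bad("severity_amplitude", f"missing treatment {t}")
            if t not in self.yield_means:
                bad("yield_means", f"missing treatment {t}")
        if self.monitored not in ("paper", "all"):
            bad("monitored", "must be 'paper' or 'all'")
        if self.cross_corr_target is not None and not 0 < self.cross_corr_target < 1:
            bad("cross_corr_target", "must lie in (0, 1)")
        if self.ids0_ampere == 0:
            bad("ids0_ampere", "reference current must be nonzero")
        if self.yield_replicates < 2:
            bad("yield_replicates", "must be >= 2")

    @property
    def baseline(self) -> CWSIBaseline:
        return CWSIBaseline(self.baseline_a, self.baseline_b)

    def severity(self, treatment: int, dat) -> np.ndarray:
        """Latent stress severity s(treatment, DAT) in [0, 1]."""
        ramp = np.clip((np.asarray(dat, dtype=float) - self.onset_dat)
                       / self.ramp_days, 0.0, 1.0)
        return np.clip(self.base_severity
                       + self.severity_amplitude[treatment] * ramp, 0.0, 1.0)


@dataclass
class SimTruth:
    """Ground truth of a simulated trial, keyed by (plot_id, DAT)."""

    vegetation_masks: dict
    green_fraction: dict
    greener_fraction: dict
    stress_severity: dict          # base latent severity
    thermal_severity: dict         # severity as rendered in the thermal channel
    yield_means: dict

    def __post_init__(self) -> None:
        for key, gf in self.green_fraction.items():
            if self.greener_fraction[key] > gf + 1e-12:
                raise ValidationError(
                    f"truth inconsistency at {key}: greener_fraction > green_fraction")


@dataclass
class FieldDataset:
    """Complete synthetic trial: all sensor streams plus ground truth."""

    config: SimConfig
    plots: list
    bands: dict                    # (plot_id, dat) -> BandRaster
    thermal: dict                  # (plot_id, dat) -> ThermalRaster
    rgb: dict                      # (plot_id, dat) -> uint8 image
    traces: list                   # BioristorTrace
    meteo: pd.DataFrame            # hourly: timestamp, ta, rh, rainfall
    physio: pd.DataFrame           # plot_id, dat, rwc, spad
    yields: pd.DataFrame           # treatment, replicate, components, total
    truth: SimTruth

    def treatment_of(self, plot_id: str) -> int:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p.treatment
        raise KeyError(plot_id)

    def flight_meteo(self, dat: int) -> tuple[float, float]:
        """(Ta, RH) of the meteo record at the flight time (noon of DAT)."""
        t0 = pd.Timestamp(self.config.transplant_date)
        when = t0 + pd.Timedelta(days=int(dat), hours=12)
        row = self.meteo.loc[pd.to_datetime(self.meteo["timestamp"]) == when]
        if row.empty:
            raise ValidationError(f"no meteo record at {when}")
        return float(row["ta"].iloc[0]), float(row["rh"].iloc[0])


def _fill_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Deterministic raster-order fill: first round(fraction*n) pixels True."""
    n = shape[0] * shape[1]
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[:k] = True
    return mask.reshape(shape)


def render_multispectral_plot(
    green_fraction: float,
    stress_severity: float,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (24, 24),
    ta: float = 25.0,
    rh: float = 50.0,
    baseline: Optional[CWSIBaseline] = None,
    veg_reflectance: Optional[dict] = None,
    soil_reflectance: Optional[dict] = None,
    thermal_noise_sd: Optional[float] = None,
    soil_temp_offset: float = 8.0,
) -> tuple[BandRaster, ThermalRaster, np.ndarray]:
    """Render one plot patch: 4-band reflectance, canopy temperature, truth mask.

    Vegetation pixels get NIR >> red reflectance (high NDVI), soil pixels
    NIR ~ red.  Canopy temperature is placed between the CWSI baselines at
    position ``stress_severity``: Tc = Ta + LL + s*(UL - LL), so the index
    recovered downstream equals s when noise is zero.  ``stress_severity``
    may leave [0, 1] when a coupling channel adds noise; the physical Tc is
    simply colder/hotter than the limits then.  ``thermal_noise_sd`` defaults
    to ``7.5 * noise_sd`` degC so a single knob controls both sensors.
    """
    if not 0 <= green_fraction <= 1:
        raise ValidationError(f"green_fraction {green_fraction} outside [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    baseline = baseline or CWSIBaseline(DEFAULT_BASELINE_A, DEFAULT_BASELINE_B)
    veg = veg_reflectance or {"green": 0.08, "red": 0.05, "red_edge": 0.18, "nir": 0.45}
    soil = soil_reflectance or {"green": 0.12, "red": 0.20, "red_edge": 0.22, "nir": 0.25}
    if thermal_noise_sd is None:
        thermal_noise_sd = 7.5 * noise_sd

    rng = np.random.default_rng(seed)
    mask = _fill_mask(shape, green_fraction)

    grids = {}
    for band in ("green", "red", "red_edge", "nir"):
        g = np.where(mask, veg[band], soil[band]).astype(float)
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, size=shape)
        grids[band] = np.clip(g, 0.0, None)
    raster = BandRaster(**grids)

    vpd = vapor_pressure_deficit(ta, rh)
    vpg = vapor_pressure_gradient(ta, baseline.a)
    ll, ul = baseline_limits(vpd, vpg, baseline)
    tc_veg = ta + ll + stress_severity * (ul - ll)
    tc = np.where(mask, tc_veg, ta + soil_temp_offset).astype(float)
    if thermal_noise_sd > 0:
        tc = tc + rng.normal(0.0, thermal_noise_sd, size=shape)
    return raster, ThermalRaster(tc), mask


def render_rgb_canopy(
    green_fraction: float,
    greener_fraction: float,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (48, 48),
) -> np.ndarray:
    """Render a canopy photo with controlled hue-class fractions.

    The first ``round(greener_fraction*n)`` pixels (raster order) get hues in
    [95, 160] degrees (deep green), the next block up to
    ``round(green_fraction*n)`` hues in [64, 76] (yellow-green: inside the GA
    range but outside GGA), and the remainder soil/senescent hues in
    [15, 45].  Hue margins of >= 4 degrees from the 60/80/180 thresholds
    absorb 8-bit quantization and the HSI-vs-HSV hue discrepancy.
    """
    if not 0 <= green_fraction <= 1:
        raise ValidationError(f"green_fraction {green_fraction} outside [0, 1]")
    if not 0 <= greener_fraction <= 1:
        raise ValidationError(f"greener_fraction {greener_fraction} outside [0, 1]")
    if greener_fraction > green_fraction:
        raise ValidationError(
            f"greener_fraction {greener_fraction} exceeds green_fraction {green_fraction}")
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    n_ga = int(round(green_fraction * n))
    n_gga = min(int(round(greener_fraction * n)), n_ga)

    hue = np.empty(n)
    hue[:n_gga] = rng.uniform(95, 160, n_gga)
    hue[n_gga:n_ga] = rng.uniform(64, 76, n_ga - n_gga)
    hue[n_ga:] = rng.uniform(15, 45, n - n_ga)
    sat = rng.uniform(0.6, 0.9, n)
    val = rng.uniform(0.45, 0.8, n)

    hsv = np.stack([hue / 360.0, sat, val], axis=-1).reshape(*shape, 3)
    rgb = hsv_to_rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def simulate_bioristor_trace(
    plot_id: str,
    stress_schedule: pd.Series,
    events: tuple = (),
    *,
    start_dat: int = 30,
    n_days: int = 60,
    sampling_interval_min: int = 15,
    transplant_date: str = "2019-05-01",
    r_baseline: float = 1.0,
    r_decline_frac: float = 0.75,
    diurnal_amplitude: float = 0.12,
    noise_sd: float = 0.01,
    device_offset: float = 0.0,
    ids0_ampere: float = -10e-6,
    event_gain: float = 0.02,
    event_decay_hours: float = 6.0,
    seed: int = 0,
    replicate: int = 0,
) -> BioristorTrace:
    """One continuous bioristor current trace.

    The underlying response level is ``r_baseline * (1 + device_offset) *
    (1 - r_decline_frac * s(t))`` (multiplicative drought decay), modulated
    by a 24-h sinusoid, plus additive exponential transients at event times
    with amplitude ``event_gain * intensity_mm`` (events enter the current
    additively).  Currents: Ids0 is constant, Ids = Ids0 * (1 + R).

    ``stress_schedule`` is indexed by DAT (int) and must cover the trace
    window [start_dat, start_dat + n_days].
    """
    sched = stress_schedule.sort_index()
    if sched.index.min() > start_dat or sched.index.max() < start_dat + n_days:
        raise ValidationError(
            f"stress_schedule must cover DAT [{start_dat}, {start_dat + n_days}]")
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(transplant_date)
    n = int(n_days * 24 * 60 / sampling_interval_min)
    timestamps = t0 + pd.to_timedelta(
        start_dat * 24 * 60 + np.arange(n) * sampling_interval_min, unit="m")
    dat_frac = (timestamps - t0) / pd.Timedelta(days=1)

    sev = np.interp(dat_frac, sched.index.to_numpy(dtype=float),
                    sched.to_numpy(dtype=float))
    level = r_baseline * (1.0 + device_offset) * (1.0 - r_decline_frac * sev)
    hours = np.asarray(dat_frac, dtype=float) * 24.0
    r = level * (1.0 + diurnal_amplitude * np.sin(2 * np.pi * (hours - 6.0) / 24.0))

    for dat_e, _kind, intensity in events:
        te = dat_e + 10.0 / 24.0          # events land at 10:00 local
        dt_h = (np.asarray(dat_frac, dtype=float) - te) * 24.0
        kernel = np.where(dt_h >= 0, np.exp(-dt_h / event_decay_hours), 0.0)
        r = r + event_gain * intensity * kernel

    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=n)
    r = np.clip(r, 0.0, None)

    ids0 = np.full(n, ids0_ampere)
    ids = ids0 * (1.0 + r)
    return BioristorTrace(plot_id=plot_id, timestamps=pd.DatetimeIndex(timestamps),
                          ids=ids, ids0=ids0, replicate=replicate)


def simulate_meteo(
    days: int,
    seed: int = 0,
    *,
    start_dat: int = 30,
    transplant_date: str = "2019-05-01",
    ta_mean: float = 24.0,
    ta_diurnal_amplitude: float = 6.0,
    rh_mean: float = 62.0,
    rh_diurnal_amplitude: float = 18.0,
    noise_sd: float = 0.8,
    events: tuple = (),
) -> pd.DataFrame:
    """Hourly meteorological series: air temperature (degC, peaking 15:00),
    relative humidity (%, clipped to [0, 100], anti-phase with Ta) and
    rainfall (mm, nonzero in the hour of each rain event)."""
    if days < 1:
        raise ValidationError("days must be >= 1")
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(transplant_date)
    hours = np.arange(days * 24)
    timestamps = t0 + pd.to_timedelta(start_dat * 24 + hours, unit="h")
    hod = (start_dat * 24 + hours) % 24

    phase = np.sin(2 * np.pi * (hod - 9.0) / 24.0)    # peaks at 15:00
    ta = ta_mean + ta_diurnal_amplitude * phase
    rh = rh_mean - rh_diurnal_amplitude * phase
    if noise_sd > 0:
        ta = ta + rng.normal(0.0, noise_sd, len(hours))
        rh = rh + rng.normal(0.0, 2.0 * noise_sd, len(hours))
    rh = np.clip(rh, 0.0, 100.0)

    rain = np.zeros(len(hours))
    for dat_e, kind, intensity in events:
        if kind != "rain":
            continue
        idx = (dat_e - start_dat) * 24 + 10
        if 0 <= idx < len(rain):
            rain[idx] += intensity
    return pd.DataFrame({"timestamp": timestamps, "ta": ta, "rh": rh,
                         "rainfall": rain})


def simulate_yield(
    treatment_means: dict,
    noise_sd,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate yield table around per-treatment component means (t/ha).

    ``treatment_means`` maps treatment -> {marketable, unripen, rotten};
    ``noise_sd`` is either a scalar SD applied to every component or a
    per-component dict.  Components are truncated at zero; the total is the
    component sum, so additivity holds exactly for every replicate.
    """
    if replicates < 2:
        raise ValidationError("replicates must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in sorted(treatment_means, reverse=True):
        means = treatment_means[treatment]
        for rep in range(1, replicates + 1):
            row = {"treatment": treatment, "replicate": rep}
            for trait in ("marketable", "unripen", "rotten"):
                sd = noise_sd[trait] if isinstance(noise_sd, dict) else noise_sd
                v = means[trait] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                row[trait] = max(v, 0.0)
            row["total"] = row["marketable"] + row["unripen"] + row["rotten"]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_field(config: SimConfig) -> FieldDataset:
    """Generate the complete synthetic trial; deterministic for a fixed seed."""
    if not isinstance(config, SimConfig):
        raise ConfigurationError("simulate_field expects a SimConfig")
    root = np.random.default_rng(config.seed)
    next_seed = lambda: int(root.integers(2 ** 31))  # noqa: E731

    plots = [
        PlotGeometry(plot_id=f"T{t}_P{i}", treatment=t,
                     row_min=0, row_max=config.raster_shape[0],
                     col_min=0, col_max=config.raster_shape[1])
        for t in config.treatments
        for i in range(1, config.plots_per_treatment + 1)
    ]

    meteo = simulate_meteo(
        config.trace_days + 1, next_seed(),
        start_dat=config.trace_start_dat,
        transplant_date=config.transplant_date,
        ta_mean=config.ta_mean, ta_diurnal_amplitude=config.ta_diurnal_amplitude,
        rh_mean=config.rh_mean, rh_diurnal_amplitude=config.rh_diurnal_amplitude,
        noise_sd=config.meteo_noise_sd, events=config.events)
    meteo_ts = pd.to_datetime(meteo["timestamp"])
    t0 = pd.Timestamp(config.transplant_date)

    # latent severities and optional channel noise for cross-scale coupling
    sev_base = {
        (p.plot_id, d): float(config.severity(p.treatment, d))
        for p in plots for d in config.dates
    }
    if config.cross_corr_target is not None:
        rho = config.cross_corr_target
        var_s = float(np.var(list(sev_base.values())))
        if var_s == 0:
            warnings.warn("severity has zero variance; cross_corr_target has "
                          "no effect", stacklevel=2)
            channel_sd = 0.0
        else:
            channel_sd = float(np.sqrt(var_s * (1.0 - rho) / rho))
    else:
        channel_sd = 0.0
    chan_rng = np.random.default_rng(next_seed())
    sev_thermal = {k: v + (chan_rng.normal(0.0, channel_sd) if channel_sd else 0.0)
                   for k, v in sev_base.items()}
    # bioristor channel noise: one draw per (plot, imaging date), held constant
    # over the surrounding days so daily smoothing cannot average it away
    bio_noise = {k: (chan_rng.normal(0.0, channel_sd) if channel_sd else 0.0)
                 for k in sev_base}

    # imaging products
    bands, thermal, rgb_images, masks = {}, {}, {}, {}
    gf_truth, ggf_truth = {}, {}
    for p in plots:
        for d in config.dates:
            key = (p.plot_id, d)
            s = sev_base[key]
            gf = float(np.clip(config.green_fraction_max
                               * (1.0 - config.green_fraction_drop * s), 0.0, 1.0))
            ggf = float(np.clip(gf * (config.greener_ratio_max
                                      - config.greener_ratio_drop * s), 0.0, gf))
            gf_truth[key], ggf_truth[key] = gf, ggf

            when = t0 + pd.Timedelta(days=int(d), hours=12)
            row = meteo.loc[meteo_ts == when]
            ta = float(row["ta"].iloc[0])
            rh = float(row["rh"].iloc[0])
            raster, th, mask = render_multispectral_plot(
                gf, sev_thermal[key], config.reflectance_noise_sd, next_seed(),
                shape=config.raster_shape, ta=ta, rh=rh, baseline=config.baseline,
                veg_reflectance=config.veg_reflectance,
                soil_reflectance=config.soil_reflectance,
                soil_temp_offset=config.soil_temp_offset)
            bands[key], thermal[key], masks[key] = raster, th, mask
            rgb_images[key] = render_rgb_canopy(gf, ggf, next_seed(),
                                                shape=config.rgb_shape)

    # bioristor traces: daily severity schedule per plot + channel noise
    day_grid = np.arange(config.trace_start_dat,
                         config.trace_start_dat + config.trace_days + 1)
    if config.monitored == "paper":
        monitored = [p for p in plots if p.plot_id.endswith("_P1")]
        traces_per_plot = config.traces_per_plot
    else:
        monitored = list(plots)
        traces_per_plot = 1
    traces = []
    dates_arr = np.asarray(config.dates, dtype=float)
    for p in monitored:
        sched_base = config.severity(p.treatment, day_grid)
        nearest_date = dates_arr[np.abs(day_grid[:, None] - dates_arr).argmin(axis=1)]
        day_noise = np.array([bio_noise[(p.plot_id, int(d))] for d in nearest_date])
        sched = pd.Series(sched_base + day_noise, index=day_grid)
        for rep in range(traces_per_plot):
            dev = (np.random.default_rng(next_seed()).normal(0.0, config.device_offset_sd)
                   if config.device_offset_sd > 0 else 0.0)
            traces.append(simulate_bioristor_trace(
                p.plot_id, sched, config.events,
                start_dat=config.trace_start_dat, n_days=config.trace_days,
                sampling_interval_min=config.sampling_interval_min,
                transplant_date=config.transplant_date,
                r_baseline=config.r_baseline, r_decline_frac=config.r_decline_frac,
                diurnal_amplitude=config.diurnal_amplitude,
                noise_sd=config.trace_noise_sd, device_offset=dev,
                ids0_ampere=config.ids0_ampere, event_gain=config.event_gain,
                event_decay_hours=config.event_decay_hours,
                seed=next_seed(), replicate=rep))

    # physiology covariates
    phys_rng = np.random.default_rng(next_seed())
    phys_rows = []
    for p in plots:
        for d in config.dates:
            s = sev_base[(p.plot_id, d)]
            rwc = config.rwc_max - config.rwc_drop * s
            spad = config.spad_max - config.spad_drop * s
            if config.rwc_noise_sd > 0:
                rwc += phys_rng.normal(0.0, config.rwc_noise_sd)
            if config.spad_noise_sd > 0:
                spad += phys_rng.normal(0.0, config.spad_noise_sd)
            phys_rows.append({"plot_id": p.plot_id, "dat": d,
                              "rwc": float(np.clip(rwc, 0.0, 100.0)),
                              "spad": float(max(spad, 0.0))})
    physio = pd.DataFrame(phys_rows)

    noise_sd = {t: config.yield_noise_scale * cv / 100.0
                * float(np.mean([m[t] for m in config.yield_means.values()]))
                for t, cv in config.yield_cv.items()}
    yields = simulate_yield(config.yield_means, noise_sd,
                            config.yield_replicates, next_seed())

    truth = SimTruth(
        vegetation_masks=masks,
        green_fraction=gf_truth,
        greener_fraction=ggf_truth,
        stress_severity=sev_base,
        thermal_severity=sev_thermal,
        yield_means={t: dict(m, total=sum(m.values()))
                     for t, m in config.yield_means.items()},
    )
    return FieldDataset(config=config, plots=plots, bands=bands, thermal=thermal,
                        rgb=rgb_images, traces=traces, meteo=meteo, physio=physio,
                        yields=yields, truth=truth)
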