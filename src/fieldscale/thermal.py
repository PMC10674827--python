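"""Crop Water Stress Index (CWSI) from canopy and air temperature.

The empirical (Idso-style) CWSI normalises the canopy-air temperature
difference between two linear baselines in vapour-pressure space::

    CWSI = ((Tc - Ta) - LL) / (UL - LL)
    LL   = a + b * VPD        # lower limit: well-watered, transpiring canopy
    UL   = a + b * VPG        # upper limit: non-transpiring canopy

where VPD is the vapour pressure deficit of the air and VPG the (negative)
saturation-pressure difference es(Ta) - es(Ta + a).  With the usual b < 0,
VPD > 0 and VPG < 0, UL > LL and CWSI maps 0 (unstressed) to 1 (fully
stressed).  Saturation vapour pressure uses the Tetens formula in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CWSIRecord, PlotGeometry, ThermalRaster
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "CWSIBaseline",
    "saturation_vapor_pressure",
    "vapor_pressure_deficit",
    "vapor_pressure_gradient",
    "baseline_limits",
    "fit_baseline",
    "cwsi",
    "cwsi_plot_means",
    "meteo_at",
]

#: default non-water-stressed baseline for tomato (Idso-type coefficients):
#: Tc - Ta = 2.86 - 1.96 * VPD  [degC, degC/kPa]
DEFAULT_BASELINE_A = 2.86
DEFAULT_BASELINE_B = -1.96


@dataclass(frozen=True)
class CWSIBaseline:
    """Linear non-water-stressed baseline Tc - Ta = a + b * VPD."""

    a: float  # intercept, degC
    b: float  # slope, degC/kPa

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValidationError("baseline coefficients must be finite")
        if self.b >= 0:
            warnings.warn(
                f"baseline slope b={self.b:g} >= 0; a non-water-stressed "
                "baseline normally has b < 0",
                stacklevel=2,
            )


def saturation_vapor_pressure(t_celsius):
    """Saturation vapour pressure es(T) in kPa (Tetens formula).

    Valid for air temperatures in the physically plausible range
    [-40, 60] degC; values outside raise a :class:`ValidationError`.
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t < -40) or np.any(t > 60):
        raise ValidationError("temperature outside the plausible range [-40, 60] degC")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(es) if np.isscalar(t_celsius) else es


def vapor_pressure_deficit(ta_celsius, rh_percent):
    """VPD = es(Ta) * (1 - RH/100), kPa."""
    rh = np.asarray(rh_percent, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValidationError("relative humidity must lie in [0, 100] %")
    vpd = saturation_vapor_pressure(ta_celsius) * (1.0 - rh / 100.0)
    return float(vpd) if np.isscalar(rh_percent) else vpd


def vapor_pressure_gradient(ta_celsius, a_offset):
    """VPG = es(Ta) - es(Ta + a), kPa; negative whenever a > 0.

    The offset reuses the baseline intercept ``a`` (degC), following the
    empirical-CWSI convention.
    """
    return saturation_vapor_pressure(ta_celsius) - saturation_vapor_pressure(
        np.asarray(ta_celsius, dtype=float) + a_offset
    )


def baseline_limits(vpd: float, vpg: float, base: CWSIBaseline) -> tuple[float, float]:
    """Lower and upper canopy-air temperature limits (LL, UL) in degC.

    Raises :class:`DegenerateInputError` when UL <= LL (CWSI undefined).
    """
    ll = base.a + base.b * vpd
    ul = base.a + base.b * vpg
    if not ul > ll:
        raise DegenerateInputError(
            f"degenerate baseline: UL={ul:g} <= LL={ll:g} "
            f"(a={base.a:g}, b={base.b:g}, VPD={vpd:g}, VPG={vpg:g})"
        )
    return ll, ul


def fit_baseline(tc_minus_ta: Sequence[float], vpd: Sequence[float]) -> CWSIBaseline:
    """Fit the non-water-stressed baseline by ordinary least squares.

    ``tc_minus_ta`` observations (degC) from well-watered reference plots are
    regressed on the concurrent ``vpd`` (kPa).  At least two observations
    with distinct VPD are required.

    Returns the fitted :class:`CWSIBaseline`; the per-coefficient standard
    errors are attached as ``.fit_`` metadata on the returned object via
    :func:`fit_baseline_full` when needed.
    """
    base, _ = fit_baseline_full(tc_minus_ta, vpd)
    return base


def fit_baseline_full(tc_minus_ta, vpd):
    """As :func:`fit_baseline`, also returning the scipy linregress result
    (slope/intercept standard errors for coverage checks)."""
    y = np.asarray(tc_minus_ta, dtype=float)
    x = np.asarray(vpd, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("tc_minus_ta and vpd must be 1-D of equal length")
    if len(np.unique(x)) < 2:
        raise ValidationError("need at least 2 distinct VPD values to fit a baseline")
    res = sps.linregress(x, y)
    return CWSIBaseline(a=float(res.intercept), b=float(res.slope)), res


def cwsi(tc, ta, vpd, vpg, base: CWSIBaseline, *, clip: bool = True):
    """Crop Water Stress Index for canopy temperature ``tc`` (degC).

    Returns the clipped-to-[0, 1] headline value by default; pass
    ``clip=False`` for the raw value.  Vectorised over ``tc``.
    """
    ll, ul = baseline_limits(vpd, vpg, base)
    raw = (np.asarray(tc, dtype=float) - ta - ll) / (ul - ll)
    out = np.clip(raw, 0.0, 1.0) if clip else raw
    return float(out) if np.isscalar(tc) else out


def meteo_at(meteo: pd.DataFrame, when: pd.Timestamp,
             tolerance: Optional[pd.Timedelta] = None) -> pd.Series:
    """Nearest meteorological record to ``when``.

    ``meteo`` must have a ``timestamp`` column plus ``ta`` (degC) and ``rh``
    (%).  ``tolerance`` bounds the allowed time gap (default 3 h).
    """
    if tolerance is None:
        tolerance = pd.Timedelta(hours=3)
    ts = pd.to_datetime(meteo["timestamp"])
    gaps = (ts - pd.Timestamp(when)).abs()
    i = int(gaps.idxmin())
    if gaps.loc[i] > tolerance:
        raise ValidationError(
            f"no meteo record within {tolerance} of {when} (closest gap {gaps.loc[i]})"
        )
    return meteo.loc[i]


def cwsi_plot_means(
    thermal: ThermalRaster,
    mask: np.ndarray,
    plots: Iterable[PlotGeometry],
    dat: int,
    ta: float,
    rh: float,
    base: CWSIBaseline,
) -> list[CWSIRecord]:
    """Per-plot CWSI from mean canopy temperature over vegetation pixels.

    ``mask`` selects pure vegetation pixels; plots with no vegetation pixels
    yield a missing (NaN) CWSI with a warning.
    """
    if mask.shape != thermal.shape:
        raise ValidationError("vegetation mask shape does not match the thermal grid")
    vpd = vapor_pressure_deficit(ta, rh)
    vpg = vapor_pressure_gradient(ta, base.a)
    records = []
    for plot in plots:
        if not plot.within(thermal.shape):
            raise ValidationError(f"plot {plot.plot_id!r} lies outside the raster")
        rs, cs = plot.slices()
        sel = mask[rs, cs]
        if thermal.nodata is not None:
            sel = sel & ~thermal.nodata[rs, cs]
        vals = thermal.tc[rs, cs][sel]
        if vals.size == 0:
            warnings.warn(f"plot {plot.plot_id!r} has no vegetation pixels at DAT {dat}",
                          stacklevel=2)
            tc_mean = np.nan
        else:
            tc_mean = float(vals.mean())
        raw = cwsi(tc_mean, ta, vpd, vpg, base, clip=False) if np.isfinite(tc_mean) else np.nan
        records.append(
            CWSIRecord(
                plot_id=plot.plot_id,
                dat=dat,
                cwsi=float(np.clip(raw, 0.0, 1.0)) if np.isfinite(raw) else np.nan,
                cwsi_raw=raw,
                tc_minus_ta=tc_mean - ta if np.isfinite(tc_mean) else np.nan,
                vpd=vpd,
                vpg=vpg,
            )
        )
    return records
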