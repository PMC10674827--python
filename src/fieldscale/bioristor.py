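"""In-vivo bioristor (stem OECT) signal processing.

The sensor response is the relative modulation of the drain-source current
under gate bias::

    R = |Ids - Ids0| / |Ids0|

with Ids measured at Vg = 0.5 V and Ids0 the ungated reference (Vg = 0 V).
R tracks the cation concentration in the transpiration stream: it rises
transiently with rain/irrigation events and declines persistently under
drought.  Downstream processing smooths the day/night oscillation with a
24-h centred moving average, averages per day (DAT), and min-max normalises
to [0, 1] for display.

The denominator uses |Ids0| so R is non-negative for the negative channel
currents measured under Vds = -0.1 V (configurable via ``signed=True``).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps

from .containers import BioristorTrace
from .errors import ValidationError

__all__ = [
    "compute_response",
    "daily_smooth",
    "minmax_normalize",
    "detect_events",
    "treatment_divergence",
]


def compute_response(trace: BioristorTrace, *, signed: bool = False) -> pd.Series:
    """Raw sensor response R per sample, indexed by timestamp.

    Samples with Ids0 == 0 become NaN (with a warning); an all-zero Ids0
    channel raises :class:`ValidationError`.  With ``signed=True`` the
    printed formula |Ids - Ids0| / Ids0 is used verbatim (can be negative
    when Ids0 < 0).
    """
    ids0 = trace.ids0
    if np.all(ids0 == 0):
        raise ValidationError(f"trace {trace.plot_id!r}: Ids0 is zero everywhere")
    zero = ids0 == 0
    if np.any(zero):
        warnings.warn(
            f"trace {trace.plot_id!r}: {int(zero.sum())} samples with Ids0 == 0 "
            "set to missing", stacklevel=2)
    denom = ids0 if signed else np.abs(ids0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(trace.ids - ids0) / np.where(zero, np.nan, denom)
    out = pd.Series(r, index=trace.timestamps, name="r")
    out.attrs.update(plot_id=trace.plot_id, replicate=trace.replicate)
    return out


def daily_smooth(
    series: pd.Series,
    window_hours: float = 24.0,
    transplant_date: Optional[pd.Timestamp] = None,
) -> pd.Series:
    """Centred moving average over ``window_hours``, then per-day mean.

    Returns one value per day, indexed by DAT when ``transplant_date`` is
    given, else by calendar date.  Requires regular sampling; missing samples
    are skipped.  A series shorter than one window collapses to a single
    best-effort mean with a warning.
    """
    if series.empty:
        raise ValidationError("cannot smooth an empty series")
    deltas = series.index.to_series().diff().dropna()
    if not deltas.empty:
        step = deltas.median()
        if (deltas.max() - deltas.min()) > pd.Timedelta(seconds=1):
            warnings.warn("irregular sampling detected; window size uses the "
                          "median interval", stacklevel=2)
        window = max(1, int(round(pd.Timedelta(hours=window_hours) / step)))
    else:
        window = 1
    if window > len(series):
        warnings.warn("series shorter than one smoothing window; returning a "
                      "single mean", stacklevel=2)
        window = len(series)
    smoothed = series.rolling(window, center=True, min_periods=max(1, window // 2)).mean()
    days = smoothed.index.normalize()
    daily = smoothed.groupby(days).mean()
    if transplant_date is not None:
        t0 = pd.Timestamp(transplant_date).normalize()
        daily.index = ((daily.index - t0).days).astype(int)
        daily.index.name = "dat"
    daily.name = series.name
    daily.attrs.update(series.attrs)
    return daily


def minmax_normalize(series: pd.Series) -> pd.Series:
    """Min-max scale onto [0, 1]; a constant series maps to zeros with a
    warning (undefined range)."""
    if series.empty:
        raise ValidationError("cannot normalize an empty series")
    lo, hi = series.min(), series.max()
    if hi == lo:
        warnings.warn("constant series: min-max normalization undefined, "
                      "returning zeros", stacklevel=2)
        out = series * 0.0
    else:
        out = (series - lo) / (hi - lo)
    out.attrs.update(series.attrs)
    return out


def detect_events(series: pd.Series, min_prominence: float) -> pd.DataFrame:
    """Transient R peaks (rain/irrigation signatures).

    Local maxima with prominence >= ``min_prominence`` over the surrounding
    baseline; returns a DataFrame with columns ``time`` (index value of the
    peak) and ``amplitude`` (peak prominence, proportional to event
    intensity).
    """
    x = series.to_numpy(dtype=float)
    finite = np.isfinite(x)
    xi = np.where(finite, x, np.nanmin(x[finite]) if finite.any() else 0.0)
    peaks, props = spsig.find_peaks(xi, prominence=min_prominence)
    return pd.DataFrame({
        "time": series.index[peaks],
        "amplitude": props["prominences"],
    })


def treatment_divergence(
    daily: pd.DataFrame,
    alpha: float = 0.001,
    consecutive: int = 3,
) -> tuple[Optional[int], pd.Series]:
    """First DAT of sustained treatment separation in the daily R series.

    ``daily`` has columns ``dat``, ``treatment``, ``trace_id``, ``r`` with
    one row per trace per day.  A one-way ANOVA across treatments is run per
    day; the divergence onset is the first DAT from which p <= alpha holds
    for ``consecutive`` consecutive observed days.  Returns
    ``(onset_dat or None, per-day p-value Series)``.
    """
    required = {"dat", "treatment", "trace_id", "r"}
    if not required.issubset(daily.columns):
        raise ValidationError(f"daily table must have columns {sorted(required)}")
    if daily["treatment"].nunique() < 2:
        raise ValidationError("need at least 2 treatments")
    pvals = {}
    for dat, day in daily.groupby("dat"):
        groups = [g["r"].dropna().to_numpy() for _, g in day.groupby("treatment")]
        if any(len(g) < 2 for g in groups):
            raise ValidationError(
                f"DAT {dat}: every treatment needs >= 2 replicate traces")
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            pvals[dat] = np.nan  # identical data: no evidence of separation
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[dat] = sps.f_oneway(*groups).pvalue
    p = pd.Series(pvals).sort_index()
    p.index.name = "dat"
    p.name = "p"

    sig = (p <= alpha).to_numpy()
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= consecutive:
            return int(p.index[i - consecutive + 1]), p
    return None, p
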