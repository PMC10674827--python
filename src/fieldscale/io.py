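"""Readers/writers for every external format the pipeline touches.

Rasters are plain multi-band float32 TIFFs (band order green, red,
red edge, NIR for the 4-band files); images are 8-bit sRGB PNG/JPEG;
tables are UTF-8 CSV with ISO-8601 timestamps and empty cells for missing
values.  All coordinates are row-major, 0-based, with half-open plot
bounding boxes — the single convention used by every module.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .containers import BAND_ORDER, BandRaster, BioristorTrace, PlotGeometry, ThermalRaster
from .errors import ConfigurationError, RasterIOError, ValidationError

__all__ = [
    "read_band_raster", "write_band_raster",
    "read_thermal", "write_thermal",
    "read_rgb", "write_rgb",
    "read_table", "write_table", "TableSchema",
    "read_trace", "write_trace",
    "read_plots", "write_plots",
    "write_dataset",
    "PipelineConfig", "load_config",
    "METEO_SCHEMA", "YIELD_SCHEMA", "TRACE_SCHEMA",
]


# ---------------------------------------------------------------- rasters

def write_band_raster(path, raster: BandRaster) -> None:
    """4-band float32 TIFF in canonical band order; nodata encoded as NaN."""
    stack = raster.stack()
    if raster.nodata is not None:
        stack = stack.copy()
        stack[:, raster.nodata] = np.nan
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_band_raster(path) -> BandRaster:
    try:
        stack = np.asarray(tifffile.imread(str(path)), dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc
    if stack.ndim != 3 or stack.shape[0] != len(BAND_ORDER):
        raise RasterIOError(
            f"{path}: expected {len(BAND_ORDER)} bands "
            f"({', '.join(BAND_ORDER)}), got shape {stack.shape}")
    nodata = np.isnan(stack).any(axis=0)
    stack = np.nan_to_num(stack, nan=0.0)
    return BandRaster.from_stack(stack, nodata=nodata if nodata.any() else None)


def write_thermal(path, thermal: ThermalRaster) -> None:
    tc = thermal.tc.astype(np.float32)
    if thermal.nodata is not None:
        tc = tc.copy()
        tc[thermal.nodata] = np.nan
    tifffile.imwrite(str(path), tc, photometric="minisblack")


def read_thermal(path) -> ThermalRaster:
    try:
        tc = np.asarray(tifffile.imread(str(path)), dtype=float)
    except Exception as exc:  # noqa: BLE001
        raise RasterIOError(f"cannot read thermal raster {path}: {exc}") from exc
    if tc.ndim != 2:
        raise RasterIOError(f"{path}: expected a single-band grid, got shape {tc.shape}")
    nodata = np.isnan(tc)
    return ThermalRaster(np.nan_to_num(tc, nan=0.0),
                         nodata=nodata if nodata.any() else None)


def write_rgb(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(str(path))


def read_rgb(path) -> np.ndarray:
    try:
        img = Image.open(str(path))
    except Exception as exc:  # noqa: BLE001
        raise RasterIOError(f"cannot read image {path}: {exc}") from exc
    if img.mode == "RGBA":
        warnings.warn(f"{path}: alpha channel dropped", stacklevel=2)
        img = img.convert("RGB")
    elif img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.uint8)


# ----------------------------------------------------------------- tables

@dataclasses.dataclass(frozen=True)
class TableSchema:
    """CSV column contract: name -> kind in {float, int, str, datetime},
    with optional inclusive (min, max) range checks per column."""

    columns: dict
    ranges: dict = dataclasses.field(default_factory=dict)


METEO_SCHEMA = TableSchema(
    columns={"timestamp": "datetime", "ta": "float", "rh": "float",
             "rainfall": "float"},
    ranges={"rh": (0.0, 100.0), "rainfall": (0.0, None), "ta": (-40.0, 60.0)},
)
YIELD_SCHEMA = TableSchema(
    columns={"treatment": "int", "replicate": "int", "marketable": "float",
             "unripen": "float", "rotten": "float", "total": "float"},
    ranges={c: (0.0, None) for c in ("marketable", "unripen", "rotten", "total")},
)
TRACE_SCHEMA = TableSchema(
    columns={"timestamp": "datetime", "ids_a": "float", "ids0_a": "float"},
)

_CASTERS = {
    "float": lambda s: pd.to_numeric(s, errors="raise"),
    "int": lambda s: pd.to_numeric(s, errors="raise").astype("Int64"),
    "str": lambda s: s.astype(str),
    "datetime": lambda s: pd.to_datetime(s, errors="raise"),
}


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Typed CSV read; missing columns, unparseable cells or out-of-range
    values raise :class:`ValidationError` naming the row (1-based data row)."""
    df = pd.read_csv(path)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col, kind in schema.columns.items():
        try:
            df[col] = _CASTERS[kind](df[col])
        except Exception as exc:  # noqa: BLE001
            raise ValidationError(f"{path}: column {col!r} not parseable as "
                                  f"{kind}: {exc}") from exc
    for col, (lo, hi) in schema.ranges.items():
        v = df[col].astype(float)
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= v < lo
        if hi is not None:
            bad |= v > hi
        bad &= v.notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"{path}: column {col!r} out of range [{lo}, {hi}] at data row {row}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_trace(path, trace: BioristorTrace) -> None:
    write_table(pd.DataFrame({
        "timestamp": trace.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "ids_a": trace.ids,
        "ids0_a": trace.ids0,
    }), path)


def read_trace(path, plot_id: Optional[str] = None, replicate: int = 0) -> BioristorTrace:
    df = read_table(path, TRACE_SCHEMA)
    if plot_id is None:
        plot_id = Path(path).stem.replace("bioristor_", "")
    return BioristorTrace(plot_id=plot_id,
                          timestamps=pd.DatetimeIndex(df["timestamp"]),
                          ids=df["ids_a"].to_numpy(),
                          ids0=df["ids0_a"].to_numpy(),
                          replicate=replicate)


def write_plots(plots, path) -> None:
    write_table(pd.DataFrame([dataclasses.asdict(p) for p in plots]), path)


def read_plots(path) -> list[PlotGeometry]:
    schema = TableSchema(columns={"plot_id": "str", "treatment": "int",
                                  "row_min": "int", "row_max": "int",
                                  "col_min": "int", "col_max": "int"})
    df = read_table(path, schema)
    if df["plot_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate plot_id values")
    return [PlotGeometry(plot_id=r.plot_id, treatment=int(r.treatment),
                         row_min=int(r.row_min), row_max=int(r.row_max),
                         col_min=int(r.col_min), col_max=int(r.col_max))
            for r in df.itertuples()]


# ---------------------------------------------------------------- dataset

def write_dataset(dataset, outdir) -> Path:
    """Write a simulated trial as the on-disk dataset layout:
    ``bands_<plot>_<DAT>.tif``, ``thermal_<plot>_<DAT>.tif``,
    ``rgb_<plot>_<DAT>.png``, ``bioristor_<plot>_r<rep>.csv``, ``meteo.csv``,
    ``yield.csv``, ``plots.csv`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (plot_id, dat), raster in dataset.bands.items():
        write_band_raster(outdir / f"bands_{plot_id}_{dat}.tif", raster)
    for (plot_id, dat), th in dataset.thermal.items():
        write_thermal(outdir / f"thermal_{plot_id}_{dat}.tif", th)
    for (plot_id, dat), img in dataset.rgb.items():
        write_rgb(outdir / f"rgb_{plot_id}_{dat}.png", img)
    for trace in dataset.traces:
        write_trace(outdir / f"bioristor_{trace.plot_id}_r{trace.replicate}.csv",
                    trace)
    meteo = dataset.meteo.copy()
    meteo["timestamp"] = pd.to_datetime(meteo["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    write_table(meteo, outdir / "meteo.csv")
    write_table(dataset.yields, outdir / "yield.csv")
    write_table(dataset.physio, outdir / "physio.csv")
    write_plots(dataset.plots, outdir / "plots.csv")
    truth = {
        "green_fraction": {f"{p}|{d}": v for (p, d), v
                           in dataset.truth.green_fraction.items()},
        "greener_fraction": {f"{p}|{d}": v for (p, d), v
                             in dataset.truth.greener_fraction.items()},
        "stress_severity": {f"{p}|{d}": v for (p, d), v
                            in dataset.truth.stress_severity.items()},
        "yield_means": {str(t): m for t, m in dataset.truth.yield_means.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return outdir


# ------------------------------------------------------------ configuration

@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline settings with documented defaults."""

    seed: int = 0
    ga_range: tuple[float, float] = (60.0, 180.0)     # degrees
    gga_range: tuple[float, float] = (80.0, 180.0)
    kmeans_k: int = 2
    use_thermal_in_segmentation: bool = True
    cwsi_baseline_a: float = 2.86                     # degC (tomato, Idso-type)
    cwsi_baseline_b: float = -1.96                    # degC/kPa
    fit_baseline_from_reference: bool = False         # OLS fit on the 100% plots
    fit_baseline_reference_treatment: int = 100
    smoothing_window_hours: float = 24.0
    normalization_mode: str = "global"                # global|per_plant|per_treatment
    divergence_alpha: float = 0.001
    divergence_consecutive_days: int = 3
    tukey_alpha: float = 0.05
    date_tolerance_days: int = 0
    event_min_prominence: float = 0.05
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if self.smoothing_window_hours <= 0:
            raise ConfigurationError("smoothing_window_hours must be > 0")
        if self.normalization_mode not in ("global", "per_plant", "per_treatment"):
            raise ConfigurationError(
                f"unknown normalization_mode {self.normalization_mode!r}")
        for name in ("ga_range", "gga_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi <= 360:
                raise ConfigurationError(f"{name} must satisfy 0 <= lo < hi <= 360")
        if not 0 < self.divergence_alpha <= 1:
            raise ConfigurationError("divergence_alpha must lie in (0, 1]")
        if self.date_tolerance_days < 0:
            raise ConfigurationError("date_tolerance_days must be >= 0")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration, rejecting unknown keys."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown configuration key(s) "
                                 f"{sorted(unknown)}")
    for name in ("ga_range", "gga_range"):
        if name in raw and isinstance(raw[name], list):
            raw[name] = tuple(raw[name])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
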