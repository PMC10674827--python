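"""In-memory containers shared by the pipeline stages.

Conventions used everywhere in this package:

* grids are 2-D numpy arrays indexed ``[row, col]``, row-major, 0-based;
* plot extents are half-open pixel bounding boxes
  ``[row_min, row_max) x [col_min, col_max)``;
* the trial time axis is DAT (days after transplant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "BandRaster",
    "ThermalRaster",
    "BioristorTrace",
    "PlotGeometry",
    "ColorIndexRecord",
    "SpectralRecord",
    "CWSIRecord",
    "records_to_frame",
]

#: canonical band order for multi-band rasters (matches the 4-band TIFF layout)
BAND_ORDER = ("green", "red", "red_edge", "nir")


@dataclass
class BandRaster:
    """Aligned 2-D reflectance grids for the green/red/red-edge/NIR bands.

    Reflectance is unitless in [0, 1] for physical scenes; values are not
    clipped so synthetic edge cases stay representable.  ``nodata`` (optional)
    marks invalid pixels (True = invalid).
    """

    green: np.ndarray
    red: np.ndarray
    red_edge: np.ndarray
    nir: np.ndarray
    nodata: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {b: getattr(self, b).shape for b in BAND_ORDER}
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"band shapes differ: {shapes}")
        if self.nodata is not None and self.nodata.shape != self.green.shape:
            raise ValidationError("nodata mask shape does not match bands")
        for b in BAND_ORDER:
            a = getattr(self, b)
            valid = a if self.nodata is None else a[~self.nodata]
            if not np.all(np.isfinite(valid)):
                raise ValidationError(f"non-finite reflectance in band {b!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    def band(self, name: str) -> np.ndarray:
        if name not in BAND_ORDER:
            raise ValidationError(
                f"unknown band {name!r}; expected one of {BAND_ORDER}"
            )
        return getattr(self, name)

    def stack(self) -> np.ndarray:
        """(4, rows, cols) float32 stack in canonical band order."""
        return np.stack([getattr(self, b) for b in BAND_ORDER]).astype(np.float32)

    @classmethod
    def from_stack(cls, stack: np.ndarray, nodata: Optional[np.ndarray] = None) -> "BandRaster":
        if stack.ndim != 3 or stack.shape[0] != len(BAND_ORDER):
            raise ValidationError(
                f"expected a ({len(BAND_ORDER)}, rows, cols) stack, got {stack.shape}"
            )
        return cls(*[np.asarray(stack[i], dtype=float) for i in range(len(BAND_ORDER))],
                   nodata=nodata)


@dataclass
class ThermalRaster:
    """2-D canopy-temperature grid Tc in degrees Celsius."""

    tc: np.ndarray
    nodata: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.tc = np.asarray(self.tc, dtype=float)
        if self.tc.ndim != 2 or self.tc.size == 0:
            raise ValidationError("thermal grid must be a non-empty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tc.shape


@dataclass
class BioristorTrace:
    """Timestamped OECT drain-source currents for one monitored plant.

    ``ids`` is the gated current (Vg = 0.5 V), ``ids0`` the ungated reference
    (Vg = 0 V); both in amperes, typically negative under Vds = -0.1 V.
    """

    plot_id: str
    timestamps: pd.DatetimeIndex
    ids: np.ndarray
    ids0: np.ndarray
    replicate: int = 0
    vds: float = -0.1
    vg: float = 0.5

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=float)
        self.ids0 = np.asarray(self.ids0, dtype=float)
        n = len(self.timestamps)
        if self.ids.shape != (n,) or self.ids0.shape != (n,):
            raise ValidationError("trace arrays must match the timestamp length")
        if n and not self.timestamps.is_monotonic_increasing:
            raise ValidationError("trace timestamps must be strictly increasing")
        if n and self.timestamps.has_duplicates:
            raise ValidationError("trace timestamps must be strictly increasing")


@dataclass(frozen=True)
class PlotGeometry:
    """One experimental plot: id, irrigation treatment (% PAW) and its
    half-open pixel bounding box on the raster it belongs to."""

    plot_id: str
    treatment: int
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValidationError(
                f"plot {self.plot_id!r} has a degenerate bounding box"
            )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    def within(self, shape: tuple[int, int]) -> bool:
        return (0 <= self.row_min and self.row_max <= shape[0]
                and 0 <= self.col_min and self.col_max <= shape[1])


@dataclass
class ColorIndexRecord:
    """Per-plot, per-date RGB colour indices (whole-image statistics)."""

    plot_id: str
    dat: int
    ga: float              # percent of classifiable pixels with hue in [60, 180]
    gga: float             # percent with hue in [80, 180]
    csi: float             # 100*(GA-GGA)/GA, NaN when GA == 0
    hue: float             # circular mean hue, degrees
    saturation: float
    intensity: float
    L: float
    a: float
    b: float
    u: float
    v: float


@dataclass
class SpectralRecord:
    """Per-plot, per-date vegetation-index means over pure vegetation pixels."""

    plot_id: str
    dat: int
    ndvi: float
    gndvi: float
    ndre: float
    n_vegetation_pixels: int


@dataclass
class CWSIRecord:
    """Per-plot, per-date Crop Water Stress Index observation."""

    plot_id: str
    dat: int
    cwsi: float            # clipped to [0, 1] (headline value)
    cwsi_raw: float        # unclipped, for diagnostics
    tc_minus_ta: float     # degC
    vpd: float             # kPa
    vpg: float             # kPa


def records_to_frame(records) -> pd.DataFrame:
    """Convert a list of record dataclasses to a DataFrame sorted by
    (plot_id, dat)."""
    df = pd.DataFrame([vars(r) for r in records])
    if not df.empty:
        df = df.sort_values(["plot_id", "dat"], kind="stable").reset_index(drop=True)
    return df
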