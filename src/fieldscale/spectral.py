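"""Multispectral vegetation indices and vegetation/soil segmentation.

Normalised-difference indices contrast near-infrared reflectance with a
visible or red-edge band::

    NDVI  = (Rnir - Rred)      / (Rnir + Rred)
    GNDVI = (Rnir - Rgreen)    / (Rnir + Rgreen)
    NDRE  = (Rnir - Rrededge)  / (Rnir + Rrededge)

Vegetation is separated from soil with 2-cluster k-means on the per-pixel
band features (optionally including canopy temperature), standardised per
feature; the cluster with the higher mean NDVI is labelled vegetation.
Per-plot means are then taken over pure vegetation pixels only.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
from sklearn.cluster import KMeans

from .containers import BandRaster, PlotGeometry, SpectralRecord, ThermalRaster
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "normalized_difference",
    "ndvi",
    "gndvi",
    "ndre",
    "segment_vegetation",
    "extract_plot_means",
]


def normalized_difference(band_a: np.ndarray, band_b: np.ndarray) -> np.ndarray:
    """(a - b) / (a + b) per pixel; NaN where a + b == 0.

    Both grids must be aligned and non-negative (reflectance).
    """
    a = np.asarray(band_a, dtype=float)
    b = np.asarray(band_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"band shapes differ: {a.shape} vs {b.shape}")
    if np.nanmin(a) < 0 or np.nanmin(b) < 0:
        raise ValidationError("reflectance values must be non-negative")
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / np.where(denom == 0, 1.0, denom), np.nan)
    return out


def ndvi(r: BandRaster) -> np.ndarray:
    return normalized_difference(r.band("nir"), r.band("red"))


def gndvi(r: BandRaster) -> np.ndarray:
    return normalized_difference(r.band("nir"), r.band("green"))


def ndre(r: BandRaster) -> np.ndarray:
    return normalized_difference(r.band("nir"), r.band("red_edge"))


def segment_vegetation(
    r: BandRaster,
    thermal: Optional[ThermalRaster] = None,
    k: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Boolean vegetation mask from k-means clustering of pixel features.

    Features are the four reflectance bands plus canopy temperature when a
    thermal raster is supplied, z-standardised per feature.  k-means uses
    k-means++ with 10 restarts and the given seed.  Among the k clusters the
    one with the highest mean NDVI is labelled vegetation, so the mask is
    invariant to cluster-id relabelling.  Nodata pixels are excluded from
    clustering and never labelled vegetation.
    """
    feats = [r.band(b).ravel() for b in ("green", "red", "red_edge", "nir")]
    if thermal is not None:
        if thermal.shape != r.shape:
            raise ValidationError("thermal raster shape does not match the bands")
        feats.append(thermal.tc.ravel())
    x = np.column_stack(feats)

    valid = np.ones(x.shape[0], dtype=bool)
    if r.nodata is not None:
        valid &= ~r.nodata.ravel()
    xv = x[valid]
    if np.unique(xv, axis=0).shape[0] < k:
        raise DegenerateInputError(
            f"fewer than k={k} distinct pixel feature vectors; cannot cluster"
        )
    sd = xv.std(axis=0)
    z = (xv - xv.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(z)

    ndvi_v = ndvi(r).ravel()[valid]
    means = [np.nanmean(ndvi_v[labels == c]) if np.any(labels == c) else -np.inf
             for c in range(k)]
    veg_cluster = int(np.argmax(means))

    mask = np.zeros(x.shape[0], dtype=bool)
    mask[valid] = labels == veg_cluster
    return mask.reshape(r.shape)


def extract_plot_means(
    index_grid: np.ndarray,
    mask: np.ndarray,
    plots: Iterable[PlotGeometry],
    dat: int = 0,
    index_name: str = "index",
) -> list[tuple[PlotGeometry, float, int]]:
    """Per-plot mean of ``index_grid`` over (mask AND plot) pixels.

    Returns ``(plot, mean, n_pixels)`` triples; a plot with zero vegetation
    pixels yields NaN with a warning.  Prefer :func:`spectral_records` for
    the three standard indices at once.
    """
    index_grid = np.asarray(index_grid, dtype=float)
    if mask.shape != index_grid.shape:
        raise ValidationError("mask shape does not match the index grid")
    out = []
    for plot in plots:
        if not plot.within(index_grid.shape):
            raise ValidationError(f"plot {plot.plot_id!r} lies outside the raster")
        rs, cs = plot.slices()
        vals = index_grid[rs, cs][mask[rs, cs]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(
                f"plot {plot.plot_id!r} has no vegetation pixels for {index_name} "
                f"at DAT {dat}", stacklevel=2)
            out.append((plot, float("nan"), 0))
        else:
            out.append((plot, float(vals.mean()), int(vals.size)))
    return out


def spectral_records(
    r: BandRaster,
    mask: np.ndarray,
    plots: Iterable[PlotGeometry],
    dat: int,
) -> list[SpectralRecord]:
    """NDVI/GNDVI/NDRE plot means over pure vegetation pixels."""
    plots = list(plots)
    per_index = {
        name: extract_plot_means(grid, mask, plots, dat, name)
        for name, grid in (("ndvi", ndvi(r)), ("gndvi", gndvi(r)), ("ndre", ndre(r)))
    }
    records = []
    for i, plot in enumerate(plots):
        records.append(
            SpectralRecord(
                plot_id=plot.plot_id,
                dat=int(dat),
                ndvi=per_index["ndvi"][i][1],
                gndvi=per_index["gndvi"][i][1],
                ndre=per_index["ndre"][i][1],
                n_vegetation_pixels=per_index["ndvi"][i][2],
            )
        )
    return records
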