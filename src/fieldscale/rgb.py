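"""Proximal RGB canopy indices: HSI decomposition, GA/GGA/CSI, CIE statistics.

Green Area (GA) is the percentage of image pixels whose hue falls in
[60, 180] degrees (yellow-green through blue-green); Greener Area (GGA)
restricts the range to [80, 180], excluding yellowish-green.  The Crop
Senescence Index scales their gap::

    CSI = 100 * (GA - GGA) / GA

All three are whole-image statistics computed on the raw canopy photo
(no soil masking).  Hue uses the arccos formulation of the
hue-intensity-saturation (HIS) colour space; achromatic pixels have
undefined hue and never count as green, but remain in the denominator.
"""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor

from .containers import ColorIndexRecord
from .errors import ValidationError

__all__ = [
    "rgb_to_hsi",
    "rgb_to_cie",
    "green_area",
    "crop_senescence_index",
    "summarize_plot_rgb",
    "GA_RANGE",
    "GGA_RANGE",
]

GA_RANGE = (60.0, 180.0)   # degrees, closed interval
GGA_RANGE = (80.0, 180.0)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3 or image.size == 0:
        raise ValidationError("expected a non-empty (H, W, 3) RGB image")
    return image


def rgb_to_hsi(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel hue (degrees, NaN where undefined), saturation and intensity.

    Uses the arccos hue formulation with I = (R+G+B)/3 and
    S = 1 - min(R,G,B)/I.  Saturation-0 (achromatic) pixels get NaN hue.
    """
    image = _check_image(image)
    rgb = image.astype(float) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    intensity = (r + g + b) / 3.0
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(intensity > 0, 1.0 - mn / intensity, 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(num / np.where(achromatic, 1.0, den), -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(achromatic, np.nan, hue) % 360.0
    return hue, saturation, intensity


def rgb_to_cie(image: np.ndarray) -> dict[str, np.ndarray]:
    """Per-pixel CIELab and CIELuv channels from an sRGB image (D65).

    Returns a dict with keys ``L, a, b, u, v``; L* is shared by both spaces.
    """
    image = _check_image(image)
    rgb = image.astype(float) / 255.0
    lab = skcolor.rgb2lab(rgb)
    luv = skcolor.rgb2luv(rgb)
    return {
        "L": lab[..., 0],
        "a": lab[..., 1],
        "b": lab[..., 2],
        "u": luv[..., 1],
        "v": luv[..., 2],
    }


def green_area(hue_grid: np.ndarray, lower: float = GA_RANGE[0],
               upper: float = GA_RANGE[1]) -> float:
    """Percent of pixels with hue in the closed interval [lower, upper].

    Hue-undefined (NaN) pixels are excluded from the numerator but counted
    in the denominator: a grey pixel is not green canopy.
    """
    if not (0 <= lower < upper <= 360):
        raise ValidationError("require 0 <= lower < upper <= 360 degrees")
    hue_grid = np.asarray(hue_grid, dtype=float)
    if hue_grid.size == 0:
        raise ValidationError("hue grid has zero pixels")
    with np.errstate(invalid="ignore"):
        n_green = int(np.count_nonzero((hue_grid >= lower) & (hue_grid <= upper)))
    return 100.0 * n_green / hue_grid.size


def crop_senescence_index(ga: float, gga: float) -> float:
    """CSI = 100 * (GA - GGA) / GA; NaN (undefined) when GA == 0."""
    if not (0 <= gga <= ga <= 100):
        raise ValidationError(f"require 0 <= GGA <= GA <= 100, got GA={ga}, GGA={gga}")
    if ga == 0:
        return float("nan")
    return 100.0 * (ga - gga) / ga


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(angles_deg[np.isfinite(angles_deg)])
    if a.size == 0:
        return float("nan")
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)


def summarize_plot_rgb(image: np.ndarray, plot_id: str, dat: int,
                       ga_range: tuple[float, float] = GA_RANGE,
                       gga_range: tuple[float, float] = GGA_RANGE) -> ColorIndexRecord:
    """All colour indices for one plot photo: GA, GGA, CSI and the whole-image
    channel means (hue is a circular mean over chromatic pixels)."""
    hue, sat, inten = rgb_to_hsi(image)
    cie = rgb_to_cie(image)
    ga = green_area(hue, *ga_range)
    gga = green_area(hue, *gga_range)
    return ColorIndexRecord(
        plot_id=plot_id,
        dat=int(dat),
        ga=ga,
        gga=gga,
        csi=crop_senescence_index(ga, gga),
        hue=_circular_mean_deg(hue),
        saturation=float(np.mean(sat)),
        intensity=float(np.mean(inten)),
        L=float(np.mean(cie["L"])),
        a=float(np.mean(cie["a"])),
        b=float(np.mean(cie["b"])),
        u=float(np.mean(cie["u"])),
        v=float(np.mean(cie["v"])),
    )
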