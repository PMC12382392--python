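"""State-of-the-art comparison baselines.

SoA-NC: nitrogen estimation from the Dark Green Color Index (DGCI), a
hue/saturation/brightness greenness score computed over the leaf mask,
optionally mapped to a nitrogen concentration through a linear calibration.

SoA-DW: shoot dry-weight estimation from projected leaf area — Otsu
segmentation of the green channel, leaf area from the pixel count and the
camera's ground pixel size, then a linear model against destructively
measured DW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .spectral import ReflectanceImage

__all__ = ["CameraSpec", "DGCIResult", "dgci", "soa_nc", "leaf_area", "soa_dw"]


@dataclass(frozen=True)
class CameraSpec:
    """Smartphone camera geometry used to convert pixel counts to area."""

    pixel_length_um: float = 1.9
    magnification: float = 1.0     # ground-sample scale factor (unitless)
    focal_mm: float = 26.0
    fov_deg: float = 69.0

    def __post_init__(self) -> None:
        if min(self.pixel_length_um, self.magnification, self.focal_mm, self.fov_deg) <= 0:
            raise ValueError("all camera parameters must be positive")

    @property
    def ground_pixel_cm(self) -> float:
        """Edge length of one pixel's ground footprint, in cm."""
        return self.pixel_length_um * self.magnification * 1e-4


@dataclass(frozen=True)
class DGCIResult:
    value: float          # mean DGCI over chromatic leaf pixels
    n_excluded: int = 0   # achromatic pixels (hue undefined)


def _rgb_to_hsv(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    """Hue (degrees), saturation, value for arrays; tolerates reflectance > 1."""
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn
    h = np.zeros_like(mx)
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = np.mod((g - b) / delta, 6.0)
        hg = (b - r) / delta + 2.0
        hb = (r - g) / delta + 4.0
    h = np.where(mx == r, hr, np.where(mx == g, hg, hb)) * 60.0
    s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0), 0.0)
    return h, s, mx


def dgci(img: ReflectanceImage, mask: np.ndarray) -> DGCIResult:
    """Mean Dark Green Color Index over the masked leaf pixels.

    Per pixel, DGCI = [(H − 60)/60 + (1 − S) + (1 − V)] / 3 with hue H in
    degrees and S, V in [0, 1]; bounded in [0, 1] for hues in the green range
    [60°, 180°]. Achromatic pixels (undefined hue, max = min) are excluded
    and counted.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask dimensions must match the image")
    if not mask.any():
        raise ValueError("mask is empty")
    r = img.band(0)[mask]
    g = img.band(1)[mask]
    b = img.band(2)[mask]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    chromatic = (mx > mn) & (mx > 0)
    n_excl = int(np.count_nonzero(~chromatic))
    if not chromatic.any():
        return DGCIResult(value=float("nan"), n_excluded=n_excl)
    h, s, v = _rgb_to_hsv(r[chromatic], g[chromatic], b[chromatic])
    per_pixel = ((h - 60.0) / 60.0 + (1.0 - s) + (1.0 - v)) / 3.0
    return DGCIResult(value=float(np.mean(per_pixel)), n_excluded=n_excl)


def soa_nc(
    dgci_values: Sequence[float],
    calibration: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """DGCI-based nitrogen baseline.

    Without calibration, returns the raw DGCI values (index-comparison mode);
    with ≥ 2 (dgci, nitrogen) calibration pairs, maps DGCI to nitrogen through
    an ordinary-least-squares line.
    """
    x = np.asarray(dgci_values, dtype=float)
    if calibration is None:
        return x
    cal = np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[0] < 2:
        raise ValueError("calibration needs at least 2 (dgci, nitrogen) pairs")
    intercept, slope = np.polynomial.polynomial.polyfit(cal[:, 0], cal[:, 1], 1)
    return intercept + slope * x


def leaf_area(
    img: ReflectanceImage, cam: CameraSpec, literal_product: bool = False
) -> float:
    """Projected leaf area (cm²) from Otsu segmentation of the green channel.

    Area = PPN · (PL·MF)², the ground footprint of the plant-pixel count.
    ``literal_product=True`` instead returns PPN · PL · MF (the
    dimensionally-inconsistent literal product, kept for comparison).
    """
    green = img.band(1)
    if np.ptp(green) == 0:
        raise ValueError("cannot segment: green channel has zero variance")
    ppn = int(np.count_nonzero(green > threshold_otsu(green)))
    if literal_product:
        return ppn * cam.pixel_length_um * cam.magnification
    return ppn * cam.ground_pixel_cm**2


def soa_dw(
    img: ReflectanceImage,
    cam: CameraSpec,
    calibration: Sequence[tuple[float, float]],
    literal_product: bool = False,
) -> float:
    """Leaf-area-based shoot dry weight (g) prediction.

    ``calibration`` holds ≥ 2 (leaf_area, observed_DW) pairs from destructive
    sampling; DW is predicted by the OLS line through them at this image's
    leaf area.
    """
    cal = np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[0] < 2:
        raise ValueError("calibration needs at least 2 (leaf_area, DW) pairs")
    la = leaf_area(img, cam, literal_product=literal_product)
    intercept, slope = np.polynomial.polynomial.polyfit(cal[:, 0], cal[:, 1], 1)
    return float(intercept + slope * la)
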