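"""Spectral processing of top-view RGB plant imagery.

Raw camera digital numbers (DN) are converted to relative reflectance with a
dark frame and a white-reference frame, leaves are segmented from the
background, and 15 RGB vegetation indices are averaged over the leaf pixels
to give one spectral feature vector per plant.

The index set covers the common greenness/chlorophyll proxies (ExG, GLI,
NGRDI, MGRVI, VARI, TGI, ...) plus normalized band ratios (NRI, NGI, NBI) and
stress/senescence indices (ExR, NDYI). Each index is evaluated per pixel and
then averaged ("per-pixel first"), and pixels whose denominator is within
``epsilon`` of zero are excluded from that index's mean rather than clipped,
so single degenerate pixels cannot dominate a plant-level value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "IndexConfig",
    "ReflectanceImage",
    "SpectralFeatureVector",
    "INDEX_NAMES",
    "calibrate",
    "segment_leaves",
    "iou",
    "compute_indices",
]

#: the 15 vegetation indices computed by :func:`compute_indices`
INDEX_NAMES = (
    "GLI", "MGRVI", "RGBVI", "ExG", "ExR", "TGI", "VARI", "NRI", "NGI",
    "NBI", "GMRI", "GRRI", "EGMERI", "NGRDI", "NDYI",
)


@dataclass(frozen=True)
class IndexConfig:
    """Band-center wavelengths (nm, used by TGI) and the zero-denominator guard."""

    lambda_red: float = 670.0
    lambda_green: float = 550.0
    lambda_blue: float = 480.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.lambda_red > self.lambda_green > self.lambda_blue > 0):
            raise ValueError("wavelengths must satisfy lambda_red > lambda_green > lambda_blue > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ReflectanceImage:
    """Calibrated 3-band raster of per-pixel relative reflectance.

    Values above 1 (DN above the white-reference mean, e.g. specular spots)
    are kept and counted in ``n_over_unity`` rather than clipped.
    """

    data: np.ndarray  # (H, W, 3) float
    n_over_unity: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != 3:
            raise ValueError("reflectance image must be (H, W, 3)")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("reflectance must be finite and non-negative")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def band(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass(frozen=True)
class SpectralFeatureVector:
    """Per-plant mean of each vegetation index over leaf pixels.

    ``values`` maps index name to its leaf-pixel mean (NaN when every pixel
    was excluded by the denominator guard); ``excluded`` counts the pixels
    excluded per index.
    """

    values: Mapping[str, float]
    excluded: Mapping[str, int] = field(default_factory=dict)
    plant_id: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _band_means(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float).reshape(-1, 3).mean(axis=0)


def calibrate(raw: np.ndarray, dark: np.ndarray, white: np.ndarray) -> ReflectanceImage:
    """Convert raw digital numbers to relative reflectance.

    Per band ``b``: ``refl = max(raw_b - mean(dark_b), 0) / (mean(white_b) - mean(dark_b))``,
    i.e. the white frame is itself dark-subtracted so a pixel at the dark mean
    maps to 0 and one at the white mean maps to 1.

    Raises
    ------
    ValueError
        if shapes differ or any band's white mean does not exceed its dark mean.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("raw image must be (H, W, 3)")
    if raw.shape != dark.shape or raw.shape != white.shape:
        raise ValueError("raw, dark and white images must share dimensions")
    if np.any(raw < 0) or np.any(dark < 0) or np.any(white < 0):
        raise ValueError("digital numbers must be non-negative")

    dark_mean = _band_means(dark)
    white_mean = _band_means(white)
    span = white_mean - dark_mean
    if np.any(span <= 0):
        bad = [i for i, s in enumerate(span) if s <= 0]
        raise ValueError(f"white mean does not exceed dark mean in band(s) {bad}")

    refl = np.clip(raw - dark_mean, 0.0, None) / span
    return ReflectanceImage(refl, n_over_unity=int(np.count_nonzero(refl > 1.0)))


def segment_leaves(img: ReflectanceImage, min_area: int = 25) -> np.ndarray:
    """Classical leaf segmentation: Otsu threshold on the per-pixel ExG image.

    Connected foreground components smaller than ``min_area`` pixels are
    dropped. Serves as the mask source when no externally produced mask (e.g.
    from a CNN segmenter) is supplied; external masks bypass this entirely.

    Raises
    ------
    ValueError
        if the ExG image has zero variance (no threshold exists).
    """
    r, g, b = (img.band(i) for i in range(3))
    exg = 2.0 * g - r - b
    if np.ptp(exg) == 0:
        raise ValueError("cannot threshold: ExG image has zero variance")
    mask = exg > threshold_otsu(exg)
    # drop components strictly smaller than min_area pixels
    mask = remove_small_objects(mask, max_size=min_area - 1)
    return mask


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1 = identical, 0 = disjoint."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share dimensions")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return np.count_nonzero(a & b) / union


def _guarded_mean(num: np.ndarray, den: np.ndarray, eps: float) -> tuple[float, int]:
    """Mean of num/den over pixels with |den| >= eps; (NaN, n) if none qualify."""
    ok = np.abs(den) >= eps
    n_excl = int(np.count_nonzero(~ok))
    if not np.any(ok):
        return float("nan"), n_excl
    return float(np.mean(num[ok] / den[ok])), n_excl


def compute_indices(
    img: ReflectanceImage,
    mask: np.ndarray,
    cfg: IndexConfig | None = None,
    plant_id: str = "",
) -> SpectralFeatureVector:
    """Evaluate all 15 vegetation indices over the masked (leaf) pixels.

    Each index is computed per pixel from the band reflectances, then averaged
    over the mask. Ratio indices exclude pixels whose denominator magnitude is
    below ``cfg.epsilon``; if every pixel is excluded the index is reported as
    NaN (missing), never as zero.
    """
    cfg = cfg or IndexConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask dimensions must match the image")
    if not mask.any():
        raise ValueError("mask is empty")

    R = img.band(0)[mask]
    G = img.band(1)[mask]
    B = img.band(2)[mask]
    eps = cfg.epsilon
    lr, lg, lb = cfg.lambda_red, cfg.lambda_green, cfg.lambda_blue

    values: dict[str, float] = {}
    excluded: dict[str, int] = {}

    def put(name: str, value: float, n_excl: int = 0) -> None:
        values[name] = value
        excluded[name] = n_excl

    total = R + G + B
    exg = 2.0 * G - R - B

    put("ExG", float(np.mean(exg)))
    put("GMRI", float(np.mean(G - R)))
    # TGI: triangular greenness from band-center wavelengths
    tgi = -0.5 * ((lr - lb) * (R - G) - (lr - lg) * (R - B))
    put("TGI", float(np.mean(tgi)))

    put("GLI", *_guarded_mean(exg, 2.0 * G + R + B, eps))
    put("MGRVI", *_guarded_mean(G**2 - R**2, G**2 + R**2, eps))
    put("RGBVI", *_guarded_mean(G - R * B, G + R * B, eps))
    put("ExR", *_guarded_mean(1.4 * R - G, total, eps))
    put("VARI", *_guarded_mean(G - R, G + R - B, eps))
    put("NRI", *_guarded_mean(R, total, eps))
    put("NGI", *_guarded_mean(G, total, eps))
    put("NBI", *_guarded_mean(B, total, eps))
    put("GRRI", *_guarded_mean(G, R, eps))
    put("NGRDI", *_guarded_mean(G - R, G + R, eps))
    put("NDYI", *_guarded_mean(G - B, G + B, eps))

    # EGMERI = ExG - ExR per pixel; inherits ExR's denominator guard
    ok = np.abs(total) >= eps
    if np.any(ok):
        egmeri = float(np.mean(exg[ok] - (1.4 * R[ok] - G[ok]) / total[ok]))
    else:
        egmeri = float("nan")
    put("EGMERI", egmeri, int(np.count_nonzero(~ok)))

    return SpectralFeatureVector(values=values, excluded=excluded, plant_id=plant_id)
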