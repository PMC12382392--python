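"""Seeded generator of a synthetic greenhouse nitrogen-dosing experiment.

Emulates the statistical structure the downstream analysis assumes: 84 potted
leafy-vegetable plants in 8 nitrogen dose groups (20–800 ppm, 10–11
replicates), destructive trait measurements (leaf total reduced nitrogen TRN
and nitrate NO3 in mg N/g DW, shoot dry weight DW in g) whose group means
follow concave quadratics in sqrt(dose), top-view RGB digital-number images
with dark/white calibration frames, and colored point clouds with a dark
background plane and isolated acquisition noise.

Couplings built in (and relied on by the analysis):

* leaf green reflectance is an affine function of TRN (the chlorophyll–
  nitrogen rationale), so spectral greenness indices track leaf nitrogen;
* canopy height, width and hence hull volume scale with DW, so structural
  traits track biomass; leaf count in the image also grows with DW;
* injected noise points sit in voxels of ≤ 4 points on the exact 1 cm grid
  the denoiser will use (the cloud's bounding-box minimum is pinned to the
  origin), so density denoising at the default threshold removes exactly the
  injected noise set.

Each plant draws from three independent substreams (traits, image, cloud)
spawned from the experiment seed, so regenerating one modality never
perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structural import PlantPointCloud

__all__ = [
    "TraitCurve",
    "TraitRecord",
    "ExperimentConfig",
    "SyntheticPlant",
    "generate_experiment",
    "generate_traits",
    "write_experiment",
]

TRAITS = ("TRN", "NO3", "DW")


@dataclass(frozen=True)
class TraitCurve:
    """Quadratic dose-response curve y = a·u² + b·u + c with u = √dose."""

    a: float
    b: float
    c: float

    @classmethod
    def from_peak(cls, a: float, peak_dose_ppm: float, peak_value: float) -> "TraitCurve":
        """Concave curve with its maximum ``peak_value`` at ``peak_dose_ppm``."""
        if a >= 0:
            raise ValueError("a peaked curve requires a negative leading coefficient")
        u0 = np.sqrt(peak_dose_ppm)
        return cls(a=a, b=-2.0 * a * u0, c=peak_value + a * u0**2)

    @property
    def concave(self) -> bool:
        return self.a < 0

    @property
    def peak_dose_ppm(self) -> float:
        if self.a == 0:
            return float("nan")
        return (-self.b / (2.0 * self.a)) ** 2

    def __call__(self, dose_ppm) -> np.ndarray | float:
        u = np.sqrt(dose_ppm)
        return self.a * u**2 + self.b * u + self.c


@dataclass(frozen=True)
class TraitRecord:
    """Per-plant treatment and destructively measured traits."""

    dose_ppm: float
    TRN: float   # mg N / g DW
    NO3: float   # mg N / g DW
    DW: float    # g

    def __post_init__(self) -> None:
        if min(self.dose_ppm, self.TRN, self.NO3, self.DW) < 0:
            raise ValueError("doses and traits must be non-negative")


def _default_curves() -> dict[str, TraitCurve]:
    # peaks at exactly 150 ppm; magnitudes typical of leafy greens
    return {
        "TRN": TraitCurve.from_peak(-0.12, 150.0, 60.0),
        "NO3": TraitCurve.from_peak(-0.02, 150.0, 10.0),
        "DW": TraitCurve.from_peak(-0.15, 150.0, 55.0),
    }


def _default_noise() -> dict[str, float]:
    return {"TRN": 9.0, "NO3": 1.5, "DW": 3.0}


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the synthetic experiment.

    Defaults mirror the emulated study: 8 dose levels from 20 to 800 ppm,
    10–11 replicates each (84 plants), trait means quadratic in √dose with
    a common peak at 150 ppm. Within-group scatter is ≈6 % CV for DW and
    ≈15 % for the nitrogen traits, whose biological variation the spectral
    channel tracks directly while structure only reflects the dose mean.
    """

    doses_ppm: Sequence[float] = (20, 40, 80, 120, 160, 200, 400, 800)
    replicates_per_dose: Sequence[int] = (11, 11, 11, 11, 10, 10, 10, 10)
    seed: int = 0
    trait_curves: Mapping[str, TraitCurve] = field(default_factory=_default_curves)
    noise_sd: Mapping[str, float] = field(default_factory=_default_noise)
    image_size: int = 96
    cloud_points: int = 1200
    background_noise_points: int = 25
    dn_noise_sd: float = 1.0        # sensor noise on raw digital numbers
    leaf_color_jitter: float = 0.04  # per-plant reflectance jitter (illumination/shading)
    geometry_jitter: float = 0.15    # lognormal sd on canopy height/width (scan variability)

    def __post_init__(self) -> None:
        if len(self.doses_ppm) != len(self.replicates_per_dose):
            raise ValueError("doses_ppm and replicates_per_dose lengths differ")
        if any(d <= 0 for d in self.doses_ppm):
            raise ValueError("every dose must be positive")
        if any(r < 2 for r in self.replicates_per_dose):
            raise ValueError("need at least 2 replicates per dose for within-group variance")
        for name in TRAITS:
            if name not in self.trait_curves:
                raise ValueError(f"missing trait curve for {name}")
            if name not in self.noise_sd or self.noise_sd[name] < 0:
                raise ValueError(f"missing or negative noise_sd for {name}")
        for name in ("DW", "TRN"):  # biomass and chlorophyll-linked greenness
            curve = self.trait_curves[name]
            if not curve.concave:
                raise ValueError(
                    f"{name} curve must be concave (negative leading coefficient) "
                    "so an interior optimum exists"
                )
        if self.image_size < 32:
            raise ValueError("image_size too small to place leaves")
        if self.cloud_points < 50:
            raise ValueError("cloud_points too small for a canopy")

    @property
    def n_plants(self) -> int:
        return int(sum(self.replicates_per_dose))


@dataclass(frozen=True)
class SyntheticPlant:
    """One generated plant: traits, calibrated-imaging inputs, and cloud."""

    plant_id: str
    dose_ppm: float
    traits: TraitRecord
    image: np.ndarray            # raw DN raster (H, W, 3)
    dark_frame: np.ndarray
    white_frame: np.ndarray
    true_leaf_mask: np.ndarray   # bool (H, W)
    cloud: PlantPointCloud
    true_plant_point_ids: np.ndarray  # indices into cloud
    true_noise_point_ids: np.ndarray  # indices of injected isolated noise


# imaging constants: per-band dark floor and white-reference DN levels
_DARK_LEVEL = np.array([10.0, 12.0, 9.0])
_WHITE_LEVEL = np.array([210.0, 200.0, 190.0])
_BACKGROUND_REFL = np.array([0.035, 0.04, 0.03])
_VOXEL_EDGE = 0.01   # m; the grid the denoiser uses by default
_JITTER_MARGIN = 5e-4  # keeps jittered points strictly inside their voxel


def _leaf_reflectance(trn: float, rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Leaf (R, G, B) reflectance; green channel affine in TRN."""
    g = 0.15 + 0.006 * trn
    base = np.array([0.18, g, 0.10])
    base = base + jitter * rng.normal(size=3)
    return np.clip(base, 0.0, 1.0)


def _draw_traits(dose: float, cfg: ExperimentConfig, rng: np.random.Generator) -> TraitRecord:
    vals = {}
    for name in TRAITS:
        mean = float(cfg.trait_curves[name](dose))
        vals[name] = max(0.0, mean + cfg.noise_sd[name] * rng.normal())
    return TraitRecord(dose_ppm=dose, **vals)


def _synthesize_image(
    traits: TraitRecord, cfg: ExperimentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw DN image, dark frame, white frame, and the true leaf mask.

    Leaves are random ellipses; their count grows with DW so projected leaf
    area tracks biomass, and their color encodes TRN through the green band.
    """
    n = cfg.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    n_leaves = 3 + rng.poisson(0.08 * traits.DW)
    mask = np.zeros((n, n), dtype=bool)
    lo, hi = 0.25 * n, 0.75 * n
    for _ in range(n_leaves):
        cx, cy = rng.uniform(lo, hi, size=2)
        ax_ = rng.uniform(0.06 * n, 0.12 * n)
        bx_ = rng.uniform(0.06 * n, 0.12 * n)
        theta = rng.uniform(0, np.pi)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / ax_) ** 2 + (v / bx_) ** 2 <= 1.0
    if not mask.any():  # degenerate draw: force one central leaf
        mask |= ((xx - n / 2) ** 2 + (yy - n / 2) ** 2) <= (0.08 * n) ** 2

    leaf = _leaf_reflectance(traits.TRN, rng, cfg.leaf_color_jitter)
    refl = np.broadcast_to(_BACKGROUND_REFL, (n, n, 3)).copy()
    refl[mask] = leaf

    span = _WHITE_LEVEL - _DARK_LEVEL
    raw = _DARK_LEVEL + refl * span + cfg.dn_noise_sd * rng.normal(size=(n, n, 3))
    raw = np.clip(raw, 0.0, None)
    dark = np.clip(_DARK_LEVEL + 0.2 * rng.normal(size=(n, n, 3)), 0.0, None)
    white = np.clip(_WHITE_LEVEL + 0.5 * rng.normal(size=(n, n, 3)), 0.0, None)
    return raw, dark, white, mask


def _cluster_points(
    centers_idx: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Jittered points inside the given voxels (strictly interior)."""
    pts = []
    half = _VOXEL_EDGE / 2 - _JITTER_MARGIN
    for idx, k in zip(centers_idx, counts):
        center = (idx + 0.5) * _VOXEL_EDGE
        pts.append(center + rng.uniform(-half, half, size=(k, 3)))
    return np.concatenate(pts, axis=0)


def _synthesize_cloud(
    traits: TraitRecord, cfg: ExperimentConfig, rng: np.random.Generator
) -> tuple[PlantPointCloud, np.ndarray, np.ndarray]:
    """Colored cloud = canopy + background plane + isolated noise.

    The canopy is a half-ellipsoid (spheroid cap) whose height and width are
    affine in DW. All persistent points are laid down ≥ 5 per voxel on the
    1 cm grid anchored at the origin; one background point sits exactly at
    (0, 0, 0) to pin the bounding-box minimum, so the denoiser reconstructs
    the same grid. Noise points occupy otherwise-empty voxels, ≤ 4 points
    each.
    """
    e = _VOXEL_EDGE
    # per-scan multiplicative jitter: pose, leaf droop, fusion artifacts
    hj, wj = np.exp(cfg.geometry_jitter * rng.normal(size=2))
    height = (0.05 + 0.004 * traits.DW) * hj    # m
    semi_w = (0.05 + 0.0025 * traits.DW) * wj   # m, canopy semi-axis
    center = np.array([0.30, 0.30])
    z_base = 0.05

    # --- canopy voxels: sample interior of the half-ellipsoid, voxelize
    n_vox_target = max(20, cfg.cloud_points // 8)
    samples = rng.uniform(-1, 1, size=(n_vox_target * 4, 3))
    inside = (samples**2).sum(axis=1) <= 1.0
    samples = samples[inside & (samples[:, 2] >= 0)]
    pts = np.column_stack([
        center[0] + semi_w * samples[:, 0],
        center[1] + semi_w * samples[:, 1],
        z_base + height * samples[:, 2],
    ])
    canopy_vox = np.unique(np.floor(pts / e).astype(np.int64), axis=0)

    canopy_counts = rng.integers(5, 12, size=len(canopy_vox))
    canopy_xyz = _cluster_points(canopy_vox, canopy_counts, rng)
    leaf = _leaf_reflectance(traits.TRN, rng, cfg.leaf_color_jitter)
    canopy_rgb = np.clip(
        leaf * 255.0 + 8.0 * rng.normal(size=(len(canopy_xyz), 3)), 0, 255
    )

    # --- background plane voxels at z-index 0, including the origin cell
    plane_span = int(0.5 / e)
    n_plane = 60
    plane_xy = rng.integers(0, plane_span, size=(n_plane, 2))
    plane_vox = np.unique(
        np.vstack([[[0, 0, 0]], np.column_stack([plane_xy, np.zeros(n_plane, np.int64)])]),
        axis=0,
    )
    plane_counts = rng.integers(5, 10, size=len(plane_vox))
    plane_xyz = _cluster_points(plane_vox, plane_counts, rng)
    plane_xyz[0] = 0.0  # pin the bounding-box minimum corner exactly
    plane_rgb = np.clip(25.0 + 5.0 * rng.normal(size=(len(plane_xyz), 3)), 0, 255)

    # --- isolated noise points in voxels disjoint from every persistent cell
    occupied = {tuple(v) for v in canopy_vox} | {tuple(v) for v in plane_vox}
    noise_vox: list[tuple[int, int, int]] = []
    noise_counts: list[int] = []
    remaining = cfg.background_noise_points
    while remaining > 0:
        cand = (
            int(rng.integers(0, plane_span)),
            int(rng.integers(0, plane_span)),
            int(rng.integers(1, int(0.6 / e))),
        )
        if cand in occupied:
            continue
        occupied.add(cand)
        k = int(min(remaining, rng.integers(1, 5)))
        noise_vox.append(cand)
        noise_counts.append(k)
        remaining -= k
    if noise_vox:
        noise_xyz = _cluster_points(np.array(noise_vox), np.array(noise_counts), rng)
        noise_rgb = rng.uniform(0, 120, size=(len(noise_xyz), 3))
    else:
        noise_xyz = np.empty((0, 3))
        noise_rgb = np.empty((0, 3))

    xyz = np.concatenate([canopy_xyz, plane_xyz, noise_xyz])
    rgb = np.concatenate([canopy_rgb, plane_rgb, noise_rgb])
    cloud = PlantPointCloud(xyz=xyz, colors=rgb, color_range="0-255")
    plant_ids = np.arange(len(canopy_xyz))
    noise_ids = np.arange(len(xyz) - len(noise_xyz), len(xyz))
    return cloud, plant_ids, noise_ids


def _plant_streams(cfg: ExperimentConfig):
    """Per-plant (trait, image, cloud) RNGs spawned from the experiment seed."""
    root = np.random.SeedSequence(cfg.seed)
    for child in root.spawn(cfg.n_plants):
        t, i, c = child.spawn(3)
        yield (
            np.random.default_rng(t),
            np.random.default_rng(i),
            np.random.default_rng(c),
        )


def _dose_assignments(cfg: ExperimentConfig) -> list[float]:
    doses = []
    for d, r in zip(cfg.doses_ppm, cfg.replicates_per_dose):
        doses.extend([float(d)] * int(r))
    return doses


def generate_traits(cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Trait table only (plant_id, dose_ppm, TRN, NO3, DW) — fast path.

    Uses the same per-plant trait substream as :func:`generate_experiment`,
    so the values are identical to the full generator's.
    """
    cfg = cfg or ExperimentConfig()
    rows = []
    for (trait_rng, _, _), dose, i in zip(
        _plant_streams(cfg), _dose_assignments(cfg), range(cfg.n_plants)
    ):
        t = _draw_traits(dose, cfg, trait_rng)
        rows.append({"plant_id": f"P{i+1:03d}", "dose_ppm": dose,
                     "TRN": t.TRN, "NO3": t.NO3, "DW": t.DW})
    return pd.DataFrame(rows)


def generate_experiment(cfg: ExperimentConfig | None = None) -> list[SyntheticPlant]:
    """Generate the full synthetic experiment (traits, imagery, clouds).

    Deterministic given ``cfg.seed``: the same config yields bitwise-identical
    outputs on repeated calls.
    """
    cfg = cfg or ExperimentConfig()
    plants = []
    for i, ((trait_rng, img_rng, cloud_rng), dose) in enumerate(
        zip(_plant_streams(cfg), _dose_assignments(cfg))
    ):
        traits = _draw_traits(dose, cfg, trait_rng)
        raw, dark, white, mask = _synthesize_image(traits, cfg, img_rng)
        cloud, plant_ids, noise_ids = _synthesize_cloud(traits, cfg, cloud_rng)
        plants.append(SyntheticPlant(
            plant_id=f"P{i+1:03d}",
            dose_ppm=dose,
            traits=traits,
            image=raw,
            dark_frame=dark,
            white_frame=white,
            true_leaf_mask=mask,
            cloud=cloud,
            true_plant_point_ids=plant_ids,
            true_noise_point_ids=noise_ids,
        ))
    return plants


def write_experiment(plants: Sequence[SyntheticPlant], out_dir: str | Path) -> Path:
    """Write images/masks (TIFF/PNG), clouds (ascii PLY), traits CSV, manifest JSON."""
    from . import io as nio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "clouds").mkdir(exist_ok=True)
    manifest = {"plants": []}
    rows = []
    for p in plants:
        img = out / "images" / f"{p.plant_id}.tif"
        dark = out / "images" / f"{p.plant_id}_dark.tif"
        white = out / "images" / f"{p.plant_id}_white.tif"
        mask = out / "images" / f"{p.plant_id}_mask.png"
        ply = out / "clouds" / f"{p.plant_id}.ply"
        nio.write_raster(img, p.image)
        nio.write_raster(dark, p.dark_frame)
        nio.write_raster(white, p.white_frame)
        nio.write_mask(mask, p.true_leaf_mask)
        nio.save_point_cloud(p.cloud, ply)
        t = p.traits
        rows.append({"plant_id": p.plant_id, "dose_ppm": p.dose_ppm,
                     "TRN": t.TRN, "NO3": t.NO3, "DW": t.DW})
        manifest["plants"].append({
            "plant_id": p.plant_id, "dose_ppm": p.dose_ppm,
            "image": img.name, "dark": dark.name, "white": white.name,
            "mask": mask.name, "cloud": ply.name,
        })
    traits_csv = out / "traits.csv"
    pd.DataFrame(rows).to_csv(traits_csv, index=False)
    manifest["traits"] = traits_csv.name
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
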