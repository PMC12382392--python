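"""Structural trait extraction from colored plant point clouds.

A handheld-LiDAR scan of a potted plant yields a fused point cloud holding the
plant canopy, the dark background plane, and scattered acquisition noise. The
processing chain is: voxel-density denoising (drop points in sparse 1 cm
voxels), two-class K-means on the RGB attributes to split plant from
background, then nine canopy traits: height (HT), crown width (CW), convex or
alpha-shape crown volume (CV), point count (PC), point density (PD = PC/CV),
per-voxel count variance (CR), and the counts of points above 75/50/25 % of
the plant height (PC75/PC50/PC25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

__all__ = [
    "PlantPointCloud",
    "HullConfig",
    "StructuralFeatures",
    "voxel_indices",
    "density_keep_mask",
    "denoise",
    "segment_plant",
    "extract_features",
]


@dataclass(frozen=True)
class PlantPointCloud:
    """Points (x, y, z in meters) with per-point RGB color attributes.

    ``color_range`` records whether colors are stored on 0–255 or 0–1 scale.
    """

    xyz: np.ndarray      # (M, 3) float
    colors: np.ndarray   # (M, 3) float
    color_range: str = "0-255"

    def __post_init__(self) -> None:
        xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        colors = np.atleast_2d(np.asarray(self.colors, dtype=float))
        if xyz.shape[1] != 3 or colors.shape != xyz.shape:
            raise ValueError("xyz and colors must both be (M, 3)")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if self.color_range not in ("0-255", "0-1"):
            raise ValueError("color_range must be '0-255' or '0-1'")
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "colors", colors)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def colors01(self) -> np.ndarray:
        """Colors rescaled to [0, 1]."""
        if self.color_range == "0-1":
            return self.colors
        return self.colors / 255.0

    def select(self, idx: np.ndarray) -> "PlantPointCloud":
        return replace(self, xyz=self.xyz[idx], colors=self.colors[idx])


@dataclass(frozen=True)
class HullConfig:
    """Canopy-volume envelope: plain convex hull or alpha-shape subcomplex.

    In alpha mode, Delaunay tetrahedra with circumradius > ``alpha`` (meters)
    are discarded before summing volumes, giving a tighter, possibly concave
    envelope; alpha-shape volume never exceeds the convex volume.
    """

    mode: str = "convex"
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("convex", "alpha"):
            raise ValueError("hull mode must be 'convex' or 'alpha'")
        if self.mode == "alpha" and self.alpha <= 0:
            raise ValueError("alpha must be positive in alpha mode")


@dataclass(frozen=True)
class StructuralFeatures:
    """The nine plant-level structural traits (units: m, m³, counts)."""

    ht: float
    cw: float
    cv: float
    pc: int
    pd: float       # NaN when the hull is degenerate (cv == 0)
    cr: float
    pc75: int
    pc50: int
    pc25: int
    plant_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "HT": self.ht, "CW": self.cw, "CV": self.cv, "PC": self.pc,
            "PD": self.pd, "CR": self.cr, "PC75": self.pc75,
            "PC50": self.pc50, "PC25": self.pc25,
        }


FEATURE_NAMES = ("HT", "CW", "CV", "PC", "PD", "CR", "PC75", "PC50", "PC25")


def voxel_indices(xyz: np.ndarray, grid_edge: float, origin: np.ndarray | None = None) -> np.ndarray:
    """Integer voxel index of each point on a grid anchored at ``origin``.

    ``origin`` defaults to the cloud's bounding-box minimum corner; because
    the partition depends on it, callers that need reproducible grids should
    pass it explicitly.
    """
    xyz = np.asarray(xyz, dtype=float)
    if grid_edge <= 0:
        raise ValueError("grid_edge must be positive")
    if origin is None:
        origin = xyz.min(axis=0)
    return np.floor((xyz - origin) / grid_edge).astype(np.int64)


def _voxel_counts(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(inverse mapping point->cell, per-cell counts) for integer voxel indices."""
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    return inverse, counts


def density_keep_mask(
    cloud: PlantPointCloud,
    grid_edge: float = 0.01,
    min_count: int = 4,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of points in voxels holding strictly more than ``min_count`` points."""
    inverse, counts = _voxel_counts(voxel_indices(cloud.xyz, grid_edge, origin))
    return counts[inverse] > min_count


def denoise(
    cloud: PlantPointCloud,
    grid_edge: float = 0.01,
    min_count: int = 4,
    origin: np.ndarray | None = None,
) -> PlantPointCloud:
    """Remove isolated points by voxel point-density thresholding.

    The cloud is partitioned into cubic voxels of edge ``grid_edge`` (default
    1 cm) anchored at ``origin`` (default: bounding-box minimum corner); only
    points in voxels whose cardinality exceeds ``min_count`` (default 4, i.e.
    cells of ≥ 5 points) are kept. Idempotent under a fixed origin. If every
    voxel is sparse, an empty cloud is returned with a warning rather than an
    exception.
    """
    if len(cloud) == 0:
        raise ValueError("cannot denoise an empty cloud")
    keep = density_keep_mask(cloud, grid_edge, min_count, origin)
    if not keep.any():
        warnings.warn("denoise removed every point: all voxels below the density threshold")
    return cloud.select(keep)


class SegmentationResult(NamedTuple):
    plant: PlantPointCloud
    background: PlantPointCloud
    plant_indices: np.ndarray
    background_indices: np.ndarray


def _exg(colors01: np.ndarray) -> np.ndarray:
    r, g, b = colors01[:, 0], colors01[:, 1], colors01[:, 2]
    return 2.0 * g - r - b


def _canonical_centers(colors: np.ndarray) -> np.ndarray:
    """Deterministic, point-order-invariant 2-center init (farthest-point style).

    First center: color farthest from the mean color; second: color farthest
    from the first. Ties broken by lexicographically smallest color, so a
    permutation of the points yields the same centers.
    """
    def far_from(ref: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(colors - ref, axis=1)
        cand = colors[d == d.max()]
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
        return cand[order[0]]

    c1 = far_from(colors.mean(axis=0))
    c2 = far_from(c1)
    return np.vstack([c1, c2])


def segment_plant(cloud: PlantPointCloud, seed: int = 0) -> SegmentationResult:
    """Split the cloud into plant and background by K-means (k=2) on color.

    Clustering uses only the RGB attributes; the cluster with the higher mean
    excess-green (2g − r − b) is returned as the plant. Initialization is a
    deterministic farthest-point rule, so the partition does not depend on
    point order.

    Raises
    ------
    ValueError
        if the cloud has < 2 points or all colors are identical (degenerate
        clustering).
    """
    if len(cloud) < 2:
        raise ValueError("need at least 2 points to segment")
    colors = cloud.colors01
    if np.all(colors == colors[0]):
        raise ValueError("degenerate clustering: all point colors are identical")

    centers = _canonical_centers(colors)
    km = KMeans(n_clusters=2, init=centers, n_init=1, random_state=seed)
    labels = km.fit_predict(colors)

    exg_means = [
        _exg(colors[labels == k]).mean() if np.any(labels == k) else -np.inf
        for k in (0, 1)
    ]
    plant_label = int(np.argmax(exg_means))
    plant_idx = np.flatnonzero(labels == plant_label)
    bg_idx = np.flatnonzero(labels != plant_label)
    return SegmentationResult(
        plant=cloud.select(plant_idx),
        background=cloud.select(bg_idx),
        plant_indices=plant_idx,
        background_indices=bg_idx,
    )


def _max_pairwise_xy(xy: np.ndarray) -> float:
    """Exact planar diameter: pairwise maximum over 2-D convex-hull vertices.

    Restricting to hull vertices is lossless (the diameter of a point set is
    attained at hull vertices); for degenerate (collinear) sets the brute
    force over all points is used.
    """
    if xy.shape[0] < 2:
        return 0.0
    if xy.shape[0] > 3:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass  # collinear: brute force below is still exact
    return float(pdist(xy).max())


def _tetra_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c, d = (pts[simplices[:, i]] for i in range(4))
    return np.abs(np.einsum("ij,ij->i", a - d, np.cross(b - d, c - d))) / 6.0


def _tetra_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    radii = np.empty(len(simplices))
    for i, s in enumerate(simplices):
        p = pts[s]
        a = 2.0 * (p[1:] - p[0])
        rhs = np.einsum("ij,ij->i", p[1:], p[1:]) - p[0] @ p[0]
        try:
            center = np.linalg.solve(a, rhs)
            radii[i] = np.linalg.norm(center - p[0])
        except np.linalg.LinAlgError:
            radii[i] = np.inf  # flat tetrahedron: treated as unbounded
    return radii


def hull_volume(xyz: np.ndarray, hull: HullConfig = HullConfig()) -> float:
    """Canopy volume of a point set per the hull configuration; 0 if degenerate."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[0] < 4:
        return 0.0
    try:
        if hull.mode == "convex":
            return float(ConvexHull(xyz).volume)
        tri = Delaunay(xyz)
        keep = _tetra_circumradii(xyz, tri.simplices) <= hull.alpha
        if not keep.any():
            return 0.0
        return float(_tetra_volumes(xyz, tri.simplices[keep]).sum())
    except QhullError:
        return 0.0


def extract_features(
    plant: PlantPointCloud,
    grid_edge: float = 0.01,
    hull: HullConfig = HullConfig(),
    percentile_counts: bool = False,
    plant_id: str = "",
) -> StructuralFeatures:
    """Compute the nine structural traits of a segmented plant cloud.

    HT is the z-extent (max z − min z), which makes the traits invariant to
    the arbitrary vertical offset of a handheld scan. CW is the exact maximum
    pairwise distance of the points projected on the ground (X-Y) plane. CV is
    the hull volume (convex by default); a degenerate hull gives CV = 0 and
    PD = NaN. CR is the population variance of per-occupied-voxel point
    counts. PCq counts points higher than q·HT above the plant base for
    q ∈ {0.75, 0.5, 0.25}; with ``percentile_counts=True`` the thresholds are
    the z-percentiles instead (in which case the counts are fixed fractions
    of PC by construction).
    """
    if len(plant) == 0:
        raise ValueError("plant cloud is empty")
    xyz = plant.xyz
    z = xyz[:, 2]
    z0 = z.min()
    ht = float(z.max() - z0)
    cw = _max_pairwise_xy(xyz[:, :2])
    cv = hull_volume(xyz, hull)
    pc = len(plant)
    pd_ = pc / cv if cv > 0 else float("nan")

    _, counts = _voxel_counts(voxel_indices(xyz, grid_edge))
    cr = float(np.var(counts))

    if percentile_counts:
        thresholds = [np.percentile(z, q) for q in (75, 50, 25)]
        pcq = [int(np.count_nonzero(z > t)) for t in thresholds]
    else:
        pcq = [int(np.count_nonzero(z - z0 > q * ht)) for q in (0.75, 0.50, 0.25)]

    return StructuralFeatures(
        ht=ht, cw=cw, cv=cv, pc=pc, pd=pd_, cr=cr,
        pc75=pcq[0], pc50=pcq[1], pc25=pcq[2], plant_id=plant_id,
    )
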