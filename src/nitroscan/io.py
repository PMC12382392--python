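"""Raster and point-cloud I/O.

Rasters (raw DN images, calibration frames) are float TIFFs; binary masks are
8-bit PNGs. Point clouds are PLY files with x, y, z, red, green, blue
(read/written through trimesh) or whitespace-delimited XYZRGB text.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import trimesh

from .structural import PlantPointCloud

__all__ = [
    "read_raster", "write_raster", "read_mask", "write_mask",
    "load_point_cloud", "save_point_cloud",
]


def write_raster(path: str | Path, arr: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32), photometric="rgb")


def read_raster(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 127


def save_point_cloud(cloud: PlantPointCloud, path: str | Path) -> None:
    """Write an ascii PLY (x, y, z, red, green, blue) or .xyz text file."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        colors = cloud.colors if cloud.color_range == "0-255" else cloud.colors * 255.0
        pc = trimesh.PointCloud(
            vertices=cloud.xyz, colors=np.clip(colors, 0, 255).astype(np.uint8)
        )
        path.write_bytes(pc.export(file_type="ply", encoding="ascii"))
    else:
        colors = cloud.colors if cloud.color_range == "0-255" else cloud.colors * 255.0
        np.savetxt(path, np.column_stack([cloud.xyz, colors]), fmt="%.6f")


def load_point_cloud(path: str | Path) -> PlantPointCloud:
    """Read a PLY (binary or ascii) or whitespace-delimited XYZRGB text file."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        pc = trimesh.load(str(path), process=False)
        xyz = np.asarray(pc.vertices, dtype=float)
        colors = np.asarray(pc.colors, dtype=float)[:, :3]  # drop alpha
        return PlantPointCloud(xyz=xyz, colors=colors, color_range="0-255")
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] < 6:
        raise ValueError("XYZRGB text file needs 6 columns: x y z r g b")
    return PlantPointCloud(xyz=data[:, :3], colors=data[:, 3:6], color_range="0-255")
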