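"""Shape descriptors of the ROI mask — 14 values, mask-only.

Surface area and mesh volume come from a marching-cubes triangulation of the
(zero-padded) mask at iso-level 0.5, in physical mm; axis lengths from the
principal components of the voxel-center point cloud.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

SHAPE_NAMES = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]


def _mesh(mask: np.ndarray, spacing: Sequence[float]):
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull first when large."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)), border_value=0)
    surf = mask & ~eroded
    return np.argwhere(surf)


def shape_features(mask: np.ndarray, spacing: Sequence[float]) -> Dict[str, float]:
    mask = mask.astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    out = dict.fromkeys(SHAPE_NAMES, 0.0)
    out["VoxelVolume"] = n * voxel_volume
    if n == 0:
        return out

    verts, faces = _mesh(mask, spacing)
    volume = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = volume
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / volume if volume > 0 else 0.0
    out["Sphericity"] = (
        (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    )

    surf_idx = _surface_voxels(mask)
    phys = surf_idx * spacing
    out["Maximum3DDiameter"] = _max_pairwise(phys)
    # per-plane maxima: fix one index, measure in the remaining two axes
    for name, fixed_axis in (
        ("Maximum2DDiameterSlice", 2),   # fixed z: x-y plane
        ("Maximum2DDiameterColumn", 0),  # fixed x: y-z plane
        ("Maximum2DDiameterRow", 1),     # fixed y: x-z plane
    ):
        best = 0.0
        for v in np.unique(surf_idx[:, fixed_axis]):
            pts = phys[surf_idx[:, fixed_axis] == v]
            keep = [a for a in range(3) if a != fixed_axis]
            best = max(best, _max_pairwise(pts[:, keep]))
        out[name] = best

    coords = np.argwhere(mask) * spacing
    if n > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))  # ascending
        eig = np.clip(eig, 0.0, None)
        out["MajorAxisLength"] = 4.0 * np.sqrt(eig[2])
        out["MinorAxisLength"] = 4.0 * np.sqrt(eig[1])
        out["LeastAxisLength"] = 4.0 * np.sqrt(eig[0])
        if eig[2] > 0:
            out["Elongation"] = float(np.sqrt(eig[1] / eig[2]))
            out["Flatness"] = float(np.sqrt(eig[0] / eig[2]))
        else:
            out["Elongation"] = 1.0
            out["Flatness"] = 1.0
    else:
        out["Elongation"] = 1.0
        out["Flatness"] = 1.0
    return out
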