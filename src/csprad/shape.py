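"""3D shape descriptors of a binary lesion mask (spacing-aware).

Mesh-based quantities (surface area, mesh volume, diameters) use a
marching-cubes surface at the 0.5 iso-level of the padded indicator;
axis lengths come from the principal components of the physical voxel
coordinates (4 * sqrt(eigenvalue) convention).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from skimage import measure

from .image import ImageVolume, as_mask

SHAPE_FEATURES = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 1500:
        points = points[:: len(points) // 1500 + 1]
    return float(pdist(points).max())


def shape_features(mask: ImageVolume) -> dict[str, float]:
    m = as_mask(mask)
    spacing = mask.spacing
    feats = dict.fromkeys(SHAPE_FEATURES, float("nan"))
    nv = int(m.sum())
    if nv == 0:
        return feats
    feats["VoxelVolume"] = nv * mask.voxel_volume

    idx = np.argwhere(m).astype(np.float64)
    coords = idx * np.asarray(spacing)
    feats.update(_pca_axes(coords))

    padded = np.pad(m.astype(np.float64), 1)
    try:
        verts, faces, *_ = measure.marching_cubes(padded, level=0.5,
                                                  spacing=spacing)
    except (ValueError, RuntimeError):
        return feats   # mesh undefined (e.g. single-voxel mask)
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    surface = float(measure.mesh_surface_area(verts, faces))
    mesh_vol = float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0)
    feats["SurfaceArea"] = surface
    feats["MeshVolume"] = mesh_vol
    if mesh_vol > 0 and surface > 0:
        feats["SurfaceVolumeRatio"] = surface / mesh_vol
        feats["Sphericity"] = (36 * np.pi * mesh_vol ** 2) ** (1 / 3) / surface
    feats["Maximum3DDiameter"] = _max_pairwise(verts)
    feats["Maximum2DDiameterSlice"] = _max_pairwise(verts[:, (0, 1)])   # x-y
    feats["Maximum2DDiameterColumn"] = _max_pairwise(verts[:, (0, 2)])  # x-z
    feats["Maximum2DDiameterRow"] = _max_pairwise(verts[:, (1, 2)])     # y-z
    return feats


def _pca_axes(coords: np.ndarray) -> dict[str, float]:
    out = {"MajorAxisLength": 0.0, "MinorAxisLength": 0.0,
           "LeastAxisLength": 0.0, "Elongation": 1.0, "Flatness": 1.0}
    if len(coords) < 2:
        return out
    cov = np.cov(coords, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0, None)
    out["MajorAxisLength"] = float(4 * np.sqrt(eig[0]))
    out["MinorAxisLength"] = float(4 * np.sqrt(eig[1]))
    out["LeastAxisLength"] = float(4 * np.sqrt(eig[2]))
    if eig[0] > 0:
        out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
        out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    return out
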