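"""Shape features of a binary tumor mask (mask-only; independent of any
intensity filter).

Volume is the voxel-count volume; surface area and mesh volume come from a
marching-cubes surface of the (zero-padded) mask at physical spacing;
sphericity is the isoperimetric ratio (36 pi V^2)^(1/3) / A.  Axis lengths
derive from the principal components of the voxel-centre point cloud
(4 * sqrt(eigenvalue), the full axis length of the matching ellipsoid).
Degenerate masks (too small or flat for a mesh) fall back to exposed
voxel-face area.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from ..io import TumorMask

__all__ = ["shape_features", "SHAPE_FEATURES"]

SHAPE_FEATURES = (
    "VoxelVolume", "MeshVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(surface_area, mesh_volume) via marching cubes on the padded mask."""
    padded = np.pad(mask.astype(np.float64), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=tuple(spacing)
        )
    except (ValueError, RuntimeError):
        # Fallback for degenerate masks: exposed voxel faces.
        area = 0.0
        sp = np.asarray(spacing, float)
        face_areas = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
        m = mask.astype(np.int8)
        for axis, fa in enumerate(face_areas):
            d = np.abs(np.diff(np.pad(m, 1), axis=axis))
            area += fa * d.sum()
        vol = mask.sum() * float(np.prod(sp))
        return float(area), float(vol)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(np.abs(np.einsum(
        "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ).sum()) / 6.0)
    return area, vol


def _surface_points(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    boundary = mask & ~ndimage.binary_erosion(mask)
    return np.argwhere(boundary)


def _max_diameter(points_mm: np.ndarray) -> float:
    if len(points_mm) < 2:
        return 0.0
    if len(points_mm) > 10:
        try:
            hull = ConvexHull(points_mm, qhull_options="QJ")
            points_mm = points_mm[hull.vertices]
        except QhullError:
            pass
    return float(pdist(points_mm).max())


def shape_features(mask: TumorMask) -> dict[str, float]:
    m = mask.labels.astype(bool)
    spacing = np.asarray(mask.spacing, dtype=float)
    n = int(m.sum())
    voxel_volume = n * float(np.prod(spacing))
    area, mesh_volume = _mesh(m, spacing)
    if mesh_volume <= 0:
        mesh_volume = voxel_volume

    sphericity = float(
        (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / area
    ) if area > 0 else float("nan")

    surf = _surface_points(m).astype(np.float64) * spacing
    d3 = _max_diameter(surf)
    # In-plane maximum diameters: max over the fixed-index planes.
    d2 = []
    for axis in range(3):
        best = 0.0
        coords = _surface_points(m)
        vals = coords[:, axis]
        for plane in np.unique(vals):
            pts = coords[vals == plane].astype(np.float64) * spacing
            keep = [a for a in range(3) if a != axis]
            best = max(best, _max_diameter(pts[:, keep]))
        d2.append(best)

    pts = np.argwhere(m).astype(np.float64) * spacing
    if len(pts) > 1:
        cov = np.cov(pts.T, bias=False)
        eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else float("nan")
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else float("nan")

    return {
        "VoxelVolume": float(voxel_volume),
        "MeshVolume": float(mesh_volume),
        "SurfaceArea": float(area),
        "SurfaceVolumeRatio": float(area / mesh_volume),
        "Sphericity": sphericity,
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": d2[0],   # axial plane (fixed z)
        "Maximum2DDiameterColumn": d2[1],  # coronal plane (fixed y)
        "Maximum2DDiameterRow": d2[2],     # sagittal plane (fixed x)
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
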