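"""Morphological (shape) features — 18 descriptors of the binary ROI.

The reported volume is voxel-counted.  Surface area and the mesh volume
used inside the sphericity-type indices come from a marching-cubes mesh of
the indicator, anti-aliased with a half-voxel Gaussian so the staircase
artefact of binary meshes (which otherwise inflates the area of a digital
ball by ~8 % at any radius) is suppressed; tiny masks whose smoothed field
never reaches the 0.5 level fall back to the binary mesh.  The
principal-axis descriptors use the eigenvalues of the physical voxel-centre
covariance.  Shape features depend only on the mask and its spacing, never
on intensities.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..volumes import ROIMask

__all__ = ["SHAPE_FEATURES", "shape_features"]

SHAPE_FEATURES = (
    "voxel_count",
    "volume_mm3",
    "surface_area_mm2",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "equivalent_spherical_diameter",
    "maximum_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "bounding_box_x_mm",
    "bounding_box_y_mm",
    "bounding_box_z_mm",
)


def _surface_mesh(mask: np.ndarray, spacing: tuple[float, float, float]
                  ) -> tuple[float, float]:
    """(surface area, enclosed mesh volume) of the ROI boundary."""
    padded = np.pad(mask.astype(float), 3)
    smoothed = ndimage.gaussian_filter(padded, 0.5)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    volume = float(abs(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum()) / 6.0)
    return area, volume


def _max_diameter(points: np.ndarray) -> float:
    if len(points) == 1:
        return 0.0
    pts = points
    if len(points) > 4:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pts = points
    return float(pdist(pts).max())


def shape_features(mask: ROIMask) -> dict[str, float]:
    """Compute the 18 shape features of a nonempty ROI mask."""
    if mask.voxel_count() == 0:
        raise ValueError("shape features require a nonempty mask")
    m = mask.values
    spacing = np.asarray(mask.spacing_mm, dtype=float)
    n = int(m.sum())
    volume = n * float(spacing.prod())
    area, mesh_volume = _surface_mesh(m, tuple(spacing))

    ijk = np.argwhere(m)
    xyz = ijk * spacing  # physical voxel centres
    r_eq = (3.0 * mesh_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    cov = np.cov(xyz.T) if n > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
    else:  # single voxel / degenerate: treat as isotropic
        elongation = flatness = 1.0

    bbox = (ijk.max(axis=0) - ijk.min(axis=0) + 1) * spacing
    return {
        "voxel_count": float(n),
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "surface_to_volume_ratio": area / mesh_volume,
        "sphericity": float(np.pi ** (1 / 3) * (6.0 * mesh_volume) ** (2 / 3) / area),
        "compactness1": float(mesh_volume / (np.sqrt(np.pi) * area**1.5)),
        "compactness2": float(36.0 * np.pi * mesh_volume**2 / area**3),
        "spherical_disproportion": float(area / (4.0 * np.pi * r_eq**2)),
        "equivalent_spherical_diameter": float(2.0 * r_eq),
        "maximum_3d_diameter": _max_diameter(xyz),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elongation,
        "flatness": flatness,
        "bounding_box_x_mm": float(bbox[0]),
        "bounding_box_y_mm": float(bbox[1]),
        "bounding_box_z_mm": float(bbox[2]),
    }
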