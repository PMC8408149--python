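"""Per-precipitate morphometry: volume, Maximum Feret diameter, aspect
ratio, and mean absorption.

The Feret diameter along a direction is the distance between the two
parallel planes perpendicular to that direction that just enclose the
object; the Maximum Feret diameter (MFD) is its maximum over all
directions, i.e. the object's longest caliper dimension.  For a voxel
object the MFD equals the diameter of the convex hull of its voxel
centers, plus one voxel pitch to account for the physical extent of the
voxels themselves (an n-voxel straight rod thus measures exactly
n * pitch).

The aspect ratio AR = (minimum principal-axis extent) / MFD lies in
(0, 1]: ~1 for spheres, -> 0 for chain- or strip-like objects.  The
minimum extent uses peak-to-peak projections onto the three principal
axes of the voxel-center covariance (plus one pitch) — an approximation
to the exhaustive minimum Feret that matches it closely for compact and
elongated particles alike.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .segmentation import LabelMap
from .volume_io import AttenuationVolume, PrecipitateRecord

__all__ = ["max_feret", "min_extent", "principal_extents", "aspect_ratio",
           "measure"]


def _points_um(voxel_coords, pitch_um: float) -> np.ndarray:
    pts = np.asarray(voxel_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("voxel_coords must be a nonempty (n, 3) array")
    return pts * float(pitch_um)


def _hull_vertices(pts: np.ndarray) -> np.ndarray:
    if len(pts) < 5:
        return pts
    try:
        return pts[ConvexHull(pts).vertices]
    except QhullError:  # degenerate (coplanar/collinear) point sets
        return pts


def max_feret(voxel_coords, pitch_um: float) -> float:
    """Maximum Feret diameter (µm) of a voxel object.

    Computed as the maximum pairwise distance over convex-hull vertices of
    the voxel centers, plus one pitch.  A single voxel measures exactly
    one pitch.
    """
    pts = _points_um(voxel_coords, pitch_um)
    if len(pts) == 1:
        return float(pitch_um)
    verts = _hull_vertices(pts)
    return float(pdist(verts).max()) + float(pitch_um)


def principal_extents(voxel_coords, pitch_um: float) -> np.ndarray:
    """Peak-to-peak extents (µm, descending) along the three principal
    axes of the voxel-center covariance, each plus one pitch."""
    pts = _points_um(voxel_coords, pitch_um)
    centered = pts - pts.mean(axis=0)
    if len(pts) == 1:
        return np.full(3, float(pitch_um))
    cov = np.cov(centered.T)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + float(pitch_um)
    return np.sort(extents)[::-1]


def min_extent(voxel_coords, pitch_um: float) -> float:
    """Smallest principal-axis extent (µm): minimum-Feret approximation."""
    return float(principal_extents(voxel_coords, pitch_um)[-1])


def aspect_ratio(voxel_coords, pitch_um: float) -> float:
    """AR = min_extent / max_feret, clipped to (0, 1]."""
    mfd = max_feret(voxel_coords, pitch_um)
    ar = min_extent(voxel_coords, pitch_um) / mfd
    return float(np.clip(ar, np.finfo(float).tiny, 1.0))


def measure(label_map: LabelMap, volume: AttenuationVolume) -> list:
    """Measure every labeled precipitate.

    Returns one :class:`~lensxct.volume_io.PrecipitateRecord` per label,
    ordered by id, with voxel count, physical volume (voxel_count *
    pitch^3), centroid (mean voxel center, µm), MFD, minimum extent,
    aspect ratio and mean attenuation over the object's voxels.  The
    distance-to-center and anterior fields are left for the spatial stage.

    Raises
    ------
    ValueError
        If the label map and volume differ in shape or pitch.
    """
    if label_map.labels.shape != volume.grid.shape:
        raise ValueError("label map and volume shapes differ")
    if not np.isclose(label_map.voxel_pitch_um, volume.voxel_pitch_um):
        raise ValueError("label map and volume voxel pitches differ")
    pitch = float(volume.voxel_pitch_um)
    labels = label_map.labels
    n = label_map.n_labels
    records = []
    objects = ndimage.find_objects(labels, max_label=n)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:  # pragma: no cover - contiguity guaranteed upstream
            continue
        sub = labels[sl] == lab
        coords = np.argwhere(sub) + [s.start for s in sl]
        mfd = max_feret(coords, pitch)
        ext_min = min_extent(coords, pitch)
        centroid = coords.mean(axis=0) * pitch
        records.append(PrecipitateRecord(
            id=lab,
            voxel_count=int(coords.shape[0]),
            volume_um3=float(coords.shape[0]) * pitch ** 3,
            centroid_um=tuple(float(c) for c in centroid),
            mfd_um=mfd,
            min_extent_um=ext_min,
            aspect_ratio=float(np.clip(ext_min / mfd, np.finfo(float).tiny, 1.0)),
            mean_absorption_per_cm=float(volume.grid[sl][sub].mean(dtype=np.float64)),
        ))
    return records
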