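"""Lens geometry and radial shell analysis.

Locates the lens (largest bright connected component over an Otsu
threshold), takes its centroid as the lens center, maps each precipitate's
Euclidean distance to that center, histograms the distances, and detects
shell peaks in the lightly smoothed histogram.  The anterior/posterior
split is the sign of each centroid's offset along the volume's anterior
axis.

The lens-mask centroid — not the precipitate-cloud centroid — defines the
center, because the precipitate cloud is anterior-biased and would drag
the center toward it; the alternative reading is available via
``center_of_precipitation``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .volume_io import AttenuationVolume

__all__ = ["RadialProfile", "lens_mask", "lens_center",
           "center_of_precipitation", "radial_profile", "write_profile",
           "DEFAULT_BIN_WIDTH_UM"]

DEFAULT_BIN_WIDTH_UM = 10.0
_SMOOTH_WINDOW = 3          # centered moving average, bins
_PROMINENCE_FRACTION = 0.1  # of the global smoothed maximum

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class RadialProfile:
    """Binned distance-to-center distribution with detected shell peaks.

    ``peaks`` is a list of ``(location_um, prominence)`` tuples sorted by
    location; locations are bin centers.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peaks: list = field(default_factory=list)
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def peak_locations(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


def lens_mask(volume: AttenuationVolume) -> np.ndarray:
    """Binary mask of the lens: largest bright 26-connected component over
    an Otsu threshold between surround and tissue, holes filled.

    Raises
    ------
    ValueError
        If no foreground voxels are found (e.g. an all-zero volume).
    """
    grid = volume.grid
    if grid.max() <= grid.min():
        raise ValueError("volume is constant: no lens tissue to segment")
    thr = threshold_otsu(grid)
    mask = grid > thr
    if not mask.any():
        raise ValueError("no voxels above the Otsu threshold")
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labeled.ravel())
        sizes[0] = 0
        mask = labeled == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def lens_center(mask: np.ndarray, voxel_pitch_um: float) -> np.ndarray:
    """Centroid of the mask's voxel centers, (z, y, x) in µm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no center")
    return np.asarray(ndimage.center_of_mass(mask)) * float(voxel_pitch_um)


def center_of_precipitation(records) -> np.ndarray:
    """Centroid (µm) of the precipitate centroids — the alternative
     'center of precipitation' reading, selectable instead of the
    lens-mask center."""
    if len(records) == 0:
        raise ValueError("no records to take a center from")
    return np.mean([r.centroid_um for r in records], axis=0)


def radial_profile(records, center_um, bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                   anterior_axis: str = "+z") -> RadialProfile:
    """Fill per-record distances/hemisphere flags and bin them radially.

    Mutates each record's ``distance_to_center_um`` (Euclidean distance
    from its centroid to ``center_um``) and ``anterior`` (sign of the
    centroid offset along the anterior axis), then histograms the
    distances from 0 in ``bin_width_um`` steps, smooths with a centered
    3-bin moving average, and marks local maxima whose prominence is at
    least 10% of the global smoothed maximum.

    An empty record list yields all-zero counts and no peaks.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    center = np.asarray(center_um, dtype=float)
    sign = 1.0 if anterior_axis[0] == "+" else -1.0
    axis = _AXIS_INDEX[anterior_axis[1]]

    dists = np.empty(len(records))
    for i, rec in enumerate(records):
        offset = np.asarray(rec.centroid_um, dtype=float) - center
        rec.distance_to_center_um = float(np.linalg.norm(offset))
        rec.anterior = bool(sign * offset[axis] > 0)
        dists[i] = rec.distance_to_center_um

    max_d = dists.max() if len(dists) else 0.0
    n_bins = max(3, int(np.ceil(max_d / bin_width_um)) or 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    if len(dists):
        counts, _ = np.histogram(dists, bins=edges)
    else:
        counts = np.zeros(n_bins, dtype=int)
    smoothed = uniform_filter1d(counts.astype(float), _SMOOTH_WINDOW,
                                mode="constant")
    peaks = _detect_peaks(smoothed, edges)
    return RadialProfile(bin_edges=edges, counts=counts, smoothed=smoothed,
                         peaks=peaks, bin_width_um=float(bin_width_um))


def _detect_peaks(smoothed: np.ndarray, edges: np.ndarray) -> list:
    if smoothed.max(initial=0.0) <= 0:
        return []
    padded = np.concatenate(([0.0], smoothed, [0.0]))  # allow edge-bin peaks
    idx, props = find_peaks(padded,
                            prominence=_PROMINENCE_FRACTION * smoothed.max())
    centers = (edges[:-1] + edges[1:]) / 2.0
    bw = float(edges[1] - edges[0])
    peaks = []
    for i, p in zip(idx, props["prominences"]):
        loc = centers[i - 1] + _parabolic_offset(padded, i) * bw
        peaks.append((float(loc), float(p)))
    return sorted(peaks, key=lambda t: t[0])


def _parabolic_offset(values: np.ndarray, i: int) -> float:
    """Sub-bin vertex offset (in bins, clamped to ±1/2) of the parabola
    through the peak bin and its neighbors; 0 for flat-topped peaks."""
    denom = values[i - 1] - 2.0 * values[i] + values[i + 1]
    if denom >= 0:  # plateau or degenerate
        return 0.0
    return float(np.clip(0.5 * (values[i - 1] - values[i + 1]) / denom,
                         -0.5, 0.5))


def write_profile(profile: RadialProfile, csv_path, peaks_path=None) -> None:
    """Export a radial profile as CSV (bin_center, count, smoothed) plus a
    JSON peak list."""
    frame = pd.DataFrame({
        "bin_center_um": profile.bin_centers,
        "count": profile.counts,
        "smoothed": profile.smoothed,
    })
    frame.to_csv(csv_path, index=False)
    if peaks_path is not None:
        payload = {
            "bin_width_um": profile.bin_width_um,
            "peaks": [{"location_um": loc, "prominence": prom}
                      for loc, prom in profile.peaks],
        }
        Path(peaks_path).write_text(json.dumps(payload, indent=1))
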