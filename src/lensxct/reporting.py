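"""Summary quantifications over a measured precipitate population.

Mirrors the summaries used to characterize lens-core calcification:
fractions of precipitates by Maximum Feret diameter class (below 40 µm,
40-100, 100-200, above 200), an eight-bin absorption histogram, and an
aspect-ratio x log-volume occupancy heat map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import _jsonable

__all__ = ["SummaryReport", "summarize", "MFD_BIN_EDGES_UM",
           "plot_radial_profile", "plot_absorption_histogram",
           "plot_ar_volume_heatmap"]

#: Fixed MFD class edges (µm); chosen to match the thresholds lens-core
#: calcification is conventionally reported against.
MFD_BIN_EDGES_UM = (0.0, 40.0, 100.0, 200.0, np.inf)

_N_ABSORPTION_BINS = 8
_N_AR_BINS = 10
_N_VOLUME_BINS = 10


@dataclass
class SummaryReport:
    """Machine-readable population summary (a pure function of records)."""

    n_precipitates: int
    mfd_bins: np.ndarray               # 4 fractions, sum to 1 when n > 0
    absorption_hist: np.ndarray        # 8 counts
    absorption_bin_edges: np.ndarray   # 9 edges over [0, max absorption]
    ar_volume_heatmap: np.ndarray      # (10 AR bins, 10 log-volume bins)
    ar_bin_edges: np.ndarray
    volume_bin_edges: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonable({
            "n_precipitates": self.n_precipitates,
            "mfd_bin_edges_um": list(MFD_BIN_EDGES_UM),
            "mfd_bins": self.mfd_bins,
            "absorption_hist": self.absorption_hist,
            "absorption_bin_edges_per_cm": self.absorption_bin_edges,
            "ar_volume_heatmap": self.ar_volume_heatmap,
            "ar_bin_edges": self.ar_bin_edges,
            "volume_bin_edges_um3": self.volume_bin_edges,
            "provenance": self.provenance,
        })

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def summarize(records, provenance: dict = None) -> SummaryReport:
    """Summarize measured precipitate records.

    Binning is exhaustive and mutually exclusive: the MFD fractions sum to
    one and the histogram/heat-map counts each sum to the number of
    records.  Empty input yields n = 0 and all-zero histograms.
    """
    provenance = dict(provenance or {})
    n = len(records)
    if n == 0:
        return SummaryReport(
            n_precipitates=0,
            mfd_bins=np.zeros(4),
            absorption_hist=np.zeros(_N_ABSORPTION_BINS, dtype=int),
            absorption_bin_edges=np.linspace(0, 1, _N_ABSORPTION_BINS + 1),
            ar_volume_heatmap=np.zeros((_N_AR_BINS, _N_VOLUME_BINS), dtype=int),
            ar_bin_edges=np.linspace(0, 1, _N_AR_BINS + 1),
            volume_bin_edges=np.logspace(0, 1, _N_VOLUME_BINS + 1),
            provenance=provenance)

    mfd = np.array([r.mfd_um for r in records])
    absorption = np.array([r.mean_absorption_per_cm for r in records])
    ar = np.array([r.aspect_ratio for r in records])
    volume = np.array([r.volume_um3 for r in records])

    mfd_counts, _ = np.histogram(mfd, bins=MFD_BIN_EDGES_UM)
    mfd_bins = mfd_counts / n

    abs_max = float(absorption.max())
    abs_edges = np.linspace(0.0, abs_max if abs_max > 0 else 1.0,
                            _N_ABSORPTION_BINS + 1)
    abs_hist, _ = np.histogram(absorption, bins=abs_edges)

    ar_edges = np.linspace(0.0, 1.0, _N_AR_BINS + 1)
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmin == vmax:
        vmin, vmax = vmin * 0.9, vmax * 1.1
    vol_edges = np.logspace(np.log10(vmin), np.log10(vmax), _N_VOLUME_BINS + 1)
    vol_edges[0], vol_edges[-1] = vmin, vmax  # exact endpoints: conserve n
    heatmap, _, _ = np.histogram2d(ar, volume, bins=[ar_edges, vol_edges])

    return SummaryReport(
        n_precipitates=n,
        mfd_bins=mfd_bins,
        absorption_hist=abs_hist.astype(int),
        absorption_bin_edges=abs_edges,
        ar_volume_heatmap=heatmap.astype(int),
        ar_bin_edges=ar_edges,
        volume_bin_edges=vol_edges,
        provenance=provenance)


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_radial_profile(profile, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(profile.bin_centers, profile.counts, width=profile.bin_width_um,
           color="#9ecae1", label="counts")
    ax.plot(profile.bin_centers, profile.smoothed, color="#08519c",
            label="smoothed")
    for loc, _ in profile.peaks:
        ax.axvline(loc, color="#e6550d", ls="--", lw=1)
    ax.set_xlabel("distance to lens center (µm)")
    ax.set_ylabel("precipitate count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_absorption_histogram(report: SummaryReport, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (report.absorption_bin_edges[:-1]
               + report.absorption_bin_edges[1:]) / 2
    width = np.diff(report.absorption_bin_edges)
    colors = plt.get_cmap("rainbow")(np.linspace(0, 1, len(centers)))
    ax.bar(centers, report.absorption_hist, width=width, color=colors)
    ax.set_xlabel("mean absorption (cm$^{-1}$)")
    ax.set_ylabel("precipitate count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ar_volume_heatmap(report: SummaryReport, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.pcolormesh(report.volume_bin_edges, report.ar_bin_edges,
                       report.ar_volume_heatmap, cmap="inferno")
    ax.set_xscale("log")
    ax.set_xlabel("volume (µm$^3$)")
    ax.set_ylabel("aspect ratio")
    fig.colorbar(im, ax=ax, label="precipitate count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
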