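"""Volume, label-map, record-table and configuration I/O.

Conventions used throughout the package (and stated only here):

* arrays are indexed ``(z, y, x)``, 0-based;
* physical positions are voxel centers at ``index * voxel_pitch_um`` µm;
* the anterior pole of the lens lies along the signed axis named in
  ``anterior_axis`` (default ``"+z"``).

Volumes are stored as multi-page 32-bit float TIFF stacks (one page per
z-slice) with a mandatory JSON metadata sidecar carrying the voxel pitch.
A raw binary grid with a sidecar describing dtype and shape is accepted as
an alternative input format.  Measurement tables are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "AttenuationVolume",
    "PrecipitateRecord",
    "RECORD_COLUMNS",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "load_config",
    "save_config",
]


@dataclass
class AttenuationVolume:
    """A reconstructed 3D grid of linear attenuation values.

    Parameters
    ----------
    grid : ndarray, shape (nz, ny, nx)
        Linear attenuation in cm^-1, indexed (z, y, x).
    voxel_pitch_um : float
        Isotropic voxel pitch in µm; must be positive.
    anterior_axis : str
        Signed axis label for the anterior pole, e.g. ``"+z"`` or ``"-z"``.
    meta : dict
        Free-form provenance (seed, config echo, lens center, ...).
    """

    grid: np.ndarray
    voxel_pitch_um: float
    anterior_axis: str = "+z"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a 3D array with nonzero extents")
        if not (self.voxel_pitch_um > 0):
            raise ValueError("voxel_pitch_um must be positive")
        if self.anterior_axis not in ("+z", "-z", "+y", "-y", "+x", "-x"):
            raise ValueError(f"invalid anterior_axis {self.anterior_axis!r}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.grid.shape


#: Column order of the per-precipitate measurement table (stable contract).
RECORD_COLUMNS = [
    "id",
    "voxel_count",
    "volume_um3",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "mfd_um",
    "min_extent_um",
    "aspect_ratio",
    "mean_absorption_per_cm",
    "distance_to_center_um",
    "anterior",
]


@dataclass
class PrecipitateRecord:
    """Morphometric and densitometric measurements of one segmented object.

    ``distance_to_center_um`` and ``anterior`` are filled by the spatial
    analysis stage and are ``None`` until then.  ``centroid_um`` is stored
    (z, y, x) to match array indexing; the CSV columns are x/y/z.
    """

    id: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple  # (z, y, x)
    mfd_um: float
    min_extent_um: float
    aspect_ratio: float
    mean_absorption_per_cm: float
    distance_to_center_um: Optional[float] = None
    anterior: Optional[bool] = None


def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: AttenuationVolume, path, sidecar_path=None) -> Path:
    """Write a volume as a multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    tifffile.imwrite(path, volume.grid.astype(np.float32, copy=False),
                     photometric="minisblack")
    sidecar = {
        "format": "tiff-stack",
        "voxel_pitch_um": float(volume.voxel_pitch_um),
        "anterior_axis": volume.anterior_axis,
        "axis_order": "zyx",
        "shape": [int(s) for s in volume.grid.shape],
        "dtype": "float32",
    }
    sidecar.update(_jsonable(volume.meta))
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_volume(path, sidecar_path=None) -> AttenuationVolume:
    """Read a TIFF stack or raw binary grid with its metadata sidecar.

    The sidecar is mandatory: the physical voxel pitch is never guessed.
    """
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar not found: {sidecar_path} "
            "(a sidecar with voxel_pitch_um is required; pitch is never assumed)"
        )
    meta = json.loads(sidecar_path.read_text())
    if "voxel_pitch_um" not in meta:
        raise ValueError(f"sidecar {sidecar_path} lacks required key 'voxel_pitch_um'")
    pitch = float(meta["voxel_pitch_um"])
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
        if grid.ndim == 2:  # single-page stack
            grid = grid[np.newaxis]
    else:
        if "shape" not in meta or "dtype" not in meta:
            raise ValueError("raw binary volumes require 'shape' and 'dtype' in the sidecar")
        grid = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    extra = {k: v for k, v in meta.items()
             if k not in ("voxel_pitch_um", "anterior_axis", "axis_order",
                          "shape", "dtype", "format")}
    return AttenuationVolume(
        grid=np.asarray(grid, dtype=np.float32),
        voxel_pitch_um=pitch,
        anterior_axis=meta.get("anterior_axis", "+z"),
        meta=extra,
    )


def write_labels(labels: np.ndarray, provenance: dict, path, sidecar_path=None) -> Path:
    """Persist a label map as a 16-bit TIFF stack plus provenance JSON."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; 16-bit label TIFF not possible")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    sidecar_path.write_text(json.dumps(_jsonable(provenance), indent=1))
    return sidecar_path


def read_labels(path, sidecar_path=None):
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    sidecar_path = Path(sidecar_path) if sidecar_path else _default_sidecar(path)
    provenance = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return labels, provenance


def records_to_frame(records: Sequence[PrecipitateRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with the canonical column order."""
    rows = []
    for r in records:
        cz, cy, cx = r.centroid_um
        rows.append({
            "id": r.id,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "centroid_x_um": cx,
            "centroid_y_um": cy,
            "centroid_z_um": cz,
            "mfd_um": r.mfd_um,
            "min_extent_um": r.min_extent_um,
            "aspect_ratio": r.aspect_ratio,
            "mean_absorption_per_cm": r.mean_absorption_per_cm,
            "distance_to_center_um": (np.nan if r.distance_to_center_um is None
                                      else r.distance_to_center_um),
            "anterior": r.anterior,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list:
    records = []
    for _, row in frame.iterrows():
        dist = row["distance_to_center_um"]
        ant = row["anterior"]
        records.append(PrecipitateRecord(
            id=int(row["id"]),
            voxel_count=int(row["voxel_count"]),
            volume_um3=float(row["volume_um3"]),
            centroid_um=(float(row["centroid_z_um"]),
                         float(row["centroid_y_um"]),
                         float(row["centroid_x_um"])),
            mfd_um=float(row["mfd_um"]),
            min_extent_um=float(row["min_extent_um"]),
            aspect_ratio=float(row["aspect_ratio"]),
            mean_absorption_per_cm=float(row["mean_absorption_per_cm"]),
            distance_to_center_um=(None if pd.isna(dist) else float(dist)),
            anterior=(None if pd.isna(ant) else bool(ant)),
        ))
    return records


def write_records(records, path) -> Path:
    """Write per-precipitate measurements to CSV (lossless round-trip).

    Accepts either a list of :class:`PrecipitateRecord` or a DataFrame with
    the canonical columns.  An empty record list yields a header-only CSV.
    """
    path = Path(path)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False)
    return path


def read_records(path) -> list:
    frame = pd.read_csv(Path(path))
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    return frame_to_records(frame)


def load_config(path) -> dict:
    """Load a YAML configuration whose keys mirror PhantomConfig fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return cfg


def save_config(config, path) -> Path:
    path = Path(path)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config), fh, sort_keys=False)
    return path


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays so json/yaml can serialize."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj
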