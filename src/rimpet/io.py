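"""Volumetric containers, NIfTI and table I/O, and pipeline configuration.

All spatial quantities are in millimetres.  Volumes are stored as NIfTI-1
with an affine built from the voxel spacing and origin; voxel indices are
0-based and world coordinates are in mm.  Binary masks are written as
unsigned 8-bit and label maps as unsigned 16-bit images so that round-trips
are bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, GridCompatibilityError, RimpetError, ShapeError

log = logging.getLogger("rimpet")


@dataclass
class Volume3D:
    """A 3D scalar grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values (e.g. a parametric DVR map, a mask).
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ShapeError("Volume3D axes must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def like(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same grid and different data."""
        return Volume3D(data, self.spacing, self.origin)


@dataclass
class DynamicPET4D:
    """A dynamic PET acquisition: a stack of 3D frames plus frame timing.

    ``frame_mid_times`` are frame mid-points in minutes (strictly
    increasing); ``frame_durations`` are frame lengths in minutes.
    """

    frames: np.ndarray
    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_mid_times = np.asarray(self.frame_mid_times, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if self.frames.ndim != 4:
            raise ShapeError(f"DynamicPET4D requires (x,y,z,t) data, got ndim={self.frames.ndim}")
        nt = self.frames.shape[3]
        if len(self.frame_mid_times) != nt or len(self.frame_durations) != nt:
            raise ValueError(
                f"timing length mismatch: {nt} frames, "
                f"{len(self.frame_mid_times)} mid-times, {len(self.frame_durations)} durations"
            )
        if np.any(np.diff(self.frame_mid_times) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]

    def spatial_grid(self) -> Volume3D:
        """A Volume3D carrying the spatial grid (first frame's data)."""
        return Volume3D(self.frames[..., 0], self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer lesion labels aligned to a Volume3D grid.

    0 is background; lesions carry contiguous positive integer ids.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"LabelMap requires a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("label map values must be integers")
            self.labels = self.labels.astype(np.uint16)
        if self.labels.min() < 0:
            raise ValueError("label map values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def as_binary(self) -> np.ndarray:
        return self.labels > 0


def check_same_grid(a, b, context: str = "") -> None:
    """Raise GridCompatibilityError unless a and b share shape and spacing."""
    sa = a.shape if hasattr(a, "shape") else None
    sb = b.shape if hasattr(b, "shape") else None
    if sa != sb:
        raise GridCompatibilityError(f"{context}: shape mismatch {sa} vs {sb}")
    if not np.allclose(a.spacing, b.spacing):
        raise GridCompatibilityError(f"{context}: spacing mismatch {a.spacing} vs {b.spacing}")


@dataclass
class PipelineConfig:
    """Shipped defaults for every rule threshold in the pipeline.

    dvr_threshold
        DVR above which a voxel counts as aberrantly active (healthy-control
        white-matter mean + 1 s.d.).
    shell_step, shell_max
        Perilesional shell construction: concentric bands every
        ``shell_step`` mm out to ``shell_max`` mm.
    min_lesion_volume
        Lesions must exceed this physical volume (mm^3) to be phenotyped.
    t_star
        Start of the linear segment for Logan graphical analysis (minutes).
    brl_rim_min_width
        Minimum mean myeloid rim width (um) for a histological broad-rim
        lesion call.
    interedge_step
        Arc-length sampling interval (um) along the outer rim edge.
    """

    dvr_threshold: float = 1.3624
    shell_step: float = 2.0
    shell_max: float = 4.0
    min_lesion_volume: float = 50.0
    t_star: float = 20.0
    brl_rim_min_width: float = 1000.0
    interedge_step: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dvr_threshold",
            "shell_step",
            "shell_max",
            "min_lesion_volume",
            "t_star",
            "brl_rim_min_width",
            "interedge_step",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        ratio = self.shell_max / self.shell_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"shell_max ({self.shell_max}) must be an integer multiple of "
                f"shell_step ({self.shell_step})"
            )

    def hash(self) -> str:
        """Stable short hash of the configuration, logged by every stage."""
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)!r}" for f in dataclasses.fields(self)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a ``key: value`` config file, with keyword overrides on top."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain key: value pairs")
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI volume; header spacing/origin become the grid."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise RimpetError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D payload, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume3D(data, tuple(float(z) for z in zooms), origin)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a Volume3D as NIfTI-1 (masks uint8, labels uint16, else float32)."""
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        maxv = data.max() if data.size else 0
        dtype = np.uint8 if maxv <= 255 else np.uint16
        data = data.astype(dtype)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label_map(path: str | Path) -> LabelMap:
    vol = read_volume(path)
    return LabelMap(np.rint(vol.data).astype(np.uint16), vol.spacing, vol.origin)


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    write_volume(Volume3D(labels.labels.astype(np.uint16), labels.spacing, labels.origin), path)


def read_dynamic(path: str | Path, timing_path: str | Path) -> DynamicPET4D:
    """Read a 4D NIfTI plus a frame-timing CSV (columns mid_time_min, duration_min)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ShapeError(f"{path}: expected a 4D payload, got ndim={data.ndim}")
    timing = pd.read_csv(timing_path)
    for col in ("mid_time_min", "duration_min"):
        if col not in timing.columns:
            raise RimpetError(f"{timing_path}: missing column {col!r}")
    zooms = img.header.get_zooms()[:3]
    return DynamicPET4D(
        data,
        timing["mid_time_min"].to_numpy(float),
        timing["duration_min"].to_numpy(float),
        tuple(float(z) for z in zooms),
        tuple(float(v) for v in img.affine[:3, 3]),
    )


def write_dynamic(dyn: DynamicPET4D, path: str | Path, timing_path: str | Path) -> None:
    img = nib.Nifti1Image(dyn.frames.astype(np.float32), _affine(dyn.spacing, dyn.origin))
    nib.save(img, str(path))
    pd.DataFrame(
        {"mid_time_min": dyn.frame_mid_times, "duration_min": dyn.frame_durations}
    ).to_csv(timing_path, index=False)


# ---------------------------------------------------------------------------
# Tabular I/O for phenotype reports

#: Stable column order of the per-lesion phenotype report.
REPORT_COLUMNS = [
    "lesion_id",
    "volume_mm3",
    "core_active_pct",
    "rim_inner_active_pct",
    "rim_inner_mean_dvr",
    "rim_outer_mean_dvr",
    "rim_inner_label",
    "rim_outer_label",
    "activity_class",
    "category",
]


def write_report(records: list, path: str | Path) -> None:
    """Write per-lesion phenotypes to CSV, one row per lesion.

    The ``category`` column is "rBRL" for broad-rim calls and "non-rBRL"
    otherwise, so reports remain greppable; the boolean is recovered on read.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "lesion_id": rec.lesion_id,
                "volume_mm3": rec.volume_mm3,
                "core_active_pct": rec.core_active_pct,
                "rim_inner_active_pct": rec.rim_inner_active_pct,
                "rim_inner_mean_dvr": rec.rim_inner_mean_dvr,
                "rim_outer_mean_dvr": rec.rim_outer_mean_dvr,
                "rim_inner_label": rec.rim_inner_label,
                "rim_outer_label": rec.rim_outer_label,
                "activity_class": rec.activity_class,
                "category": "rBRL" if rec.is_rbrl else "non-rBRL",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)


def read_report(path: str | Path) -> list:
    """Parse a phenotype report back into LesionPhenotype records."""
    from .phenotype import LesionPhenotype  # local import to avoid a cycle

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            LesionPhenotype(
                lesion_id=int(row["lesion_id"]),
                volume_mm3=float(row["volume_mm3"]),
                core_active_pct=float(row["core_active_pct"]),
                rim_inner_active_pct=float(row["rim_inner_active_pct"]),
                rim_inner_mean_dvr=float(row["rim_inner_mean_dvr"]),
                rim_outer_mean_dvr=float(row["rim_outer_mean_dvr"]),
                rim_inner_label=str(row["rim_inner_label"]),
                rim_outer_label=str(row["rim_outer_label"]),
                activity_class=str(row["activity_class"]),
                is_rbrl=(str(row["category"]) == "rBRL"),
            )
        )
    return records


def array_checksum(arr: np.ndarray) -> str:
    """Short sha256 of an array's bytes, for audit logging."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]
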