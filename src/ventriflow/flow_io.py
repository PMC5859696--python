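"""Dataset input/output, shared physical constants and core domain types.

A dataset on disk is a directory holding three 4D NIfTI volumes with the
velocity components (``vx.nii.gz``, ``vy.nii.gz``, ``vz.nii.gz``, shaped
``(nx, ny, nz, n_frames)``), two binary masks on the same grid
(``ed_mask.nii.gz``, ``es_mask.nii.gz``) and a JSON sidecar
(``sidecar.json``) with the acquisition timing, VENC, valve planes and
ED/ES frame indices.  Everything downstream of :func:`read_dataset`
operates on the in-memory types defined here; no other module touches
files.

Unit conventions (stated once, used everywhere):

* velocities are stored internally in m/s; the sidecar records VENC in
  cm/s as acquisition consoles do;
* positions and voxel sizes are in mm; voxel indexing is 0-based and
  physical coordinates refer to voxel *centers*;
* times are in seconds; kinetic energies are computed in joules and
  reported in mJ and µJ/ml.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import nibabel as nib
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .energetics import ComponentResult

logger = logging.getLogger("ventriflow")

#: Density of blood in kg/m^3.  Configurable in every entry point and
#: recorded in the run log; 1060 kg/m^3 is the standard literature value.
RHO_BLOOD = 1060.0

#: Conversion factors kept next to the density so that the phantom's
#: ground truth and the pipeline share a single source of constants.
M3_PER_ML = 1e-6
MM_PER_M = 1000.0
CM_PER_M = 100.0

SIDECAR_NAME = "sidecar.json"
VOLUME_NAMES = ("vx.nii.gz", "vy.nii.gz", "vz.nii.gz")
MASK_NAMES = ("ed_mask.nii.gz", "es_mask.nii.gz")


class DatasetError(Exception):
    """Base class for typed dataset I/O failures."""


class MissingFileError(DatasetError):
    pass


class GridMismatchError(DatasetError):
    pass


class SidecarError(DatasetError):
    pass


class ConfigurationError(Exception):
    """Invalid analysis or phantom configuration."""


def voxel_volume_ml(voxel_size_mm: float) -> float:
    """Volume of one isotropic voxel in ml (1 ml = 1000 mm^3)."""
    return float(voxel_size_mm) ** 3 / 1000.0


@dataclass
class Plane:
    """An oriented plane given by a point and unit normal, in mm.

    Valve planes are stored with the normal pointing into the LV blood
    pool, so the signed distance of inflowing blood goes from negative
    (atrial side) to positive (ventricular side) as it crosses.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        norm = float(np.linalg.norm(normal))
        if not np.isfinite(norm) or norm == 0.0:
            raise ConfigurationError("plane normal must be a non-zero vector")
        self.normal = normal / norm

    def signed_distance(self, positions: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of ``positions`` (..., 3) from the plane."""
        pos = np.asarray(positions, dtype=float)
        return (pos - self.point) @ self.normal

    def to_dict(self) -> dict:
        return {"point_mm": self.point.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Plane":
        return cls(np.asarray(d["point_mm"]), np.asarray(d["normal"]))


@dataclass
class VelocityField:
    """Time-resolved three-directional velocity data on a regular grid.

    Attributes
    ----------
    values
        Array of shape ``(n_frames, nx, ny, nz, 3)`` in m/s.
    voxel_size
        Isotropic voxel edge length in mm.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    frame_times
        Strictly increasing frame times in seconds.
    venc
        Velocity-encoding limit in m/s.
    cycle_duration
        Length of the reconstructed cardiac cycle in seconds.
    periodic
        Whether the time axis wraps (retrospectively gated cine); the
        last frame is followed by the first one ``cycle_duration`` after
        the start of the cycle.
    """

    values: np.ndarray
    voxel_size: float
    frame_times: np.ndarray
    venc: float
    cycle_duration: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ConfigurationError(
                f"velocity values must have shape (T, nx, ny, nz, 3), got {self.values.shape}"
            )
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.values.shape[0]:
            raise ConfigurationError("frame_times length must match the number of frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ConfigurationError("frame_times must be strictly increasing")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        if self.cycle_duration <= self.frame_times[-1] - self.frame_times[0]:
            raise ConfigurationError("cycle_duration must exceed the spanned frame times")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:4]

    @property
    def box_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def box_max(self) -> np.ndarray:
        return self.origin + (np.array(self.grid_shape) - 1) * self.voxel_size

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.voxel_size)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical centers (mm) of all voxels, or of ``mask`` voxels."""
        if mask is None:
            idx = np.indices(self.grid_shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.origin + idx * self.voxel_size

    def nearest_voxel(self, positions: np.ndarray) -> np.ndarray:
        """Nearest voxel index of physical positions; may lie out of bounds."""
        pos = np.asarray(positions, dtype=float)
        return np.rint((pos - self.origin) / self.voxel_size).astype(np.int64)

    def in_box(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        return np.all((pos >= self.box_min) & (pos <= self.box_max), axis=-1)

    def copy_with(self, values: np.ndarray) -> "VelocityField":
        return dataclasses.replace(self, values=np.array(values, dtype=float))


@dataclass
class LvSegmentation:
    """End-diastolic/end-systolic LV masks plus valve-plane definitions."""

    ed_mask: np.ndarray
    es_mask: np.ndarray
    mitral_plane: Plane
    aortic_plane: Plane

    def __post_init__(self) -> None:
        self.ed_mask = np.asarray(self.ed_mask).astype(bool)
        self.es_mask = np.asarray(self.es_mask).astype(bool)
        if self.ed_mask.shape != self.es_mask.shape:
            raise GridMismatchError(
                f"ED mask grid {self.ed_mask.shape} != ES mask grid {self.es_mask.shape}"
            )
        if not self.ed_mask.any():
            raise ConfigurationError("ED mask is empty")
        if not self.es_mask.any():
            raise ConfigurationError("ES mask is empty")

    def edv_ml(self, voxel_size_mm: float) -> float:
        return int(self.ed_mask.sum()) * voxel_volume_ml(voxel_size_mm)

    def esv_ml(self, voxel_size_mm: float) -> float:
        return int(self.es_mask.sum()) * voxel_volume_ml(voxel_size_mm)


@dataclass
class CardiacTiming:
    """Frame indices separating the reconstructed cycle into phases."""

    ed_frame: int
    es_frame: int
    cycle_duration: float
    mid_diastasis_frame: int | None = None

    def __post_init__(self) -> None:
        if self.ed_frame == self.es_frame:
            raise ConfigurationError("ed_frame and es_frame must differ")

    def n_systole(self, n_frames: int) -> int:
        """Number of frame intervals from ED forward to ES."""
        return (self.es_frame - self.ed_frame) % n_frames

    def n_diastole(self, n_frames: int) -> int:
        """Number of frame intervals from ES forward to ED."""
        return n_frames - self.n_systole(n_frames)

    def diastolic_frames(self, n_frames: int) -> np.ndarray:
        """Frames from ES through ED (inclusive), in cycle order."""
        return (self.es_frame + np.arange(self.n_diastole(n_frames) + 1)) % n_frames


@dataclass
class AcquisitionMeta:
    """Phase-contrast sequence parameters that set the temporal resolution."""

    tr: float  # ms
    n_velocity_encodings: int = 4
    k_segmentation_factor: int = 1

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.n_velocity_encodings <= 0 or self.k_segmentation_factor <= 0:
            raise ConfigurationError("acquisition parameters must be positive")


def temporal_resolution(meta: AcquisitionMeta) -> float:
    """Effective temporal resolution in ms.

    With interleaved three-directional encoding (three flow-encoded plus
    one reference acquisition) and k-space segmentation, one cine frame
    takes ``TR x encodings x segmentation factor``.
    """
    return meta.tr * meta.n_velocity_encodings * meta.k_segmentation_factor


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------

def _affine(voxel_size: float, origin: np.ndarray) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = origin
    return aff


def write_dataset(
    path: str | Path,
    velocity: VelocityField,
    seg: LvSegmentation,
    timing: CardiacTiming,
    extra_sidecar: Mapping | None = None,
) -> Path:
    """Write a dataset directory in the on-disk layout ``read_dataset`` expects."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = _affine(velocity.voxel_size, velocity.origin)
    for axis, name in enumerate(VOLUME_NAMES):
        # (T, nx, ny, nz) -> (nx, ny, nz, T) as NIfTI wants space first
        comp = np.moveaxis(velocity.values[..., axis], 0, -1)
        nib.save(nib.Nifti1Image(comp.astype(np.float64), aff), path / name)
    for mask, name in zip((seg.ed_mask, seg.es_mask), MASK_NAMES):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), path / name)
    sidecar = {
        "voxel_size_mm": velocity.voxel_size,
        "origin_mm": velocity.origin.tolist(),
        "frame_times_s": velocity.frame_times.tolist(),
        "cycle_duration_s": velocity.cycle_duration,
        "venc_cm_s": velocity.venc * CM_PER_M,
        "periodic": velocity.periodic,
        "ed_frame": timing.ed_frame,
        "es_frame": timing.es_frame,
        "mid_diastasis_frame": timing.mid_diastasis_frame,
        "mitral_plane": seg.mitral_plane.to_dict(),
        "aortic_plane": seg.aortic_plane.to_dict(),
    }
    if extra_sidecar:
        sidecar.update(dict(extra_sidecar))
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_dataset(path: str | Path) -> tuple[VelocityField, LvSegmentation, CardiacTiming]:
    """Read a dataset directory and normalize units to m/s, mm, s."""
    path = Path(path)
    for name in (*VOLUME_NAMES, *MASK_NAMES, SIDECAR_NAME):
        if not (path / name).exists():
            raise MissingFileError(f"dataset file missing: {path / name}")
    try:
        sidecar = json.loads((path / SIDECAR_NAME).read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - malformed input
        raise SidecarError(f"cannot parse {path / SIDECAR_NAME}: {exc}") from exc
    for key in ("voxel_size_mm", "frame_times_s", "venc_cm_s", "cycle_duration_s",
                "ed_frame", "es_frame"):
        if key not in sidecar:
            raise SidecarError(f"sidecar field missing: {key}")

    comps = [np.asarray(nib.load(path / name).dataobj, dtype=float) for name in VOLUME_NAMES]
    shapes = {c.shape for c in comps}
    if len(shapes) != 1:
        raise GridMismatchError(f"velocity component grids differ: {sorted(shapes)}")
    values = np.moveaxis(np.stack(comps, axis=-1), 2 + 1, 0)  # (T, nx, ny, nz, 3)

    frame_times = np.asarray(sidecar["frame_times_s"], dtype=float)
    if frame_times.ndim != 1 or np.any(np.diff(frame_times) <= 0):
        raise SidecarError("sidecar frame_times_s must be strictly increasing")
    if len(frame_times) != values.shape[0]:
        raise SidecarError(
            f"sidecar lists {len(frame_times)} frame times but volumes hold "
            f"{values.shape[0]} frames"
        )

    velocity = VelocityField(
        values=values,
        voxel_size=float(sidecar["voxel_size_mm"]),
        origin=np.asarray(sidecar.get("origin_mm", [0.0, 0.0, 0.0])),
        frame_times=frame_times,
        venc=float(sidecar["venc_cm_s"]) / CM_PER_M,
        cycle_duration=float(sidecar["cycle_duration_s"]),
        periodic=bool(sidecar.get("periodic", True)),
    )

    masks = [np.asarray(nib.load(path / name).dataobj) > 0 for name in MASK_NAMES]
    for mask, name in zip(masks, MASK_NAMES):
        if mask.shape != velocity.grid_shape:
            raise GridMismatchError(
                f"{name} grid {mask.shape} does not match velocity grid {velocity.grid_shape}"
            )
    seg = LvSegmentation(
        ed_mask=masks[0],
        es_mask=masks[1],
        mitral_plane=Plane.from_dict(sidecar["mitral_plane"]),
        aortic_plane=Plane.from_dict(sidecar["aortic_plane"]),
    )
    timing = CardiacTiming(
        ed_frame=int(sidecar["ed_frame"]),
        es_frame=int(sidecar["es_frame"]),
        cycle_duration=float(sidecar["cycle_duration_s"]),
        mid_diastasis_frame=(None if sidecar.get("mid_diastasis_frame") is None
                             else int(sidecar["mid_diastasis_frame"])),
    )
    logger.info(
        "read dataset %s: grid %s, %d frames, VENC %.1f cm/s, EDV %.1f ml",
        path, velocity.grid_shape, velocity.n_frames, velocity.venc * CM_PER_M,
        seg.edv_ml(velocity.voxel_size),
    )
    return velocity, seg, timing


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def config_hash(config: Mapping) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    results: Mapping[str, "ComponentResult"],
    path: str | Path,
    qc: Mapping | None = None,
    run_config: Mapping | None = None,
) -> Path:
    """Write per-component summary and KE-curve CSVs plus a run-log JSON.

    The CSVs are written with ``repr`` float formatting so that re-running
    the same configuration produces byte-identical files.
    """
    from . import __version__

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    lines = ["component,volume_ml,ke_at_ed_mJ,ke_per_ml_at_ed_uJ_per_ml,n_pathlines,empty"]
    for name, res in results.items():
        lines.append(
            f"{name},{_fmt(res.volume_ml)},{_fmt(res.ke_at_ed_mj)},"
            f"{_fmt(res.ke_per_ml_at_ed_uj)},{res.n_pathlines},{int(res.empty)}"
        )
    (path / "components.csv").write_text("\n".join(lines) + "\n")

    lines = ["component,frame,time_s,ke_mJ"]
    for name, res in results.items():
        for k, (t, ke) in enumerate(zip(res.frame_times, res.ke_curve_mj)):
            lines.append(f"{name},{k},{_fmt(t)},{_fmt(ke)}")
    (path / "ke_curves.csv").write_text("\n".join(lines) + "\n")

    log: dict = {"software": f"ventriflow {__version__}"}
    if run_config is not None:
        log["config"] = dict(run_config)
        log["config_hash"] = config_hash(run_config)
    if qc is not None:
        log["qc"] = dict(qc)
    (path / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return path


def read_subject_table(path: str | Path) -> "pd.DataFrame":  # noqa: F821
    """Read a tidy per-subject CSV for the statistics stage."""
    import pandas as pd

    table = pd.read_csv(path)
    if "group" not in table.columns:
        raise ConfigurationError("subject table needs a 'group' column")
    return table
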