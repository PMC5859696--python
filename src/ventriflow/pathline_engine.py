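"""Lagrangian pathline emission and integration.

One pathline is emitted from the center of every end-diastolic mask
voxel and integrated forwards through systole to the next end-systole
and backwards through diastole to the previous end-systole, so each
trajectory covers exactly one cardiac cycle.  The velocity field is
interpolated trilinearly in space and linearly in time, with the time
axis wrapping periodically across the cine reconstruction boundary
(retrospective gating yields one averaged periodic cycle; the
"previous" cycle is the same data).

Integration is fixed-step classical 4th-order Runge-Kutta.  The step is
a fixed fraction of the frame interval (default 1/4) and always
subdivides each inter-frame interval exactly, so trajectory samples fall
on the reconstructed frame times.  Pathlines that leave the imaged
volume are frozen at their last inside position and flagged, never
dropped: every trajectory keeps representing its voxel of blood, which
is what makes the component volumes sum exactly to the segmented EDV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .flow_io import (
    CardiacTiming,
    ConfigurationError,
    LvSegmentation,
    MM_PER_M,
    VelocityField,
)

logger = logging.getLogger("ventriflow")

FLAG_OK = 0
FLAG_LEFT_FOV = 1
FLAG_UNRELIABLE = 2


# ---------------------------------------------------------------------------
# velocity interpolation
# ---------------------------------------------------------------------------

def _wrap_time(field: VelocityField, t: float) -> float:
    t0 = field.frame_times[0]
    if field.periodic:
        return (t - t0) % field.cycle_duration + t0
    return float(np.clip(t, t0, field.frame_times[-1]))


def _time_bracket(field: VelocityField, t: float) -> tuple[int, int, float]:
    """Frame pair (k0, k1) and weight w so that v(t) = (1-w) v_k0 + w v_k1."""
    tau = _wrap_time(field, t)
    times = field.frame_times
    k0 = int(np.searchsorted(times, tau, side="right") - 1)
    k0 = min(max(k0, 0), field.n_frames - 1)
    if k0 == field.n_frames - 1:
        if not field.periodic:
            return k0, k0, 0.0
        # wrap interval: last frame -> first frame of the next cycle
        dt = field.cycle_duration - (times[-1] - times[0])
        w = (tau - times[-1]) / dt
        return k0, 0, float(w)
    dt = times[k0 + 1] - times[k0]
    return k0, k0 + 1, float((tau - times[k0]) / dt)


def _trilinear(frame_values: np.ndarray, grid_idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of (nx, ny, nz, 3) at continuous indices (N, 3)."""
    shape = np.array(frame_values.shape[:3])
    g = np.clip(grid_idx, 0.0, shape - 1)
    i0 = np.clip(np.floor(g).astype(np.int64), 0, np.maximum(shape - 2, 0))
    f = g - i0
    i1 = np.minimum(i0 + 1, shape - 1)
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]
    fx, fy, fz = f[:, 0:1], f[:, 1:2], f[:, 2:3]
    c000 = frame_values[x0, y0, z0]
    c100 = frame_values[x1, y0, z0]
    c010 = frame_values[x0, y1, z0]
    c110 = frame_values[x1, y1, z0]
    c001 = frame_values[x0, y0, z1]
    c101 = frame_values[x1, y0, z1]
    c011 = frame_values[x0, y1, z1]
    c111 = frame_values[x1, y1, z1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def interpolate_velocity(
    field: VelocityField,
    positions: np.ndarray,
    time: float,
) -> np.ndarray:
    """Velocity (m/s) at physical positions (mm) and a single time (s).

    Trilinear in space, linear in time, periodic across the cycle
    boundary.  Spatial queries are clamped to the grid bounding box for
    evaluation; callers decide what leaving the box means (see
    :func:`trace`).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    grid_idx = (pos - field.origin) / field.voxel_size
    k0, k1, w = _time_bracket(field, float(time))
    v = _trilinear(field.values[k0], grid_idx)
    if w != 0.0:
        v = v * (1.0 - w) + _trilinear(field.values[k1], grid_idx) * w
    if np.asarray(positions).ndim == 1:
        return v[0]
    return v


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _rk4_span(
    field: VelocityField,
    pos: np.ndarray,
    t0: float,
    t1: float,
    n_steps: int,
    frozen: np.ndarray,
    unreliable: np.ndarray,
) -> np.ndarray:
    """Advance positions (N, 3) from t0 to t1 with n_steps RK4 steps.

    ``frozen`` and ``unreliable`` are boolean state vectors updated in
    place; frozen pathlines stop moving but keep their bookkeeping.
    Velocities (m/s) are converted to mm/s to match the mm positions.
    """
    h = (t1 - t0) / n_steps
    pos = pos.copy()
    for i in range(n_steps):
        t = t0 + i * h
        k1 = interpolate_velocity(field, pos, t)
        k2 = interpolate_velocity(field, pos + 0.5 * h * MM_PER_M * k1, t + 0.5 * h)
        k3 = interpolate_velocity(field, pos + 0.5 * h * MM_PER_M * k2, t + 0.5 * h)
        k4 = interpolate_velocity(field, pos + h * MM_PER_M * k3, t + h)
        incr = (h * MM_PER_M / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        bad = ~np.isfinite(incr).all(axis=1)
        if bad.any():
            unreliable |= bad
            incr[bad] = 0.0
        new = pos + incr
        inside = field.in_box(new)
        newly_out = ~inside & ~frozen
        frozen |= newly_out
        move = ~frozen
        pos[move] = new[move]
    return pos


@dataclass
class Trajectory:
    """A single traced pathline sampled at frame times (plus endpoints)."""

    times: np.ndarray  # (K,)
    positions: np.ndarray  # (K, 3) mm
    left_fov: bool
    unreliable: bool

    @property
    def endpoint(self) -> np.ndarray:
        return self.positions[-1]


def trace(
    field: VelocityField,
    seed: np.ndarray,
    t0: float,
    t1: float,
    step: float | None = None,
) -> Trajectory:
    """Trace one seed from t0 to t1 (backwards if t1 < t0).

    Positions are recorded at every reconstructed frame time crossed,
    plus the start and end times.  Integration is segmented at frame
    times, each segment subdivided into uniform RK4 steps no longer than
    ``step`` (default: a quarter of the frame interval).
    """
    if t1 == t0:
        raise ConfigurationError("trace needs a non-empty time span")
    span = abs(t1 - t0)
    if span > field.cycle_duration * (1 + 1e-9):
        raise ConfigurationError("trace span exceeds one cardiac cycle")
    dt_frame = float(np.min(np.diff(field.frame_times)))
    if step is None:
        step = dt_frame / 4.0
    if step <= 0:
        raise ConfigurationError("step must be positive")

    # frame times (unwrapped onto the [t0, t1] axis) strictly inside the span
    lo, hi = (t0, t1) if t1 > t0 else (t1, t0)
    times = field.frame_times
    period = field.cycle_duration
    n0 = int(np.floor((lo - times[0]) / period)) - 1
    n1 = int(np.ceil((hi - times[0]) / period)) + 1
    crossings = np.concatenate([times + n * period for n in range(n0, n1 + 1)])
    crossings = crossings[(crossings > lo + 1e-12) & (crossings < hi - 1e-12)]
    crossings = np.sort(crossings)
    if t1 < t0:
        crossings = crossings[::-1]
    knots = np.concatenate([[t0], crossings, [t1]])

    pos = np.atleast_2d(np.asarray(seed, dtype=float)).copy()
    frozen = np.zeros(len(pos), dtype=bool)
    unreliable = np.zeros(len(pos), dtype=bool)
    recorded = [pos[0].copy()]
    for a, b in zip(knots[:-1], knots[1:]):
        n_steps = max(1, int(np.ceil(abs(b - a) / step - 1e-9)))
        pos = _rk4_span(field, pos, float(a), float(b), n_steps, frozen, unreliable)
        recorded.append(pos[0].copy())
    return Trajectory(
        times=knots,
        positions=np.array(recorded),
        left_fov=bool(frozen[0]),
        unreliable=bool(unreliable[0]),
    )


# ---------------------------------------------------------------------------
# full emission
# ---------------------------------------------------------------------------

@dataclass
class PathlineSet:
    """All pathlines of one dataset, sampled at reconstructed frame times.

    Sample index ``j`` runs 0..n_frames: j=0 is the previous end-systole,
    j=n_diastole is end-diastole (the seeds), j=n_frames is the next
    end-systole.  ``sample_times`` are unwrapped times on a single-cycle
    axis (they may be negative before the cine start); the field's
    periodicity maps them back into the reconstructed cycle.
    """

    seeds: np.ndarray          # (N, 3) mm
    positions: np.ndarray      # (N, n_frames + 1, 3) mm
    speeds: np.ndarray         # (N, n_frames + 1) m/s, field speed at the samples
    sample_times: np.ndarray   # (n_frames + 1,) s
    frame_times: np.ndarray    # (n_frames,) s, cine frame times
    flags: np.ndarray          # (N,) bitmask of FLAG_*
    voxel_volume_ml: float
    voxel_size: float          # mm
    grid_origin: np.ndarray    # (3,) mm, center of voxel (0, 0, 0)
    ed_frame: int
    es_frame: int
    n_frames: int
    n_diastole: int

    @property
    def n_pathlines(self) -> int:
        return len(self.seeds)

    @property
    def represented_edv_ml(self) -> float:
        return self.n_pathlines * self.voxel_volume_ml

    def sample_of_frame(self, frame: int) -> int:
        """Sample index whose time corresponds to the given cine frame.

        Each frame maps to exactly one sample in 0..n_frames-1; the next
        end-systole (sample n_frames) revisits frame ``es_frame``.
        """
        return (frame - self.es_frame) % self.n_frames

    @property
    def origins(self) -> np.ndarray:
        """Backward-trace endpoints (positions at the previous ES)."""
        return self.positions[:, 0]

    @property
    def destinations(self) -> np.ndarray:
        """Forward-trace endpoints (positions at the next ES)."""
        return self.positions[:, -1]

    def to_table(self) -> "np.ndarray":
        """Flat (pathline, sample, x, y, z, speed) table for visualization dumps."""
        n, m = self.positions.shape[:2]
        ids = np.repeat(np.arange(n), m)
        samples = np.tile(np.arange(m), n)
        flat_pos = self.positions.reshape(-1, 3)
        flat_speed = self.speeds.reshape(-1)
        return np.column_stack([ids, samples, flat_pos, flat_speed])


def emit_all(
    field: VelocityField,
    seg: LvSegmentation,
    timing: CardiacTiming,
    step_fraction: float = 0.25,
) -> PathlineSet:
    """Emit and trace one pathline per ED-mask voxel center.

    ``step_fraction`` sets the RK4 step as a fraction of the frame
    interval; it is rounded to an integer number of substeps per frame
    so that samples land exactly on frame times.
    """
    if not seg.ed_mask.any():
        raise ConfigurationError("ED mask is empty; nothing to seed")
    if seg.ed_mask.shape != field.grid_shape:
        raise ConfigurationError("segmentation grid does not match field grid")
    if not (0 < step_fraction <= 1):
        raise ConfigurationError("step_fraction must be in (0, 1]")
    frame_dts = np.diff(field.frame_times)
    if not np.allclose(frame_dts, frame_dts[0], rtol=1e-6):
        raise ConfigurationError("emit_all expects uniformly spaced frame times")
    n = field.n_frames
    dt = field.cycle_duration / n
    substeps = max(1, int(round(1.0 / step_fraction)))

    n_dia = timing.n_diastole(n)
    t_ed = field.frame_times[timing.ed_frame % n]
    sample_times = t_ed + (np.arange(n + 1) - n_dia) * dt

    seeds = field.voxel_centers(seg.ed_mask)
    n_seeds = len(seeds)
    positions = np.empty((n_seeds, n + 1, 3))
    positions[:, n_dia] = seeds
    frozen_b = np.zeros(n_seeds, dtype=bool)
    unreliable_b = np.zeros(n_seeds, dtype=bool)

    # backward through diastole: ED -> previous ES
    pos = seeds.copy()
    for j in range(n_dia, 0, -1):
        pos = _rk4_span(field, pos, sample_times[j], sample_times[j - 1],
                        substeps, frozen_b, unreliable_b)
        positions[:, j - 1] = pos

    # forward through systole: ED -> next ES
    frozen_f = np.zeros(n_seeds, dtype=bool)
    unreliable_f = np.zeros(n_seeds, dtype=bool)
    pos = seeds.copy()
    for j in range(n_dia, n):
        pos = _rk4_span(field, pos, sample_times[j], sample_times[j + 1],
                        substeps, frozen_f, unreliable_f)
        positions[:, j + 1] = pos

    flags = np.zeros(n_seeds, dtype=np.uint8)
    flags[frozen_b | frozen_f] |= FLAG_LEFT_FOV
    flags[unreliable_b | unreliable_f] |= FLAG_UNRELIABLE

    speeds = np.empty((n_seeds, n + 1))
    for j, t in enumerate(sample_times):
        v = interpolate_velocity(field, positions[:, j], float(t))
        speeds[:, j] = np.linalg.norm(v, axis=1)

    n_flagged = int((flags != 0).sum())
    if n_flagged:
        logger.info("emit_all: %d/%d pathlines flagged (left_fov or unreliable)",
                    n_flagged, n_seeds)
    return PathlineSet(
        seeds=seeds,
        positions=positions,
        speeds=speeds,
        sample_times=sample_times,
        frame_times=field.frame_times.copy(),
        flags=flags,
        voxel_volume_ml=field.voxel_volume_ml,
        voxel_size=field.voxel_size,
        grid_origin=field.origin.copy(),
        ed_frame=timing.ed_frame % n,
        es_frame=timing.es_frame % n,
        n_frames=n,
        n_diastole=n_dia,
    )
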