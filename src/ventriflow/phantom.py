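"""Synthetic 4D flow datasets with analytic ground truth.

The slab phantom is a straight-tube stand-in for the left ventricle: a
spatially uniform, purely axial velocity field ``u(t) z_hat`` over the
whole grid, an end-diastolic mask that is an axial slab of voxels, and
an end-systolic mask that is a sub-slab sharing the distal (aortic)
face.  Blood enters across the mitral plane at the proximal ES-slab
face during diastole and exits across the aortic plane during systole.

Because the field is uniform in space, every trajectory is a pure axial
translation whose displacement is an exact integral of ``u(t)``, and
the component classification, E/A subdivision, mid-diastasis frame and
kinetic-energy curves all have closed forms.  The ground truth in
:class:`PhantomTruth` is computed from those closed forms only — it
never calls the pathline engine or the classifier — which makes it an
independent oracle for the entire downstream pipeline.

The waveform is defined by its samples at the reconstructed frame
times: the phantom's "true" velocity is the piecewise-linear (in time)
interpolation of those samples, exactly the field the tracer sees, so
truth and pipeline can agree to floating-point precision rather than to
a discretization tolerance.

A rigid-body rotation phantom is provided as a separate oracle for the
integrator's accuracy, and :func:`corrupt_field` injects the artifacts
(polynomial background offsets, phase wraps, noise) that the
preprocessing stage must remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from .flow_io import (
    CM_PER_M,
    CardiacTiming,
    ConfigurationError,
    LvSegmentation,
    Plane,
    RHO_BLOOD,
    M3_PER_ML,
    VelocityField,
    voxel_volume_ml,
)
from .flow_components import ALL_COMPONENTS

logger = logging.getLogger("ventriflow")


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------

@dataclass
class WaveSegment:
    """One piece of the axial speed waveform.

    ``duration`` in seconds (must span a whole number of frames),
    ``peak`` in cm/s (non-negative; flow is unidirectional mitral ->
    apex -> aorta in the tube picture), ``shape`` either ``"hann"``
    (a sin^2 bump) or ``"trapezoid"`` (one-frame linear ramps and a flat
    top).
    """

    duration: float
    peak: float = 0.0
    shape: str = "hann"

    def samples(self, n_intervals: int) -> np.ndarray:
        """Segment samples at its n_intervals + 1 frame points, cm/s."""
        m = n_intervals
        if self.peak == 0.0:
            return np.zeros(m + 1)
        if self.shape == "hann":
            return self.peak * np.sin(np.pi * np.arange(m + 1) / m) ** 2
        if self.shape == "trapezoid":
            if m < 2:
                raise ConfigurationError("trapezoid segment needs >= 2 frame intervals")
            s = np.full(m + 1, self.peak)
            s[0] = s[-1] = 0.0
            return s
        raise ConfigurationError(f"unknown waveform shape {self.shape!r}")


@dataclass
class Waveform:
    """Piecewise axial speed: systolic ejection, E-wave, diastasis, A-wave.

    ``ed_speed`` (cm/s) is the residual blood speed at the end-diastolic
    frame itself — real ventricular blood keeps a small pre-systolic
    motion as the mitral valve closes, and the method's headline
    quantity (KE at ED) is identically zero without it.
    """

    systole: WaveSegment
    e_wave: WaveSegment
    diastasis: WaveSegment
    a_wave: WaveSegment
    ed_speed: float = 0.0

    @property
    def segments(self) -> tuple[WaveSegment, ...]:
        return (self.systole, self.e_wave, self.diastasis, self.a_wave)

    @property
    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(*[
            WaveSegment(seg.duration, seg.peak * factor, seg.shape)
            for seg in self.segments
        ], ed_speed=self.ed_speed * factor)

    def segment_frames(self, n_frames: int, cycle_duration: float) -> list[int]:
        """Whole-frame interval counts per segment; errors on misalignment."""
        dt = cycle_duration / n_frames
        counts = []
        for seg in self.segments:
            m = seg.duration / dt
            if abs(m - round(m)) > 1e-9 or round(m) < 0:
                raise ConfigurationError(
                    f"segment duration {seg.duration} s is not a whole number of "
                    f"frames (dt = {dt} s)"
                )
            counts.append(int(round(m)))
        if sum(counts) != n_frames:
            raise ConfigurationError("segment durations must sum to the cycle duration")
        return counts

    def frame_samples(self, n_frames: int, cycle_duration: float) -> np.ndarray:
        """Axial speed u at the n_frames frame times, in m/s.

        Frame 0 is end-diastole / onset of systole.  Every segment shape
        starts and ends at zero, so the periodic wrap (frame n -> 0) is
        continuous.
        """
        counts = self.segment_frames(n_frames, cycle_duration)
        u = np.zeros(n_frames + 1)
        start = 0
        for seg, m in zip(self.segments, counts):
            if m == 0:
                continue
            s = seg.samples(m)
            u[start:start + m + 1] += s  # boundary samples are zero; += is safe
            start += m
        u[0] += self.ed_speed
        if any(seg.peak < 0 for seg in self.segments) or self.ed_speed < 0:
            raise ConfigurationError("waveform amplitudes must be non-negative")
        return u[:n_frames] / CM_PER_M


def default_waveform() -> Waveform:
    """The phantom's study-condition waveform (40 frames, 1 s cycle).

    Displacement integrals: 35.84 mm forward over systole, 7.84 mm
    during the E-wave and 8.4 mm during the A-wave, with a clear
    zero-flow diastasis.  Together with the default slabs this makes
    Direct Flow, Retained Inflow and Delayed Ejection Flow all
    non-empty, splits Direct Flow into E and A subvolumes, and balances
    inflow and outflow volumes exactly (QC discrepancy 0%).
    """
    return Waveform(
        systole=WaveSegment(duration=0.350, peak=20.48, shape="hann"),
        e_wave=WaveSegment(duration=0.075, peak=15.68, shape="trapezoid"),
        diastasis=WaveSegment(duration=0.150, peak=0.0),
        a_wave=WaveSegment(duration=0.425, peak=2.1, shape="trapezoid"),
        ed_speed=8.0,
    )


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class Corruption:
    """Artifacts to inject with :func:`corrupt_field`.

    ``poly_coeffs`` has shape (3, n_monomials): per velocity component,
    coefficients (cm/s) of the degree-``poly_order`` 3D monomial basis
    on per-axis [-1, 1] scaled coordinates — the same basis the
    preprocessing fit uses, so in-basis offsets are recoverable exactly.
    """

    poly_coeffs: np.ndarray | None = None
    poly_order: int = 4
    wrap_injection: bool = False
    noise_sd: float = 0.0  # cm/s
    seed: int | None = None


@dataclass
class PhantomSpec:
    """Geometry, timing and waveform of a slab phantom.

    Defaults follow the target acquisition: 2.8 mm isotropic voxels,
    40 reconstructed frames per cycle, VENC 120 cm/s.  Slabs are axial
    (z) extents in mm; a voxel belongs to a slab when its center lies
    inside the extent.  The ES slab shares the ED slab's distal face,
    like a ventricle that empties from its base.
    """

    grid_shape: tuple[int, int, int] = (8, 8, 56)
    voxel_size: float = 2.8
    n_frames: int = 40
    cycle_duration: float = 1.0
    venc: float = 120.0  # cm/s
    waveform: Waveform = dataclass_field(default_factory=default_waveform)
    ed_slab: tuple[float, float] = (58.0, 111.0)
    es_slab: tuple[float, float] = (78.0, 111.0)
    mitral_plane: Plane | None = None
    aortic_plane: Plane | None = None
    corruption: Corruption | None = None

    # -- derived geometry -------------------------------------------------
    def slab_voxel_range(self, slab: tuple[float, float]) -> tuple[int, int]:
        """Inclusive voxel-index range along z whose centers fall in the slab."""
        h = self.voxel_size
        lo = int(np.ceil(slab[0] / h - 1e-9))
        hi = int(np.floor(slab[1] / h + 1e-9))
        return lo, hi

    def es_boundaries(self) -> tuple[float, float]:
        """Nearest-voxel membership boundaries (mm) of the ES slab along z."""
        k_lo, k_hi = self.slab_voxel_range(self.es_slab)
        h = self.voxel_size
        return (k_lo - 0.5) * h, (k_hi + 0.5) * h

    def default_planes(self) -> tuple[Plane, Plane]:
        cx = (self.grid_shape[0] - 1) * self.voxel_size / 2.0
        cy = (self.grid_shape[1] - 1) * self.voxel_size / 2.0
        b0, b1 = self.es_boundaries()
        mitral = Plane(point=np.array([cx, cy, b0]), normal=np.array([0.0, 0.0, 1.0]))
        aortic = Plane(point=np.array([cx, cy, b1]), normal=np.array([0.0, 0.0, -1.0]))
        return mitral, aortic

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.cycle_duration / self.n_frames

    def u_samples(self) -> np.ndarray:
        """Waveform samples u_k (m/s) at the frame times."""
        return self.waveform.frame_samples(self.n_frames, self.cycle_duration)

    def validate(self) -> None:
        if self.n_frames < 4:
            raise ConfigurationError("need at least 4 frames")
        if abs(self.waveform.total_duration - self.cycle_duration) > 1e-9:
            raise ConfigurationError("waveform segment durations must sum to the cycle")
        self.waveform.segment_frames(self.n_frames, self.cycle_duration)
        h = self.voxel_size
        nz = self.grid_shape[2]
        for name, slab in (("ed_slab", self.ed_slab), ("es_slab", self.es_slab)):
            lo, hi = self.slab_voxel_range(slab)
            if lo > hi:
                raise ConfigurationError(f"{name} contains no voxel centers")
            if lo < 0 or hi > nz - 1:
                raise ConfigurationError(f"{name} extends outside the grid")
        ed_lo, ed_hi = self.slab_voxel_range(self.ed_slab)
        es_lo, es_hi = self.slab_voxel_range(self.es_slab)
        if not (ed_lo <= es_lo and es_hi <= ed_hi):
            raise ConfigurationError("ES slab must lie within the ED slab")
        u = self.u_samples()
        wraps_on = self.corruption is not None and self.corruption.wrap_injection
        if np.max(np.abs(u)) > self.venc / CM_PER_M and not wraps_on:
            raise ConfigurationError(
                "waveform exceeds VENC; enable wrap injection to study aliasing"
            )
        # the displaced slab must stay inside the interpolation box
        d_fwd, d_bwd = self.displacements()
        z_max = (nz - 1) * h
        if ed_hi * h + d_fwd > z_max or ed_lo * h - d_bwd < 0.0:
            raise ConfigurationError(
                "slab displaced outside grid: enlarge the grid or shrink the waveform"
            )

    # -- closed-form kinematics -------------------------------------------
    def displacements(self) -> tuple[float, float]:
        """Exact forward (systolic) and backward (diastolic) displacement, mm.

        Trapezoidal integrals of the piecewise-linear frame-sampled
        waveform — the same function of time the tracer integrates, for
        which fourth-order Runge-Kutta quadrature is exact.
        """
        s = self.cumulative_displacement_mm()
        n_sys = self.waveform.segment_frames(self.n_frames, self.cycle_duration)[0]
        d_fwd = s[n_sys]
        d_bwd = s[-1] - s[n_sys]
        return float(d_fwd), float(d_bwd)

    def cumulative_displacement_mm(self) -> np.ndarray:
        """Cumulative displacement (mm) from frame 0 to each frame 0..n."""
        u0 = self.u_samples()
        u = np.append(u0, u0[0])  # frame n wraps periodically to frame 0
        dt = self.cycle_duration / self.n_frames
        incr = 0.5 * (u[:-1] + u[1:]) * dt * 1000.0
        return np.concatenate([[0.0], np.cumsum(incr)])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Closed-form reference values for one slab phantom.

    ``component_counts`` holds exact voxel counts for all eight
    components; volumes are counts times the voxel volume.  KE curves
    are in mJ, indexed by cine frame.  ``mid_diastasis_frame`` is None
    when the phantom has no inflow (e.g. a zero waveform).
    """

    component_counts: dict[str, int]
    component_volumes: dict[str, float]
    e_a_split: dict[str, float]
    ke_curves: dict[str, np.ndarray]
    mid_diastasis_frame: int | None
    edv_ml: float
    esv_ml: float

    @property
    def all_volumes(self) -> dict[str, float]:
        """Volumes (ml) of all eight components."""
        return {**self.component_volumes, **self.e_a_split}

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        volumes = self.all_volumes
        lines = ["component,voxels,volume_ml,ke_at_ed_mJ"]
        for name in ALL_COMPONENTS:
            ke_ed = self.ke_curves[name][0]  # ED is frame 0 in the phantom
            lines.append(
                f"{name},{self.component_counts[name]},"
                f"{volumes[name]!r},{ke_ed!r}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


def _axial_plane_z(plane: Plane) -> float:
    """z-intercept of an axial plane; errors if the plane is not axial."""
    if abs(abs(plane.normal[2]) - 1.0) > 1e-12:
        raise ConfigurationError("slab-phantom ground truth requires axial valve planes")
    return float(plane.point[2])


def _truth_from_seed_z(
    spec: PhantomSpec,
    z: np.ndarray,
    origin_in: np.ndarray,
    dest_in: np.ndarray,
    n_xy: int,
) -> PhantomTruth:
    """Shared truth assembly given per-seed axial coordinates and endpoint
    membership verdicts (the two independent classification paths differ
    only in how they produce ``origin_in``/``dest_in``)."""
    n = spec.n_frames
    counts_frames = spec.waveform.segment_frames(n, spec.cycle_duration)
    n_sys = counts_frames[0]
    n_dia = n - n_sys
    dt = spec.cycle_duration / n
    s_cum = spec.cumulative_displacement_mm()
    d_fwd, d_bwd = spec.displacements()

    primary = np.empty(len(z), dtype=np.int8)
    primary[~origin_in & ~dest_in] = 0  # direct flow
    primary[~origin_in & dest_in] = 1   # retained inflow
    primary[origin_in & ~dest_in] = 2   # delayed ejection flow
    primary[origin_in & dest_in] = 3    # residual volume

    mitral, _ = (
        (spec.mitral_plane, spec.aortic_plane)
        if spec.mitral_plane is not None
        else spec.default_planes()
    )
    z_mv = _axial_plane_z(mitral)

    inflow = primary <= 1
    mid_frame: int | None = None
    wave = np.zeros(len(z), dtype=np.int8)  # 0 none, 1 E, 2 A
    if inflow.any():
        # remaining diastolic displacement S_j from diastolic sample j to ED
        # (sample j = 0 at previous ES .. j = n_dia at ED)
        s_dia = s_cum[n_sys:]  # cumulative from frame 0; s_dia[j] at frame n_sys + j
        remaining = s_dia[-1] - s_dia  # (n_dia + 1,)
        d = (z[inflow, None] - remaining[None, :]) - z_mv  # (M, n_dia + 1)
        side = d >= 0.0
        flips = side[:, :-1] != side[:, 1:]
        counts = flips.sum(axis=0)
        j_mid = int(np.argmin(counts))
        mid_frame = (n_sys + j_mid) % n
        t_mid = (j_mid - n_dia) * dt  # times relative to ED at 0

        entering = (d[:, :-1] < 0.0) & (d[:, 1:] >= 0.0)
        has_crossing = entering.any(axis=1)
        first = np.argmax(entering, axis=1)
        rows = np.arange(d.shape[0])
        d0, d1 = d[rows, first], d[rows, first + 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(d1 != d0, -d0 / (d1 - d0), 0.0)
        times_rel = (np.arange(n_dia + 1) - n_dia) * dt
        t_cross = times_rel[first] + frac * dt
        t_nearest = times_rel[np.argmin(np.abs(d), axis=1)]
        t_assign = np.where(has_crossing, t_cross, t_nearest)
        wave[inflow] = np.where(t_assign < t_mid, 1, 2)

    vol = voxel_volume_ml(spec.voxel_size)
    names4 = ("direct_flow", "retained_inflow", "delayed_ejection_flow", "residual_volume")
    counts_all: dict[str, int] = {}
    for code, name in enumerate(names4):
        counts_all[name] = int((primary == code).sum())
    for code, stem in ((0, "direct_flow"), (1, "retained_inflow")):
        counts_all[f"{stem}_e"] = int(((primary == code) & (wave == 1)).sum())
        counts_all[f"{stem}_a"] = int(((primary == code) & (wave == 2)).sum())
    volumes = {k: v * vol for k, v in counts_all.items()}

    u = spec.u_samples()
    ke_curves = {
        name: 0.5 * RHO_BLOOD * (counts_all[name] * vol * M3_PER_ML) * u**2 * 1e3
        for name in ALL_COMPONENTS
    }

    es_lo, es_hi = spec.slab_voxel_range(spec.es_slab)
    truth = PhantomTruth(
        component_counts={k: counts_all[k] for k in ALL_COMPONENTS},
        component_volumes={k: volumes[k] for k in names4},
        e_a_split={k: volumes[k] for k in
                   ("direct_flow_e", "direct_flow_a", "retained_inflow_e", "retained_inflow_a")},
        ke_curves=ke_curves,
        mid_diastasis_frame=mid_frame,
        edv_ml=len(z) * vol,
        esv_ml=(es_hi - es_lo + 1) * n_xy * vol,
    )
    # internal consistency of the partition
    assert sum(truth.component_counts[k] for k in names4) == len(z)
    assert (truth.component_counts["direct_flow_e"] + truth.component_counts["direct_flow_a"]
            == truth.component_counts["direct_flow"])
    assert (truth.component_counts["retained_inflow_e"]
            + truth.component_counts["retained_inflow_a"]
            == truth.component_counts["retained_inflow"])
    return truth


def _seed_axial_coords(spec: PhantomSpec) -> tuple[np.ndarray, int]:
    """Axial coordinates (mm) of every ED voxel center, with xy multiplicity."""
    ed_lo, ed_hi = spec.slab_voxel_range(spec.ed_slab)
    n_xy = spec.grid_shape[0] * spec.grid_shape[1]
    z_slices = np.arange(ed_lo, ed_hi + 1) * spec.voxel_size
    return np.repeat(z_slices, n_xy), n_xy


def closed_form_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground truth via interval arithmetic on the slab boundaries."""
    spec.validate()
    z, n_xy = _seed_axial_coords(spec)
    d_fwd, d_bwd = spec.displacements()
    b0, b1 = spec.es_boundaries()
    # nearest-voxel ES membership of an axial position p is p in [b0, b1)
    origin_in = (z - d_bwd >= b0) & (z - d_bwd < b1)
    dest_in = (z + d_fwd >= b0) & (z + d_fwd < b1)
    return _truth_from_seed_z(spec, z, origin_in, dest_in, n_xy)


def brute_force_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground truth via per-voxel endpoint checks against the ES mask array.

    Same arithmetic as the closed form but through an independent code
    path: endpoints are mapped to their nearest voxel index and looked
    up in the actual ES mask volume, mirroring the pipeline's membership
    rule without using any pipeline code.
    """
    spec.validate()
    h = spec.voxel_size
    es_lo, es_hi = spec.slab_voxel_range(spec.es_slab)
    nz = spec.grid_shape[2]
    es_column = np.zeros(nz, dtype=bool)
    es_column[es_lo:es_hi + 1] = True
    z, n_xy = _seed_axial_coords(spec)
    d_fwd, d_bwd = spec.displacements()

    def member(pos_z: np.ndarray) -> np.ndarray:
        idx = np.rint(pos_z / h).astype(np.int64)
        ok = (idx >= 0) & (idx < nz)
        out = np.zeros(len(pos_z), dtype=bool)
        out[ok] = es_column[idx[ok]]
        return out

    return _truth_from_seed_z(spec, z, member(z - d_bwd), member(z + d_fwd), n_xy)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_slab_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField, LvSegmentation, CardiacTiming, PhantomTruth]:
    """Build the slab phantom dataset and its closed-form truth."""
    spec.validate()
    n = spec.n_frames
    u = spec.u_samples()
    values = np.zeros((n, *spec.grid_shape, 3))
    values[..., 2] = u[:, None, None, None]

    def slab_mask(slab: tuple[float, float]) -> np.ndarray:
        lo, hi = spec.slab_voxel_range(slab)
        mask = np.zeros(spec.grid_shape, dtype=bool)
        mask[:, :, lo:hi + 1] = True
        return mask

    mitral, aortic = (
        (spec.mitral_plane, spec.aortic_plane)
        if spec.mitral_plane is not None and spec.aortic_plane is not None
        else spec.default_planes()
    )
    field = VelocityField(
        values=values,
        voxel_size=spec.voxel_size,
        frame_times=spec.frame_times(),
        venc=spec.venc / CM_PER_M,
        cycle_duration=spec.cycle_duration,
        periodic=True,
    )
    seg = LvSegmentation(
        ed_mask=slab_mask(spec.ed_slab),
        es_mask=slab_mask(spec.es_slab),
        mitral_plane=mitral,
        aortic_plane=aortic,
    )
    n_sys = spec.waveform.segment_frames(n, spec.cycle_duration)[0]
    timing = CardiacTiming(ed_frame=0, es_frame=n_sys, cycle_duration=spec.cycle_duration)
    truth = closed_form_truth(spec)
    return field, seg, timing, truth


def generate_rotation_phantom(omega: float, spec: PhantomSpec) -> VelocityField:
    """Steady rigid-body rotation v = omega x r about the grid's z axis.

    ``omega`` in rad/s; the axis passes through the grid center.  The
    field is linear in space, so trilinear interpolation reproduces it
    exactly and the only error in a traced circle is the integrator's —
    which is what this phantom is for.
    """
    if not np.isfinite(omega):
        raise ConfigurationError("omega must be finite")
    centers = [
        (n - 1) * spec.voxel_size / 2.0 for n in spec.grid_shape
    ]
    idx = np.indices(spec.grid_shape).astype(float)
    x = idx[0] * spec.voxel_size - centers[0]
    y = idx[1] * spec.voxel_size - centers[1]
    values = np.zeros((spec.n_frames, *spec.grid_shape, 3))
    # v (m/s) = omega x r with r in meters
    values[..., 0] = -omega * y[None] / 1000.0
    values[..., 1] = omega * x[None] / 1000.0
    return VelocityField(
        values=values,
        voxel_size=spec.voxel_size,
        frame_times=spec.frame_times(),
        venc=spec.venc / CM_PER_M,
        cycle_duration=spec.cycle_duration,
        periodic=True,
    )


def corrupt_field(field: VelocityField, spec: PhantomSpec) -> VelocityField:
    """Inject background offsets, phase wraps and noise (in that order).

    The polynomial offset is added to each component; wrap injection
    then aliases every sample beyond +/-VENC back into range by
    multiples of 2 VENC, exactly as a phase-contrast acquisition would;
    Gaussian noise comes last.  The input field is never modified.
    """
    if spec.corruption is None:
        raise ConfigurationError("spec has no corruption block")
    cor = spec.corruption
    values = field.values.copy()
    if cor.poly_coeffs is not None:
        from .preprocess import design_matrix, monomial_exponents

        coeffs = np.asarray(cor.poly_coeffs, dtype=float)
        n_mono = len(monomial_exponents(cor.poly_order))
        if coeffs.shape != (3, n_mono):
            raise ConfigurationError(
                f"poly_coeffs must have shape (3, {n_mono}) for order {cor.poly_order}"
            )
        design = design_matrix(field.grid_shape, cor.poly_order)
        offset = (design @ (coeffs.T / CM_PER_M)).reshape(*field.grid_shape, 3)
        values = values + offset[None]
    if cor.wrap_injection:
        two_venc = 2.0 * field.venc
        for _ in range(16):
            over = values > field.venc
            under = values < -field.venc
            if not (over.any() or under.any()):
                break
            values[over] -= two_venc
            values[under] += two_venc
    if cor.noise_sd > 0.0:
        rng = np.random.default_rng(cor.seed)
        values = values + rng.normal(0.0, cor.noise_sd / CM_PER_M, size=values.shape)
    return field.copy_with(values)


# ---------------------------------------------------------------------------
# randomized configurations (for property and acceptance testing)
# ---------------------------------------------------------------------------

def random_slab_spec(rng: np.random.Generator) -> PhantomSpec:
    """Draw a random, valid slab-phantom configuration.

    Covers both displacement regimes of the 1D tube (total displacement
    larger than the ES slab, which produces Direct Flow, and smaller,
    which produces Residual Volume) and randomizes slab sizes, waveform
    timing, shapes and amplitudes.  Displacements are sampled away from
    the half-voxel membership boundaries so that classification verdicts
    are numerically unambiguous.
    """
    h = 2.8
    n_frames = 40
    cycle = 1.0
    dt = cycle / n_frames

    k_ed_lo = int(rng.integers(12, 17))

    def offset_frac() -> float:
        # stay clear of the 0.5 h knife edge in either direction
        return float(rng.uniform(0.1, 0.4) if rng.random() < 0.5 else rng.uniform(0.6, 0.9))

    direct_flow_regime = rng.random() < 0.7
    for _ in range(1000):
        # the two 1D regimes: total displacement beyond the ES slab length
        # produces Direct Flow, below it Residual Volume
        if direct_flow_regime:
            n_ed = int(rng.integers(14, 20))
            d_fwd = (int(rng.integers(4, 10)) + offset_frac()) * h
            d_a = (int(rng.integers(2, 7)) + offset_frac()) * h
            d_e = (int(rng.integers(2, 7)) + offset_frac()) * h
        else:
            n_ed = int(rng.integers(16, 20))
            d_fwd = (int(rng.integers(2, 5)) + offset_frac()) * h
            d_a = (int(rng.integers(1, 4)) + offset_frac()) * h
            d_e = (int(rng.integers(1, 4)) + offset_frac()) * h
        d_bwd = d_a + d_e
        if d_bwd > (k_ed_lo - 1) * h:
            continue
        total = d_fwd + d_bwd
        if direct_flow_regime:
            n_es_max = min(n_ed - 6, int(np.floor(total / h - 0.2)))
            if n_es_max < 6:
                continue
            n_es = int(rng.integers(6, n_es_max + 1))
        else:
            n_es_min = max(6, int(np.ceil(total / h + 0.2)))
            if n_es_min > n_ed - 6:
                continue
            n_es = int(rng.integers(n_es_min, n_ed - 5))
        k_ed_hi = k_ed_lo + n_ed - 1
        break
    else:  # pragma: no cover - sampling ranges make this unreachable
        raise RuntimeError("could not sample a phantom configuration")

    m_sys = int(rng.integers(10, 16))
    m_e = int(rng.integers(3, 7))
    m_dia = int(rng.integers(4, 9))
    m_a = n_frames - m_sys - m_e - m_dia
    assert m_a >= 4

    def segment(d_mm: float, m: int) -> WaveSegment:
        dur = m * dt
        if rng.random() < 0.5:
            return WaveSegment(dur, peak=2.0 * d_mm / 1000.0 / dur * CM_PER_M, shape="hann")
        return WaveSegment(dur, peak=d_mm / 1000.0 / (dt * (m - 1)) * CM_PER_M,
                           shape="trapezoid")

    waveform = Waveform(
        systole=segment(d_fwd, m_sys),
        e_wave=segment(d_e, m_e),
        diastasis=WaveSegment(m_dia * dt, 0.0),
        a_wave=segment(d_a, m_a),
    )
    nz = k_ed_hi + int(np.ceil(d_fwd / h)) + 3
    nxy = int(rng.integers(4, 8))
    spec = PhantomSpec(
        grid_shape=(nxy, nxy, nz),
        voxel_size=h,
        n_frames=n_frames,
        cycle_duration=cycle,
        waveform=waveform,
        ed_slab=((k_ed_lo - 0.25) * h, (k_ed_hi + 0.25) * h),
        es_slab=((k_ed_hi - n_es + 1 - 0.25) * h, (k_ed_hi + 0.25) * h),
    )
    spec.validate()
    return spec
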