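"""Four-component classification of LV blood, E/A subdivision and QC.

The end-diastolic blood volume is partitioned by where each pathline was
at the previous end-systole (its origin, from the backward trace) and
where it is at the next end-systole (its destination, from the forward
trace), tested against the segmented end-systolic volume:

====================  ======================  =======================
origin in ESV?        destination in ESV?     component
====================  ======================  =======================
no                    no                      Direct Flow
no                    yes                     Retained Inflow
yes                   no                      Delayed Ejection Flow
yes                   yes                     Residual Volume
====================  ======================  =======================

Blood that entered during the analyzed diastole (Direct Flow and
Retained Inflow) is further split by diastolic filling phase: pathlines
whose first mitral-plane crossing falls before mid-diastasis belong to
the E-wave (early, passive filling), the rest to the A-wave (late,
atrial contraction).  Mid-diastasis itself is found from the data as
the diastolic frame interval in which the fewest inflow pathlines cross
the mitral valve plane.

A dataset-level quality control compares total inflow and outflow
volume; a discrepancy beyond 15% marks the dataset as unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .flow_io import CardiacTiming, ConfigurationError, LvSegmentation
from .pathline_engine import FLAG_LEFT_FOV, FLAG_UNRELIABLE, PathlineSet

logger = logging.getLogger("ventriflow")

DIRECT_FLOW = 0
RETAINED_INFLOW = 1
DELAYED_EJECTION_FLOW = 2
RESIDUAL_VOLUME = 3

WAVE_NONE = 0
WAVE_E = 1
WAVE_A = 2

COMPONENT_NAMES = {
    DIRECT_FLOW: "direct_flow",
    RETAINED_INFLOW: "retained_inflow",
    DELAYED_EJECTION_FLOW: "delayed_ejection_flow",
    RESIDUAL_VOLUME: "residual_volume",
}

#: Reporting order of the eight components (four primaries plus the
#: E/A subvolumes of the two inflow components).
ALL_COMPONENTS = (
    "direct_flow",
    "direct_flow_e",
    "direct_flow_a",
    "retained_inflow",
    "retained_inflow_e",
    "retained_inflow_a",
    "delayed_ejection_flow",
    "residual_volume",
)

DISPLAY_NAMES = {
    "direct_flow": "Direct Flow",
    "direct_flow_e": "Direct Flow E",
    "direct_flow_a": "Direct Flow A",
    "retained_inflow": "Retained Inflow",
    "retained_inflow_e": "Retained Inflow E",
    "retained_inflow_a": "Retained Inflow A",
    "delayed_ejection_flow": "Delayed Ejection Flow",
    "residual_volume": "Residual Volume",
}


class TimingError(ConfigurationError):
    """Dataset unusable for phase analysis (e.g. no inflow pathlines)."""


@dataclass
class ComponentLabels:
    """Per-pathline component membership.

    ``primary`` holds the four-way component code, ``wave`` the E/A
    sub-label (only meaningful for inflow components), ``crossing_time``
    the interpolated first mitral crossing time in diastole (NaN when no
    crossing was detected) and ``no_crossing`` marks inflow pathlines
    that were assigned by nearest approach instead of a crossing.
    """

    primary: np.ndarray        # (N,) int8
    wave: np.ndarray           # (N,) int8
    crossing_time: np.ndarray  # (N,) float, s
    no_crossing: np.ndarray    # (N,) bool

    def member_mask(self, component: str) -> np.ndarray:
        base = {
            "direct_flow": self.primary == DIRECT_FLOW,
            "retained_inflow": self.primary == RETAINED_INFLOW,
            "delayed_ejection_flow": self.primary == DELAYED_EJECTION_FLOW,
            "residual_volume": self.primary == RESIDUAL_VOLUME,
        }
        if component in base:
            return base[component]
        stem, wave = component.rsplit("_", 1)
        code = {"e": WAVE_E, "a": WAVE_A}[wave]
        return base[stem] & (self.wave == code)

    def counts(self) -> dict[str, int]:
        return {name: int(self.member_mask(name).sum()) for name in ALL_COMPONENTS}

    def volumes_ml(self, voxel_volume_ml: float) -> dict[str, float]:
        return {name: cnt * voxel_volume_ml for name, cnt in self.counts().items()}


def _in_mask(positions: np.ndarray, mask: np.ndarray, paths: PathlineSet) -> np.ndarray:
    """Nearest-voxel membership of physical positions (N, 3) in a binary mask.

    Nearest-voxel lookup (rather than interpolating the binary mask)
    keeps membership reproducible and fraction-free; sub-voxel boundary
    sensitivity is covered by the phantom tolerance tests.
    """
    idx = np.rint((positions - paths.grid_origin) / paths.voxel_size).astype(np.int64)
    shape = np.array(mask.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    member = np.zeros(len(positions), dtype=bool)
    if inside.any():
        ii = idx[inside]
        member[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return member


def classify(paths: PathlineSet, seg: LvSegmentation) -> ComponentLabels:
    """Label every pathline by its endpoints against the ES mask.

    Flagged pathlines (left_fov, unreliable) are classified by their
    frozen endpoints like any other; they are counted separately in the
    QC report rather than dropped, so volume accounting stays exact.
    """
    origin_in = _in_mask(paths.origins, seg.es_mask, paths)
    dest_in = _in_mask(paths.destinations, seg.es_mask, paths)
    primary = np.empty(paths.n_pathlines, dtype=np.int8)
    primary[~origin_in & ~dest_in] = DIRECT_FLOW
    primary[~origin_in & dest_in] = RETAINED_INFLOW
    primary[origin_in & ~dest_in] = DELAYED_EJECTION_FLOW
    primary[origin_in & dest_in] = RESIDUAL_VOLUME
    n = paths.n_pathlines
    return ComponentLabels(
        primary=primary,
        wave=np.full(n, WAVE_NONE, dtype=np.int8),
        crossing_time=np.full(n, np.nan),
        no_crossing=np.zeros(n, dtype=bool),
    )


def _inflow_mask(labels: ComponentLabels) -> np.ndarray:
    return (labels.primary == DIRECT_FLOW) | (labels.primary == RETAINED_INFLOW)


def _diastolic_distances(paths: PathlineSet, seg: LvSegmentation) -> np.ndarray:
    """Signed mitral-plane distance of every pathline at diastolic samples.

    Sample j = 0..n_diastole covers previous ES through ED; the plane
    normal points into the LV, so entering blood goes negative -> 0 ->
    positive.
    """
    n_dia = paths.n_diastole
    pos = paths.positions[:, : n_dia + 1]  # (N, n_dia + 1, 3)
    return seg.mitral_plane.signed_distance(pos)


def find_mid_diastasis(
    paths: PathlineSet,
    labels: ComponentLabels,
    seg: LvSegmentation,
    timing: CardiacTiming,
) -> int:
    """Data-driven mid-diastasis: the diastolic frame interval with the
    fewest mitral-plane crossings among inflow pathlines.

    Crossing counts use half-open frame intervals [t_k, t_k+1); ties are
    broken toward the earliest frame.  The result (a cine frame index)
    is stored on ``timing`` and returned.
    """
    n_dia = paths.n_diastole
    if n_dia < 3:
        raise TimingError("diastole spans fewer than 3 frames; cannot locate diastasis")
    inflow = _inflow_mask(labels)
    if not inflow.any():
        raise TimingError("no inflow pathlines; dataset unusable for the E/A split")
    d = _diastolic_distances(paths, seg)[inflow]  # (M, n_dia + 1)
    side = d >= 0.0
    crossings = side[:, :-1] != side[:, 1:]  # sign change within interval
    counts = crossings.sum(axis=0)  # (n_dia,)
    j_min = int(np.argmin(counts))  # argmin takes the earliest tie
    frame = int((paths.es_frame + j_min) % paths.n_frames)
    timing.mid_diastasis_frame = frame
    logger.info("mid-diastasis at frame %d (crossing counts %s)", frame, counts.tolist())
    return frame


def split_e_a(
    paths: PathlineSet,
    labels: ComponentLabels,
    seg: LvSegmentation,
    timing: CardiacTiming,
) -> ComponentLabels:
    """Assign E/A wave membership to the inflow components.

    The first mitral-plane crossing time during diastole is interpolated
    linearly between the bracketing samples.  Crossings strictly before
    the mid-diastasis frame time are E-wave; crossings at or after it
    are A-wave (the late-filling interval runs from mid-diastasis until
    ED).  Inflow pathlines without a detected crossing are assigned by
    their nearest-approach time to the plane and reported.
    """
    if timing.mid_diastasis_frame is None:
        raise TimingError("mid_diastasis_frame not set; run find_mid_diastasis first")
    inflow = _inflow_mask(labels)
    if not inflow.any():
        return labels
    n_dia = paths.n_diastole
    d = _diastolic_distances(paths, seg)  # (N, n_dia + 1)
    times = paths.sample_times[: n_dia + 1]
    j_mid = (timing.mid_diastasis_frame - paths.es_frame) % paths.n_frames
    if not 0 <= j_mid <= n_dia:
        raise TimingError("mid_diastasis_frame lies outside the diastolic interval")
    t_mid = times[j_mid]

    entering = (d[:, :-1] < 0.0) & (d[:, 1:] >= 0.0)  # (N, n_dia)
    has_crossing = entering.any(axis=1)
    first = np.argmax(entering, axis=1)  # first entering interval
    rows = np.arange(paths.n_pathlines)
    d0 = d[rows, first]
    d1 = d[rows, first + 1]
    denom = d1 - d0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom != 0.0, -d0 / denom, 0.0)
    t_cross = times[first] + frac * np.diff(times)[first]

    # nearest-approach fallback: earliest diastolic sample of minimal |d|
    t_nearest = times[np.argmin(np.abs(d), axis=1)]

    wave = labels.wave.copy()
    crossing_time = labels.crossing_time.copy()
    no_crossing = labels.no_crossing.copy()

    use_cross = inflow & has_crossing
    use_near = inflow & ~has_crossing
    t_assign = np.where(has_crossing, t_cross, t_nearest)
    wave[inflow] = np.where(t_assign[inflow] < t_mid, WAVE_E, WAVE_A)
    crossing_time[use_cross] = t_cross[use_cross]
    no_crossing[use_near] = True
    if use_near.any():
        logger.info("split_e_a: %d inflow pathlines had no mitral crossing; "
                    "assigned by nearest approach", int(use_near.sum()))
    return ComponentLabels(
        primary=labels.primary,
        wave=wave,
        crossing_time=crossing_time,
        no_crossing=no_crossing,
    )


@dataclass
class QcReport:
    """Inflow-outflow volume consistency check and pathline-flag summary."""

    inflow_ml: float
    outflow_ml: float
    discrepancy_pct: float
    threshold_pct: float
    passed: bool
    reason: str = ""
    left_fov_fraction: float = 0.0
    unreliable_fraction: float = 0.0
    no_crossing_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "inflow_ml": self.inflow_ml,
            "outflow_ml": self.outflow_ml,
            "discrepancy_pct": self.discrepancy_pct,
            "threshold_pct": self.threshold_pct,
            "passed": self.passed,
            "reason": self.reason,
            "left_fov_fraction": self.left_fov_fraction,
            "unreliable_fraction": self.unreliable_fraction,
            "no_crossing_fraction": self.no_crossing_fraction,
        }


def inflow_outflow_discrepancy(inflow_ml: float, outflow_ml: float) -> float:
    """Percent discrepancy |inflow - outflow| / mean(inflow, outflow) * 100.

    The symmetric mean denominator avoids biasing the check toward
    either direction of mismatch.
    """
    mean = 0.5 * (inflow_ml + outflow_ml)
    if mean == 0.0:
        return float("nan")
    return abs(inflow_ml - outflow_ml) / mean * 100.0


def qc_inflow_outflow(
    labels: ComponentLabels,
    represented_volume_ml: float,
    threshold_pct: float = 15.0,
    paths: PathlineSet | None = None,
) -> QcReport:
    """Apply the inflow-outflow discrepancy rule.

    Inflow = Direct Flow + Retained Inflow; outflow = Direct Flow +
    Delayed Ejection Flow.  Datasets whose discrepancy exceeds the
    threshold (15% by default) fail and should be excluded from
    downstream comparisons.
    """
    vols = labels.volumes_ml(represented_volume_ml)
    inflow = vols["direct_flow"] + vols["retained_inflow"]
    outflow = vols["direct_flow"] + vols["delayed_ejection_flow"]
    disc = inflow_outflow_discrepancy(inflow, outflow)
    if np.isnan(disc):
        passed, reason = False, "inflow and outflow are both zero; discrepancy undefined"
    else:
        passed = disc <= threshold_pct
        reason = "" if passed else f"discrepancy {disc:.1f}% exceeds {threshold_pct:.1f}%"
    n = len(labels.primary)
    left_fov = unreliable = 0.0
    if paths is not None and n:
        left_fov = float((paths.flags & FLAG_LEFT_FOV != 0).mean())
        unreliable = float((paths.flags & FLAG_UNRELIABLE != 0).mean())
    no_cross = float(labels.no_crossing.mean()) if n else 0.0
    return QcReport(
        inflow_ml=inflow,
        outflow_ml=outflow,
        discrepancy_pct=disc,
        threshold_pct=threshold_pct,
        passed=passed,
        reason=reason,
        left_fov_fraction=left_fov,
        unreliable_fraction=unreliable,
        no_crossing_fraction=no_cross,
    )
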