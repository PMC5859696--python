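"""Component classification, mid-diastasis timing, E/A split and QC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ventriflow as vf
from ventriflow.flow_components import (
    DELAYED_EJECTION_FLOW,
    DIRECT_FLOW,
    RESIDUAL_VOLUME,
    RETAINED_INFLOW,
    TimingError,
    WAVE_A,
    WAVE_E,
)
from ventriflow.pathline_engine import PathlineSet


def _toy_paths(positions, n_diastole, es_frame=2, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    """Hand-built PathlineSet: positions has shape (N, n_frames + 1, 3)."""
    positions = np.asarray(positions, dtype=float)
    n, m, _ = positions.shape
    n_frames = m - 1
    return PathlineSet(
        seeds=positions[:, n_diastole].copy(),
        positions=positions,
        speeds=np.zeros((n, m)),
        sample_times=(np.arange(m) - n_diastole) * 0.1,
        frame_times=np.arange(n_frames) * 0.1,
        flags=np.zeros(n, dtype=np.uint8),
        voxel_volume_ml=voxel**3 / 1000.0,
        voxel_size=voxel,
        grid_origin=np.asarray(origin, dtype=float),
        ed_frame=(es_frame + n_diastole) % n_frames,
        es_frame=es_frame,
        n_frames=n_frames,
        n_diastole=n_diastole,
    )


def _simple_seg(es_lo=5, es_hi=9, shape=(3, 3, 12)):
    """ES mask = z slices es_lo..es_hi on a unit-voxel grid."""
    es = np.zeros(shape, dtype=bool)
    es[:, :, es_lo:es_hi + 1] = True
    ed = np.ones(shape, dtype=bool)
    return vf.LvSegmentation(
        ed_mask=ed, es_mask=es,
        mitral_plane=vf.Plane([1.0, 1.0, es_lo - 0.5], [0, 0, 1.0]),
        aortic_plane=vf.Plane([1.0, 1.0, es_hi + 0.5], [0, 0, -1.0]),
    )


@pytest.mark.parametrize(
    "origin_z, dest_z, expected",
    [
        (2.0, 12.0, DIRECT_FLOW),            # enters and leaves
        (2.0, 7.0, RETAINED_INFLOW),         # enters, stays
        (7.0, 12.0, DELAYED_EJECTION_FLOW),  # was inside, leaves
        (7.0, 6.0, RESIDUAL_VOLUME),         # inside at both end-systoles
    ],
)
def test_endpoint_classification_table(origin_z, dest_z, expected):
    pos = np.zeros((1, 5, 3))
    pos[..., :2] = 1.0
    pos[0, :, 2] = np.linspace(origin_z, dest_z, 5)
    paths = _toy_paths(pos, n_diastole=2)
    labels = vf.classify(paths, _simple_seg())
    assert labels.primary[0] == expected


def test_classification_matches_phantom_truth(default_analysis, default_phantom):
    truth = default_phantom[3]
    assert default_analysis.labels.counts() == truth.component_counts


def test_classification_translation_invariant(default_phantom):
    """Rigid translation of grid, masks and planes together changes nothing."""
    field, seg, timing, _ = default_phantom
    shift = np.array([13.0, -7.5, 21.1])
    field2 = dataclasses.replace(field, origin=field.origin + shift,
                                 values=field.values)
    seg2 = vf.LvSegmentation(
        ed_mask=seg.ed_mask, es_mask=seg.es_mask,
        mitral_plane=vf.Plane(seg.mitral_plane.point + shift, seg.mitral_plane.normal),
        aortic_plane=vf.Plane(seg.aortic_plane.point + shift, seg.aortic_plane.normal),
    )
    out1 = vf.analyze(field, seg, dataclasses.replace(timing))
    out2 = vf.analyze(field2, seg2, dataclasses.replace(timing))
    assert out1.labels.counts() == out2.labels.counts()
    np.testing.assert_array_equal(out1.labels.primary, out2.labels.primary)
    np.testing.assert_array_equal(out1.labels.wave, out2.labels.wave)


def _crossing_paths(counts, es_frame=2):
    """Pathlines whose mitral crossings realize the given per-interval counts.

    Pathline i assigned to interval j sits below the plane (z = 4) up to
    diastolic sample j and above it afterwards.
    """
    n_dia = len(counts)
    n_frames = n_dia + 2  # two systolic intervals
    rows = []
    for j, c in enumerate(counts):
        for _ in range(c):
            z = np.full(n_frames + 1, 3.0)
            z[j + 1:n_dia + 1] = 5.0
            z[n_dia + 1:] = 5.0
            rows.append(z)
    pos = np.zeros((len(rows), n_frames + 1, 3))
    pos[..., :2] = 1.0
    pos[..., 2] = np.array(rows)
    return _toy_paths(pos, n_diastole=n_dia, es_frame=es_frame)


def _all_inflow_labels(paths):
    n = paths.n_pathlines
    from ventriflow.flow_components import ComponentLabels

    return ComponentLabels(
        primary=np.full(n, RETAINED_INFLOW, dtype=np.int8),
        wave=np.zeros(n, dtype=np.int8),
        crossing_time=np.full(n, np.nan),
        no_crossing=np.zeros(n, dtype=bool),
    )


def _seg_for_crossing():
    seg = np.zeros((3, 3, 10), dtype=bool)
    seg[:, :, 5:] = True
    return vf.LvSegmentation(
        ed_mask=np.ones((3, 3, 10), dtype=bool), es_mask=seg,
        mitral_plane=vf.Plane([1.0, 1.0, 4.0], [0, 0, 1.0]),
        aortic_plane=vf.Plane([1.0, 1.0, 9.5], [0, 0, -1.0]),
    )


def test_mid_diastasis_argmin():
    paths = _crossing_paths([12, 3, 0, 2, 9])
    timing = vf.CardiacTiming(ed_frame=paths.ed_frame, es_frame=paths.es_frame,
                              cycle_duration=0.7)
    frame = vf.find_mid_diastasis(paths, _all_inflow_labels(paths),
                                  _seg_for_crossing(), timing)
    # third diastolic interval -> frame es + 2
    assert frame == paths.es_frame + 2
    assert timing.mid_diastasis_frame == frame


def test_mid_diastasis_tie_breaks_earliest():
    paths = _crossing_paths([5, 0, 0, 7])
    timing = vf.CardiacTiming(ed_frame=paths.ed_frame, es_frame=paths.es_frame,
                              cycle_duration=0.6)
    frame = vf.find_mid_diastasis(paths, _all_inflow_labels(paths),
                                  _seg_for_crossing(), timing)
    assert frame == paths.es_frame + 1


def test_mid_diastasis_requires_inflow(zero_phantom_spec):
    field, seg, timing, _ = vf.generate_slab_phantom(zero_phantom_spec)
    paths = vf.emit_all(field, seg, timing)
    labels = vf.classify(paths, seg)
    with pytest.raises(TimingError, match="no inflow"):
        vf.find_mid_diastasis(paths, labels, seg, timing)


def test_mid_diastasis_in_phantom_diastasis_segment(default_analysis, default_spec):
    """The located frame lies inside the waveform's zero-flow pause."""
    frame = default_analysis.timing.mid_diastasis_frame
    counts = default_spec.waveform.segment_frames(default_spec.n_frames,
                                                  default_spec.cycle_duration)
    dia_start = counts[0] + counts[1]
    dia_end = dia_start + counts[2]
    assert dia_start <= frame <= dia_end


def test_split_e_a_boundary_rules():
    """Crossing before mid-diastasis is E; at or after it is A."""
    n_dia = 5
    n_frames = n_dia + 2

    def make_path(d_values):
        # d_values: signed distances at diastolic samples 0..n_dia
        z = np.concatenate([4.0 + np.asarray(d_values),
                            np.full(n_frames - n_dia, 4.0 + d_values[-1])])
        pos = np.zeros((n_frames + 1, 3))
        pos[:, :2] = 1.0
        pos[:, 2] = z
        return pos

    # crossing at 40% of the first interval (well before mid), mid at sample 3
    early = make_path([-0.4, 0.6, 1.0, 1.0, 1.0, 1.0])
    # crossing exactly at the mid-diastasis sample time -> A
    at_mid = make_path([-1.0, -1.0, -1.0, 0.0, 1.0, 1.0])
    # crossing after mid -> A
    late = make_path([-1.0, -1.0, -1.0, -0.5, 0.5, 1.0])
    # never crosses; nearest approach at ED -> A
    never = make_path([-3.0, -2.5, -2.0, -1.8, -1.5, -1.0])
    pos = np.stack([early, at_mid, late, never])
    paths = _toy_paths(pos, n_diastole=n_dia)
    seg = _seg_for_crossing_wide()
    labels = vf.classify(paths, seg)
    timing = vf.CardiacTiming(ed_frame=paths.ed_frame, es_frame=paths.es_frame,
                              cycle_duration=0.8)
    timing.mid_diastasis_frame = (paths.es_frame + 3) % paths.n_frames
    labels = vf.split_e_a(paths, labels, seg, timing)
    assert labels.wave[0] == WAVE_E
    assert labels.wave[1] == WAVE_A
    assert labels.wave[2] == WAVE_A
    assert labels.wave[3] == WAVE_A
    assert labels.no_crossing[3] and not labels.no_crossing[:3].any()
    # interpolated crossing time of the first pathline: 40% into interval 0
    t0 = paths.sample_times[0]
    assert labels.crossing_time[0] == pytest.approx(t0 + 0.4 * 0.1)


def _seg_for_crossing_wide():
    shape = (3, 3, 12)
    es = np.zeros(shape, dtype=bool)
    es[:, :, 8:] = True  # endpoints around z=3..5 stay outside -> inflow
    return vf.LvSegmentation(
        ed_mask=np.ones(shape, dtype=bool), es_mask=es,
        mitral_plane=vf.Plane([1.0, 1.0, 4.0], [0, 0, 1.0]),
        aortic_plane=vf.Plane([1.0, 1.0, 11.5], [0, 0, -1.0]),
    )


def test_split_e_a_matches_phantom_truth(default_analysis, default_phantom):
    truth = default_phantom[3]
    vols = default_analysis.labels.volumes_ml(default_analysis.paths.voxel_volume_ml)
    for name, expected in truth.e_a_split.items():
        assert vols[name] == pytest.approx(expected, abs=1e-12)


def test_ea_subvolumes_partition_parents(default_analysis):
    c = default_analysis.labels.counts()
    assert c["direct_flow_e"] + c["direct_flow_a"] == c["direct_flow"]
    assert c["retained_inflow_e"] + c["retained_inflow_a"] == c["retained_inflow"]


@pytest.mark.parametrize(
    "inflow, outflow, expected, passes",
    [
        (74.0, 70.0, 5.555555555555555, True),   # the study-wide mean volumes
        (80.0, 80.0, 0.0, True),
        (100.0, 80.0, 22.22222222222222, False),
    ],
)
def test_qc_discrepancy_examples(inflow, outflow, expected, passes):
    disc = vf.inflow_outflow_discrepancy(inflow, outflow)
    assert disc == pytest.approx(expected, rel=1e-12)
    assert (disc <= 15.0) == passes


def test_qc_report_from_labels(default_analysis):
    qc = default_analysis.qc
    vols = default_analysis.labels.volumes_ml(default_analysis.paths.voxel_volume_ml)
    assert qc.inflow_ml == pytest.approx(vols["direct_flow"] + vols["retained_inflow"])
    assert qc.outflow_ml == pytest.approx(
        vols["direct_flow"] + vols["delayed_ejection_flow"])
    assert qc.passed and qc.discrepancy_pct == pytest.approx(0.0, abs=1e-9)


def test_qc_zero_flow_fails_with_reason(zero_phantom_spec):
    field, seg, timing, _ = vf.generate_slab_phantom(zero_phantom_spec)
    paths = vf.emit_all(field, seg, timing)
    labels = vf.classify(paths, seg)
    qc = vf.qc_inflow_outflow(labels, paths.voxel_volume_ml, paths=paths)
    assert not qc.passed
    assert "undefined" in qc.reason


def test_qc_threshold_configurable():
    # 10% discrepancy: pass at default 15, fail at 5
    from ventriflow.flow_components import ComponentLabels

    n = 20
    primary = np.array([DIRECT_FLOW] * 9 + [RETAINED_INFLOW] * 1
                       + [DELAYED_EJECTION_FLOW] * 2 + [RESIDUAL_VOLUME] * 8,
                       dtype=np.int8)
    labels = ComponentLabels(primary=primary, wave=np.zeros(n, dtype=np.int8),
                             crossing_time=np.full(n, np.nan),
                             no_crossing=np.zeros(n, dtype=bool))
    disc = vf.inflow_outflow_discrepancy(10.0, 11.0)
    qc_loose = vf.qc_inflow_outflow(labels, 1.0, threshold_pct=15.0)
    qc_tight = vf.qc_inflow_outflow(labels, 1.0, threshold_pct=5.0)
    assert qc_loose.passed and not qc_tight.passed
    assert qc_loose.discrepancy_pct == pytest.approx(disc)


@given(st.floats(0.1, 500.0), st.floats(0.1, 500.0))
def test_qc_discrepancy_symmetric_nonnegative(a, b):
    d1 = vf.inflow_outflow_discrepancy(a, b)
    d2 = vf.inflow_outflow_discrepancy(b, a)
    assert d1 == pytest.approx(d2, rel=1e-12)
    assert d1 >= 0.0
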