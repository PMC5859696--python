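"""Slab/rotation phantom generation and its closed-form ground truth."""

import numpy as np
import pytest

import ventriflow as vf
from ventriflow.flow_io import ConfigurationError, RHO_BLOOD
from ventriflow.phantom import WaveSegment, Waveform

from conftest import zero_waveform


def test_zero_waveform_is_all_residual_volume(zero_phantom_spec):
    field, seg, timing, truth = vf.generate_slab_phantom(zero_phantom_spec)
    assert np.all(field.values == 0.0)
    n_ed = int(seg.ed_mask.sum())
    assert truth.component_counts["residual_volume"] == n_ed
    assert all(truth.component_counts[name] == 0
               for name in vf.ALL_COMPONENTS if name != "residual_volume")
    assert all(np.all(curve == 0.0) for curve in truth.ke_curves.values())
    assert truth.mid_diastasis_frame is None


@pytest.mark.parametrize("seed", range(6))
def test_brute_force_equals_closed_form(seed):
    """Per-voxel endpoint checks and interval arithmetic must agree exactly."""
    rng = np.random.default_rng(seed)
    spec = vf.random_slab_spec(rng)
    closed = vf.closed_form_truth(spec)
    brute = vf.brute_force_truth(spec)
    assert brute.component_counts == closed.component_counts
    assert brute.mid_diastasis_frame == closed.mid_diastasis_frame
    for name in vf.ALL_COMPONENTS:
        np.testing.assert_allclose(brute.ke_curves[name], closed.ke_curves[name],
                                   rtol=1e-12)


def test_truth_partition_invariants(rng):
    for _ in range(5):
        spec = vf.random_slab_spec(rng)
        truth = vf.closed_form_truth(spec)
        c = truth.component_counts
        primaries = ("direct_flow", "retained_inflow",
                     "delayed_ejection_flow", "residual_volume")
        vol = spec.voxel_size ** 3 / 1000.0
        assert sum(c[k] for k in primaries) * vol == pytest.approx(truth.edv_ml, rel=1e-12)
        assert c["direct_flow_e"] + c["direct_flow_a"] == c["direct_flow"]
        assert c["retained_inflow_e"] + c["retained_inflow_a"] == c["retained_inflow"]
        # union KE equals 1/2 rho EDV u(t)^2 at every frame
        u = spec.u_samples()
        total = sum(truth.ke_curves[k] for k in primaries)
        expected = 0.5 * RHO_BLOOD * truth.edv_ml * 1e-6 * u**2 * 1e3
        np.testing.assert_allclose(total, expected, rtol=1e-12)


def test_amplitude_doubling_quadruples_total_ke(default_spec):
    spec2 = vf.PhantomSpec(grid_shape=(8, 8, 80),
                           waveform=default_spec.waveform.scaled(2.0))
    spec1 = vf.PhantomSpec(grid_shape=(8, 8, 80))
    t1 = vf.closed_form_truth(spec1)
    t2 = vf.closed_form_truth(spec2)
    primaries = ("direct_flow", "retained_inflow",
                 "delayed_ejection_flow", "residual_volume")
    total1 = sum(t1.ke_curves[k] for k in primaries)
    total2 = sum(t2.ke_curves[k] for k in primaries)
    np.testing.assert_allclose(total2, 4.0 * total1, rtol=1e-12)
    # volumes follow the closed form of the doubled displacements
    assert t2.component_counts == vf.brute_force_truth(spec2).component_counts


def test_rotation_phantom_speed_profile(default_spec):
    omega = 2.0 * np.pi
    spec = vf.PhantomSpec(grid_shape=(16, 16, 4))
    field = vf.generate_rotation_phantom(omega, spec)
    centers = field.voxel_centers()
    cx = (np.array(spec.grid_shape) - 1) * spec.voxel_size / 2.0
    r_mm = np.linalg.norm(centers[:, :2] - cx[:2], axis=1)
    speed = np.linalg.norm(field.values[0].reshape(-1, 3), axis=1)
    np.testing.assert_allclose(speed, omega * r_mm / 1000.0, rtol=1e-12, atol=1e-15)
    zero = vf.generate_rotation_phantom(0.0, spec)
    assert np.all(zero.values == 0.0)


def test_corrupt_field_identity(default_phantom, default_spec):
    field = default_phantom[0]
    import dataclasses

    spec = dataclasses.replace(default_spec, corruption=vf.Corruption())
    out = vf.corrupt_field(field, spec)
    assert out is not field
    assert np.array_equal(out.values, field.values)
    assert np.array_equal(field.values, default_phantom[0].values)  # input untouched


def test_corrupt_field_wrap_value():
    """A 150 cm/s peak at VENC 120 cm/s aliases to -90 cm/s."""
    wf = Waveform(
        systole=WaveSegment(0.050, 150.0, "hann"),
        e_wave=WaveSegment(0.075, 15.68, "trapezoid"),
        diastasis=WaveSegment(0.450, 0.0),
        a_wave=WaveSegment(0.425, 2.1, "trapezoid"),
    )
    spec = vf.PhantomSpec(grid_shape=(4, 4, 72), waveform=wf,
                          corruption=vf.Corruption(wrap_injection=True))
    field, *_ = vf.generate_slab_phantom(spec)
    assert field.values[..., 2].max() == pytest.approx(1.5)
    wrapped = vf.corrupt_field(field, spec)
    assert wrapped.values[..., 2].min() == pytest.approx(-0.9)
    assert np.abs(wrapped.values).max() <= field.venc + 1e-12


def test_corrupt_field_noise_reproducible(default_phantom, default_spec):
    import dataclasses

    field = default_phantom[0]
    spec = dataclasses.replace(default_spec,
                               corruption=vf.Corruption(noise_sd=2.0, seed=42))
    a = vf.corrupt_field(field, spec)
    b = vf.corrupt_field(field, spec)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, field.values)


def test_waveform_exceeding_venc_requires_wrap_injection():
    wf = Waveform(
        systole=WaveSegment(0.050, 150.0, "hann"),
        e_wave=WaveSegment(0.075, 15.68, "trapezoid"),
        diastasis=WaveSegment(0.450, 0.0),
        a_wave=WaveSegment(0.425, 2.1, "trapezoid"),
    )
    with pytest.raises(ConfigurationError, match="VENC"):
        vf.PhantomSpec(grid_shape=(4, 4, 72), waveform=wf).validate()


def test_slab_displaced_outside_grid_rejected():
    wf = Waveform(
        systole=WaveSegment(0.350, 110.0, "hann"),  # ~19 cm forward displacement
        e_wave=WaveSegment(0.075, 15.68, "trapezoid"),
        diastasis=WaveSegment(0.150, 0.0),
        a_wave=WaveSegment(0.425, 2.1, "trapezoid"),
    )
    with pytest.raises(ConfigurationError, match="outside grid"):
        vf.PhantomSpec(waveform=wf).validate()


def test_misaligned_segment_durations_rejected():
    wf = zero_waveform()
    wf.systole.duration += 0.013  # not a whole number of 25 ms frames
    wf.diastasis.duration -= 0.013
    with pytest.raises(ConfigurationError, match="whole number"):
        vf.PhantomSpec(waveform=wf).validate()


def test_default_phantom_truth_geometry(default_phantom):
    """The documented study-condition configuration: three non-empty
    primary components, a split Direct Flow, and balanced in/outflow."""
    *_, truth = default_phantom
    c = truth.component_counts
    assert c["direct_flow"] > 0 and c["retained_inflow"] > 0
    assert c["delayed_ejection_flow"] > 0
    assert c["direct_flow_e"] > 0 and c["direct_flow_a"] > 0
    inflow = c["direct_flow"] + c["retained_inflow"]
    outflow = c["direct_flow"] + c["delayed_ejection_flow"]
    assert inflow == outflow
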