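import numpy as np
import pytest
from hypothesis import settings

import ventriflow as vf
from ventriflow.phantom import WaveSegment, Waveform

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return vf.PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """The study-condition slab phantom: (field, seg, timing, truth)."""
    return vf.generate_slab_phantom(default_spec)


@pytest.fixture(scope="session")
def default_analysis(default_phantom):
    field, seg, timing, _ = default_phantom
    import dataclasses

    return vf.analyze(field, seg, dataclasses.replace(timing))


def zero_waveform():
    return Waveform(
        systole=WaveSegment(0.350, 0.0),
        e_wave=WaveSegment(0.075, 0.0),
        diastasis=WaveSegment(0.150, 0.0),
        a_wave=WaveSegment(0.425, 0.0),
    )


@pytest.fixture()
def zero_phantom_spec():
    """Zero flow everywhere; ED and ES masks coincide, so the whole
    end-diastolic volume resides in the ventricle for >= two cycles."""
    return vf.PhantomSpec(waveform=zero_waveform(), es_slab=(58.0, 111.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
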