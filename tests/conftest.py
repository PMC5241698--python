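import numpy as np
import pytest

import smlmkit as sk


@pytest.fixture(scope="session")
def optics():
    return sk.OpticsConfig(field_px=(16, 16))


@pytest.fixture(scope="session")
def quiet_camera():
    """Noise-free unity-gain camera for deterministic flux/fit checks."""
    return sk.CameraModel(
        em_gain=1, readout_noise_rms=0, baseline_offset=0, quantum_efficiency=1
    )


@pytest.fixture(scope="session")
def default_camera():
    return sk.CameraModel()


def render_single(optics, camera, x_nm, y_nm, shot_noise=False, n_frames=1, frame=0):
    """One full-frame emitter at (x, y); helper shared across test modules."""
    traces = sk.EmitterTraces(
        positions=np.array([[x_nm, y_nm]]),
        n_frames=n_frames,
        active_frame=np.array([frame]),
        active_emitter=np.array([0]),
        on_fraction=np.array([1.0]),
    )
    return sk.render_frames(traces, optics, camera, 0, shot_noise=shot_noise)


@pytest.fixture(scope="session")
def strand_bundle():
    """Small 1D-strand acquisition reused by localizer/feature/classifier tests."""
    return sk.make_fixture("strand_1d", scale="ci", seed=11, n_frames=60)


@pytest.fixture(scope="session")
def strand_table(strand_bundle):
    b = strand_bundle
    return sk.localize_stack(b.stack, b.optics, b.camera)
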