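import numpy as np
import pytest

import xeventmap as xv


@pytest.fixture(scope="session")
def control_phantom():
    return xv.make_phantom(xv.control_spec(seed=7))


@pytest.fixture(scope="session")
def ova_phantom():
    return xv.make_phantom(xv.ova_spec(seed=7))


@pytest.fixture(scope="session")
def noisefree_frame(control_phantom):
    """Noise-free acquisition of the control phantom with unit flip factors."""
    return xv.simulate_acquisition(
        control_phantom.amplitude_map, xv.AcquisitionConfig(), noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noisy_image(control_phantom):
    """Windowed reconstruction of a realistically noised control baseline."""
    spec = control_phantom.spec
    frame = xv.simulate_acquisition(
        control_phantom.amplitude_map, xv.default_config(), spec.noise_sd, seed=11
    )
    return xv.reconstruct(frame)


@pytest.fixture(scope="session")
def small_series():
    """Short noisy control series for bookkeeping/metric tests."""
    spec = xv.control_spec(seed=5)
    return xv.generate_challenge_series(spec, (10, 25, 50), n_baseline=2, seed=5)
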