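import numpy as np
import pytest

from attikit import MeasureConfig, PhantomSpec, build_phantom, measure_volume


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Default noisy phantom volume plus its analytic ground truth."""
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def noisefree_phantom():
    spec = PhantomSpec(noise_sd=0.0)
    vol, gt = build_phantom(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def default_measurement(default_spec, default_phantom):
    vol, _ = default_phantom
    return measure_volume(vol, MeasureConfig(epiphyseal_z=default_spec.epiphyseal_z))


@pytest.fixture(scope="session")
def cylinder_spec():
    """Straight cylinder: no flare, no bump."""
    return PhantomSpec(
        flare_radius_at_epiphysis=12.0,
        tuberosity_height=0.0,
        noise_sd=0.0,
        blur_fwhm=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
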