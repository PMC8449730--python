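import numpy as np
import pytest

from cerevess.phantom import PhantomSpec, StraightCenterline, TubeSpec, demo_spec, make_phantom


@pytest.fixture(scope="session")
def tube_phantom_small():
    """44^3 reference phantom (straight radius-3 tube, SNR 10) plus truth."""
    spec = demo_spec(shape=(44, 44, 44), seed=5)
    vol, mask = make_phantom(spec)
    return vol, mask, spec


@pytest.fixture(scope="session")
def noiseless_tube():
    """Noise-free straight tube for analytic intensity checks."""
    spec = PhantomSpec(
        shape=(40, 40, 40),
        tubes=(TubeSpec(
            StraightCenterline((20.0, 20.0, 0.0), (20.0, 20.0, 39.0)),
            radius=3.0, peak_intensity=200.0, flow_profile_exponent=2.0,
        ),),
        background_components=((1.0, 50.0, 5.0),),
        noise_sd=0.0,
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
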