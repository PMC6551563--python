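import numpy as np
import pytest

from ventparc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 24^3 phantom without pose jitter (midline exactly on the grid)."""
    spec = PhantomSpec(shape=(24, 24, 24), spacing=(4, 4, 4), enlargement=1.0,
                       jitter_rotate_deg=0.0, jitter_translate_vox=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def jittered_phantom():
    """A 24^3 phantom with the default pose jitter enabled."""
    spec = PhantomSpec(shape=(24, 24, 24), spacing=(4, 4, 4), enlargement=1.5, seed=5)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
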