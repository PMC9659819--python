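import numpy as np
import pytest

from gsholo import PhantomSpec, generate_scene


@pytest.fixture(scope="session")
def small_spec():
    """A 64x64 phantom small enough for fast retrieval tests."""
    return PhantomSpec(
        canvas_dims=(64, 64),
        n_epithelial=1,
        n_rbc=1,
        epithelial_radius=14.0,
        rbc_radius=6.0,
        clutter_density=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
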