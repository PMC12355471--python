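import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_instrument():
    """A small, fast observation volume for simulation tests.

    w_xy = 0.2 um, S = 3 keeps particle counts and trace lengths small
    while exercising exactly the same code paths as production settings.
    """
    from nanofcs import SimulationConfig

    def make(**overrides):
        defaults = dict(
            beam_radius_xy=0.2,
            structure_parameter=3.0,
            box_dimensions=(1.4, 1.4, 4.2),
            duration=0.5,
            seed=1,
        )
        defaults.update(overrides)
        return SimulationConfig(**defaults)

    return make


@pytest.fixture
def poisson_trace(rng):
    """An i.i.d. Poisson photon trace (no correlations by construction)."""
    from nanofcs import PhotonTrace

    def make(lam=4.0, n=100_000, bin_width=1e-6, seed=0):
        local = np.random.default_rng(seed)
        return PhotonTrace(bin_width, local.poisson(lam, n))

    return make
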