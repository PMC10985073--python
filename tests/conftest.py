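import numpy as np
import pytest

from mucuslab import synth


@pytest.fixture(scope="session")
def brownian_movie():
    """500 freely diffusing particles at the reference acquisition geometry."""
    spec = synth.TrajectorySimSpec(
        n_particles=500, class_mix=(1.0, 0.0, 0.0), D_free=0.057, seed=101
    )
    return synth.simulate_trajectories(spec)


@pytest.fixture(scope="session")
def subdiffusive_movie():
    """500 fractional-Brownian particles at alpha = 0.3."""
    spec = synth.TrajectorySimSpec(
        n_particles=500, class_mix=(0.0, 1.0, 0.0), alpha_sub=0.3, seed=102
    )
    return synth.simulate_trajectories(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
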