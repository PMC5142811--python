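import numpy as np
import pytest

from wormscreen.core import StimulusProtocol
from wormscreen.synthetic import NeuronSpec, default_specs, simulate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def small_clean_stack():
    """4 well-separated silent nuclei, no noise, no drift, 10 frames."""
    specs = [
        NeuronSpec(center0=(3.0, 10.0, 10.0)),
        NeuronSpec(center0=(3.0, 10.0, 24.0)),
        NeuronSpec(center0=(4.0, 24.0, 10.0)),
        NeuronSpec(center0=(4.0, 24.0, 24.0)),
    ]
    stack, truth = simulate_stack(
        specs,
        shape=(8, 34, 34),
        n_frames=10,
        drift_max_step=0.0,
        shot_noise=False,
        read_noise=0.0,
        seed=0,
    )
    return stack, truth


@pytest.fixture(scope="session")
def default_tracking_stack():
    """The default-difficulty recording: 20 nuclei, 100 frames, bounded
    drift, default noise."""
    specs = default_specs()
    return simulate_stack(specs, n_frames=100, seed=2024)
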