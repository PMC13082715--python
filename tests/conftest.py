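import numpy as np
import pytest

from gainmod.simulate import (
    generate_trials,
    sample_neuron,
    uniform_speed_sampler,
)
from gainmod.tuning import (
    average_frequency,
    build_tensor,
    threshold_normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trials(mode, n_subunits, seed, n_trials=4800, **neuron_kwargs):
    """One neuron's normalized trial table under uniform speed sampling."""
    rng = np.random.default_rng(seed)
    neuron = sample_neuron(mode, n_subunits, rng, **neuron_kwargs)
    trials = generate_trials(
        [neuron], n_trials, rng, speed_sampler=uniform_speed_sampler()
    )
    trials["response"] = threshold_normalize(trials["response"].to_numpy())
    return neuron, trials


@pytest.fixture
def modulated_trials():
    """A speed-modulated two-subunit neuron and its normalized trials."""
    return make_trials("independent", 2, seed=7)


@pytest.fixture
def modulated_curve(modulated_trials):
    _, trials = modulated_trials
    return average_frequency(build_tensor(trials))
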