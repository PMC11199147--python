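import numpy as np
import pandas as pd
import pytest

import innerspeech as isp


@pytest.fixture(scope="session")
def config():
    return isp.TaskConfig()


@pytest.fixture(scope="session")
def four_word_config():
    return isp.TaskConfig(words=("battlefield", "cowboy", "python", "spoon"))


@pytest.fixture(scope="session")
def smg_session(config):
    """One simulated word-selective session: 8 words x 8 reps, 16 units."""
    pop = isp.sample_population(isp.PopulationSpec(n_units=16, seed=11), config)
    trials, spikes, gt = isp.simulate_session(
        pop, config, n_reps=8, cue_modalities=("written",), seed=12
    )
    return pop, trials, spikes, gt


@pytest.fixture(scope="session")
def smg_phase_rates(config, smg_session):
    _, trials, spikes, _ = smg_session
    tensor = isp.smooth_rates(isp.bin_spike_counts(spikes, trials, config), 0.05)
    return isp.phase_average(tensor, trials, config), tensor


def toy_session(config, n_units=2, n_reps=2, seed=0, modalities=("written",)):
    """Small helper session used by round-trip and validation tests."""
    pop = isp.sample_population(
        isp.PopulationSpec(n_units=n_units, tuned_fraction={}, seed=seed), config
    )
    return isp.simulate_session(
        pop, config, n_reps=n_reps, cue_modalities=modalities, seed=seed + 1
    )
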