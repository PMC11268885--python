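import numpy as np
import pytest

import seqwm


@pytest.fixture(scope="session")
def designs_small():
    """72 trials, 8 blocks: smallest size where every IEM fold is healthy."""
    return seqwm.generate_design(n_trials=72, seed=11)


@pytest.fixture(scope="session")
def designs_medium():
    return seqwm.generate_design(n_trials=144, seed=12)


@pytest.fixture(scope="session")
def noiseless_epochs(designs_medium):
    epochs, truth = seqwm.simulate_eeg(designs_medium, snr=np.inf, seed=13)
    return epochs, truth
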