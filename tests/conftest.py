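import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="mne")


@pytest.fixture(scope="session")
def leadfield():
    from breathloop import eeg

    return eeg.build_toy_leadfield()


@pytest.fixture(scope="session")
def crosstalk(leadfield):
    from breathloop import eeg

    return eeg.network_crosstalk_matrix(leadfield, lam=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
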