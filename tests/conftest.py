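import warnings

import numpy as np
import pytest

from nbselect import baseline_config, simulate_dataset


@pytest.fixture(scope="session")
def baseline_data():
    """One baseline replication: 500 features x 40 samples, 45 significant
    (case NB(20,1) vs control NB(5,1)), noise NB(5,1)."""
    return simulate_dataset(baseline_config(seed=11), 0)


@pytest.fixture(scope="session")
def null_data():
    """A dataset with no differential features (both groups NB(5,1))."""
    return simulate_dataset(baseline_config(seed=12, mu_sig_case=5.0), 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # zero-rich NB(5,1) matrices route size factors through the
    # positive-subset fallback on nearly every simulated dataset
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*positive-subset median-of-ratios.*")
        yield
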