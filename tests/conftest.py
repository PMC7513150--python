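import numpy as np
import pytest

import relgamma as rg


@pytest.fixture(scope="session")
def lpre_model():
    return rg.make_noise_model("lpre")


@pytest.fixture(scope="session")
def lsre_model():
    return rg.make_noise_model("lsre")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_data(lpre_model):
    """Small clean Model-1-style dataset (n=80, p=3, no outliers)."""
    cfg = rg.model1_config(n=80, seed=42)
    data, _ = rg.simulate_dataset(cfg, model=lpre_model)
    return data


@pytest.fixture
def contaminated_data(lpre_model):
    """Model-1 dataset with 10% gross upper outliers."""
    cfg = rg.model1_config(n=200, delta=0.1, outlier_mu=5.0, seed=7)
    data, _ = rg.simulate_dataset(cfg, model=lpre_model)
    return data
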