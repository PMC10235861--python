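import numpy as np
import pytest

from softsensor.preprocess import CalibrationDataset
from softsensor.scenarios import build_campaign, noise_free
from softsensor.simulate import DielectricParams


def random_dataset(rng, n=20, p=25, noise=1.0):
    """Random calibration dataset with a planted linear signal."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return CalibrationDataset(
        X=X, y=y, sample_timestamps=np.arange(n, dtype=float) * 300.0,
        batch_ids=np.array(["run"] * n), frequencies_kHz=np.geomspace(50, 20000, p).round(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def drift_campaign():
    """One default-conditions campaign: drift + noise, 3 cal runs + validation."""
    return build_campaign(seed=1)


@pytest.fixture(scope="session")
def drift_campaigns():
    """Ten seeded replicates of the default drift campaign."""
    return [build_campaign(seed=s) for s in range(1, 11)]


@pytest.fixture(scope="session")
def recovery_campaign():
    """Noise-free, constant-diameter campaign (inter-batch diameter spread)."""
    return build_campaign(seed=3, params=noise_free(DielectricParams()), drift=False)
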