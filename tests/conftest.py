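import numpy as np
import pytest
from hypothesis import settings

from itdcode import (DesignSpec, GenerativeTruth, LabelledLineEngine,
                     apply_itd, build_population, fit_likelihood,
                     generate_dataset, make_noise_token)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

SR = 16_000.0  # ample for the 300-1200 Hz band; keeps spectral tests fast


@pytest.fixture(scope="session")
def token():
    """1 s diotic reference token at 16 kHz."""
    return make_noise_token(duration=1.0, sample_rate=SR, seed=7)


@pytest.fixture(scope="session")
def engine(token):
    """Labelled-line engine for a +200 us source."""
    return LabelledLineEngine(apply_itd(token, 200.0), seed=11)


@pytest.fixture(scope="session")
def population():
    return build_population(seed=2)


@pytest.fixture(scope="session")
def likelihood(population):
    return fit_likelihood(population, seed=3)


@pytest.fixture(scope="session")
def full_dataset():
    """One complete synthetic study (10 listeners x 1100 trials)."""
    truth = GenerativeTruth(seed=2)
    trials, sidecar = generate_dataset(DesignSpec(), truth)
    return trials, sidecar, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
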