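import numpy as np
import pytest

from anklestage import synthetic_data as sd


@pytest.fixture(scope="session")
def profiles():
    return sd.default_profiles()


@pytest.fixture(scope="session")
def small_dataset(profiles):
    """14 cycles (imbalanced) of 6 s each; shared across read-only tests."""
    counts = {"I": 4, "II": 2, "III": 2, "IV": 2, "V": 4}
    return sd.generate_dataset(profiles, counts, duration_s=6.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
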