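import numpy as np
import pytest

from circpot import SyntheticConfig, generate_classification_dataset


def random_sequences(seed, n, min_len, max_len, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(alphabet), size=length)))
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled dataset with annotation tracks and toy genome."""
    config = SyntheticConfig(
        n_pos=40, n_neg=40,
        length_range_pos=(150, 350), length_range_neg=(150, 350),
        seed=7)
    return generate_classification_dataset(config)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return small_dataset.records
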