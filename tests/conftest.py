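"""Shared fixtures: synthetic datasets at the sizes the tests need."""

import numpy as np
import pytest

from dmyest import build_mic_grid, generate_dataset, get_profile


@pytest.fixture(scope="session")
def grid():
    return build_mic_grid()


@pytest.fixture(scope="session")
def holstein_small():
    """800 paired records, Holstein profile — cheap fits."""
    return generate_dataset(get_profile("holstein", n_cows=400, records_per_cow=2, seed=42))


@pytest.fixture(scope="session")
def holstein_mid():
    """6,000 paired records — asymmetric-interval ordering checks."""
    return generate_dataset(get_profile("holstein", n_cows=3000, records_per_cow=2, seed=7))


@pytest.fixture(scope="session")
def symmetric_large():
    """50,000 records with both sessions centered at 12 h."""
    return generate_dataset(
        get_profile("symmetric", n_cows=25000, records_per_cow=2, seed=3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
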