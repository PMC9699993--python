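import numpy as np
import pytest

from chicaudit import synthetic_data
from chicaudit.core_model import DistanceBinning


@pytest.fixture(scope="session")
def binning():
    return DistanceBinning()


@pytest.fixture(scope="session")
def small_fmap():
    """300-fragment synthetic chromosome + decoy, 30 baits."""
    return synthetic_data.generate_fragment_map(
        300, mean_len_bp=4000, bait_fraction=0.1, seed=7, n_decoy_fragments=60
    )


@pytest.fixture(scope="session")
def truth_model(small_fmap):
    return synthetic_data.default_null_model(small_fmap, seed=11)


@pytest.fixture(scope="session")
def empty_truth(small_fmap):
    """A truth set with no spiked interactions (pure null data)."""
    return synthetic_data.sample_truth(
        small_fmap, prior_params=(0.0, 0.0, 12.0, 2.0), seed=3
    )


@pytest.fixture(scope="session")
def spiked_truth(small_fmap):
    return synthetic_data.sample_truth(small_fmap, seed=3)


@pytest.fixture(scope="session")
def null_tables(small_fmap, truth_model, empty_truth):
    """Two replicates of pure-null counts."""
    return synthetic_data.simulate_counts(
        small_fmap, truth_model, empty_truth, n_replicates=2, seed=19
    )


@pytest.fixture(scope="session")
def spiked_tables(small_fmap, truth_model, spiked_truth):
    """Two replicates carrying the spiked truth."""
    return synthetic_data.simulate_counts(
        small_fmap, truth_model, spiked_truth, n_replicates=2, seed=19
    )
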