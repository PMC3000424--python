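import warnings

import pytest

from peploc import features, synthetic_data

warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)


@pytest.fixture(scope="session")
def aaindex_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("aaindex") / "aaindex1.txt"
    synthetic_data.generate_aaindex_fixture(path, n_indices=494, seed=11)
    return path


@pytest.fixture(scope="session")
def aaindex_table(aaindex_path):
    return features.load_aaindex(aaindex_path)


@pytest.fixture(scope="session")
def small_table(tmp_path_factory):
    """A 5-entry index table for tests that do not need the full snapshot."""
    path = tmp_path_factory.mktemp("aaindex_small") / "aaindex1.txt"
    synthetic_data.generate_aaindex_fixture(path, n_indices=5, seed=2)
    return features.load_aaindex(path)


@pytest.fixture(scope="session")
def registry(aaindex_table):
    return features.build_feature_registry(aaindex_table)


@pytest.fixture
def three_class_records():
    cfg = synthetic_data.SyntheticConfig(
        classes=("chl", "cyt", "mit"), n_per_class=12, signal_strength=1.0, seed=5,
    )
    return synthetic_data.generate_dataset(cfg)
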