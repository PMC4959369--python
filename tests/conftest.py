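import numpy as np
import pytest

from mraselect import mra, synthetic


@pytest.fixture(scope="session")
def small_config():
    """Easy, well-separated 3-class setup: S=6, E=4, L=4, 64-sample segments."""
    sites = (
        synthetic.InformativeSite(0, 0, (1, 4), (4.0, 8.0), 4.0),
        synthetic.InformativeSite(1, 1, (2, 5), (8.0, 16.0), 4.0),
        synthetic.InformativeSite(2, 2, (0, 3), (18.0, 28.0), 4.0),
    )
    return synthetic.SynthConfig(
        n_classes=3,
        trials_per_class=30,
        n_electrodes=4,
        n_segments=6,
        segment_len=64,
        sampling_rate=64.0,
        informative_sites=sites,
        noise_exponent=1.0,
        snr=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_mra(small_config):
    return mra.MRAConfig(
        n_segments=small_config.n_segments,
        n_electrodes=small_config.n_electrodes,
        n_levels=4,
        segment_len=small_config.segment_len,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return synthetic.split_train_test(small_dataset, 0.5, seed=1)


@pytest.fixture(scope="session")
def small_features(small_split, small_mra):
    """(train_features, train_labels, test_features, test_labels, normalizer)."""
    train, test = small_split
    train_features, normalizer = mra.extract_features(train.trials, small_mra)
    test_features, _ = mra.extract_features(test.trials, small_mra, normalizer)
    return train_features, train.labels, test_features, test.labels, normalizer


@pytest.fixture
def rng():
    return np.random.default_rng(0)
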