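import numpy as np
import pytest

from entrocsp import EpochedEEG, SimConfig, simulate_mi_eeg


@pytest.fixture(scope="session")
def separable_small():
    """Strong-contrast simulated dataset, small enough for fast CV."""
    cfg = SimConfig(trials_per_class=30, erd_ratio=0.4, seed=11)
    epoched, truth = simulate_mi_eeg(cfg)
    return epoched, truth


@pytest.fixture(scope="session")
def null_small():
    """Classes statistically identical (erd_ratio = 1)."""
    cfg = SimConfig(trials_per_class=30, erd_ratio=1.0, seed=12)
    epoched, truth = simulate_mi_eeg(cfg)
    return epoched, truth


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    from entrocsp import make_fixture_suite

    return make_fixture_suite(tmp_path_factory.mktemp("fixtures"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_epoched(rng, m=4, l=3, n=50, fs=100.0):
    return EpochedEEG(
        data=rng.normal(size=(m, l, n)),
        fs=fs,
        channel_names=[f"c{i}" for i in range(l)],
        labels=np.tile([1, 2], (m + 1) // 2)[:m],
    )
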