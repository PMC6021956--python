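import numpy as np
import pytest

from hbcikit import preprocess, simgen


@pytest.fixture(scope="session")
def default_config() -> simgen.SimConfig:
    return simgen.SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_sessions(default_config):
    return simgen.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def default_epochs(default_sessions):
    """Fully preprocessed epochs of the seed-0 synthetic subject."""
    return preprocess.preprocess_dataset(default_sessions)


@pytest.fixture(scope="session")
def small_config() -> simgen.SimConfig:
    """A quick-to-simulate subject: 3 sessions x 5 trials per class."""
    return simgen.SimConfig(seed=3, n_trials_per_class=5,
                            pre_rest_s=15.0, post_rest_s=15.0)


@pytest.fixture(scope="session")
def small_epochs(small_config):
    return preprocess.preprocess_dataset(simgen.simulate_dataset(small_config))


def make_epochset(data: np.ndarray, fs: float, labels=None, t0: float = -5.0,
                  modality: str = "EEG") -> preprocess.EpochSet:
    """Build an EpochSet around arbitrary array data for unit tests."""
    n, c, t = data.shape
    times = t0 + np.arange(t) / fs
    labels = np.asarray(labels if labels is not None else ["MA"] * n)
    return preprocess.EpochSet(
        data=data, times=times, fs=fs, labels=labels,
        session_ids=np.zeros(n, dtype=int), modality=modality,
        channel_labels=tuple(f"ch{i}" for i in range(c)),
    )
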