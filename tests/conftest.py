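import numpy as np
import pandas as pd
import pytest

from catrep.epochs import EpochSet


def make_epochs(
    n_trials=12,
    n_channels=4,
    n_times=20,
    srate=1000.0,
    tmin_ms=-5.0,
    data=None,
    tasks=None,
    categories=None,
    veog_pair=None,
    seed=0,
):
    """Hand-built EpochSet for unit tests (independent of the generator)."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_times))
    n_trials = data.shape[0]
    times = tmin_ms + 1000.0 / srate * np.arange(data.shape[2])
    channels = [f"ch{i}" for i in range(data.shape[1])]
    if veog_pair is not None:
        channels[-2], channels[-1] = veog_pair
    labels = pd.DataFrame(
        {
            "task": tasks if tasks is not None else ["basic"] * n_trials,
            "category": categories
            if categories is not None
            else [["bird", "nonbird_animal"][i % 2] for i in range(n_trials)],
            "correct": pd.array([True] * n_trials, dtype="boolean"),
            "rt_ms": 500.0,
            "participant": "0",
        }
    )
    return EpochSet(
        data=data,
        times=times,
        srate=srate,
        channels=channels,
        labels=labels,
        veog_pair=veog_pair,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One small generated participant shared across read-only tests."""
    import catrep as cr

    ep, gt = cr.generate_epochs(
        design=cr.DesignSpec(n_trials_per_task=120), n_channels=16, seed=42
    )
    return ep, gt
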