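import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import erpdecode as ed

logging.getLogger("erpdecode").setLevel(logging.WARNING)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def montage():
    return ed.builtin_montage()


@pytest.fixture(scope="session")
def small_montage(montage):
    return montage.subset(("O1", "Oz", "O2", "PO7", "PO3", "PO4", "PO8", "Pz",
                           "P9", "P10", "FCz", "Fpz"))


def make_epochs(data, fs=512.0, t_start=-100.0, labels=None, pid="S01"):
    """EpochsArray around a raw array, with minimal trial metadata."""
    n_trials, n_ch, _ = data.shape
    if labels is None:
        labels = ed.CHANNELS_64[:n_ch]
    meta = pd.DataFrame({"image_id": np.arange(n_trials) % 24 + 1,
                         "block": np.arange(n_trials) % 6 + 1,
                         "jitter_s": 4, "retained": True})
    return ed.EpochsArray(pid, data, fs, t_start, tuple(labels), meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_data():
    """One small synthetic session shared by several tests: 2 participants,
    a planted time-reference effect, mild artifacts."""
    schedule = ed.generate_design(seed=7)
    ratings = ed.generate_ratings(2, seed=7)
    effect = ed.EffectSpec(slope_uv=2.0, window_ms=(160.0, 200.0))
    noise = ed.NoiseSpec(rms_uv=10.0, extreme_fraction=0.05)
    epochs = ed.generate_epochs(schedule, ratings, [effect], noise, "S01",
                                seed=7)
    return schedule, ratings, epochs
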