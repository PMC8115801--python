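import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from mindwander import Epoch, GeneratorConfig
from mindwander.features import FEATURE_COLUMNS, FEATURE_NAMES


def make_epoch(data, fs=512.0, t0=-1000.0, channels=None, tone_type="standard",
               artifact=False):
    data = np.asarray(data, dtype=float)
    channels = tuple(channels) if channels else tuple(
        f"ch{i}" for i in range(data.shape[0]))
    times = t0 + np.arange(data.shape[1]) / fs * 1000.0
    return Epoch(data, times, channels, tone_type, 0, 0, artifact)


def make_feature_table(n_subjects=8, n_blocks=25, effect=None, rng=None,
                       mw_fraction=0.55, normalized=1):
    """Synthetic block-feature rows without any EEG simulation.

    ``effect`` maps feature names to the mean shift added to
    mind-wandering rows; remaining variation is unit-normal noise.
    """
    rng = rng or np.random.default_rng(0)
    effect = effect or {}
    rows = []
    for s in range(n_subjects):
        n_mw = int(round(n_blocks * mw_fraction))
        labels = np.array([1] * n_mw + [0] * (n_blocks - n_mw))
        rng.shuffle(labels)
        for b, label in enumerate(labels):
            row = {"subject_id": f"sub-{s + 1:02d}", "block": b,
                   "label": int(label), "n_trials_used": 10,
                   "normalized": normalized}
            for name in FEATURE_NAMES:
                value = rng.normal() + (effect.get(name, 0.0) if label else 0.0)
                if name.endswith("_sd") and not normalized:
                    value = abs(value)
                row[name] = value
            rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(noise_white_sd_uv=0.0, noise_pink_scale_uv=0.0,
                           trial_amplitude_jitter=0.0, subject_gain_sd=0.0,
                           artifact_probability=0.0, mw_attenuation=0.0,
                           seed=11)


@pytest.fixture
def small_config():
    """Short-block economy config for Monte-Carlo style tests."""
    return GeneratorConfig(seed=7).short_blocks()
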