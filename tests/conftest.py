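import dataclasses

import numpy as np
import pytest

from midecode import (
    StudyConfig,
    build_fft_features,
    build_montage,
    generate_recording,
    make_layout,
    segments_from_recording,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study configuration: 32-channel net, full trial protocol."""
    return StudyConfig(n_channels=32)


@pytest.fixture(scope="session")
def control_recording(small_config):
    return generate_recording(small_config, "control", seed=11)


@pytest.fixture(scope="session")
def ldsm_segments(control_recording):
    montage = build_montage("LD-SM", make_layout(control_recording.n_channels))
    return segments_from_recording(control_recording, montage)


@pytest.fixture(scope="session")
def mf_rs_features(ldsm_segments):
    """LD-SM FFT features restricted to the move-foot vs rest pair."""
    table = build_fft_features(ldsm_segments)
    mask = np.isin(ldsm_segments.condition, ["MF", "RS"])
    sub = dataclasses.replace(table, values=table.values[mask])
    return sub, ldsm_segments.condition[mask], ldsm_segments.trial_id[mask]


def separable_features(n_trials=25, n_features=12, shift=2.0, seed=0):
    """Trial-structured Gaussian features with a mean shift on a few columns.

    Returns (values, condition, trial_id) for a two-condition problem with
    six sub-segments per trial, mimicking the geometry of real feature
    tables.
    """
    rng = np.random.default_rng(seed)
    conds = np.repeat(["A", "B"], n_trials * 6)
    trials = np.repeat(np.arange(2 * n_trials), 6)
    X = rng.standard_normal((2 * n_trials * 6, n_features))
    X[conds == "A", :3] += shift
    return X, conds, trials
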