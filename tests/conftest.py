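"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from hemilat.preprocess import Epoch, EpochSet, PreprocessConfig


@pytest.fixture
def cfg():
    return PreprocessConfig()


def toy_epochset(per_epoch_diff, fs=25.0, window=(-10.0, 28.0),
                 base_left=0.0, trial_indices=None):
    """EpochSet on the default grid where epoch i has constant channels:
    left = base_left, right = base_left + per_epoch_diff[i].  Flagged as
    normalized and baseline-corrected so laterality ops accept it."""
    pre, post = window
    n = int(round((post - pre) * fs))
    rel_time = pre + np.arange(n) / fs
    if trial_indices is None:
        trial_indices = range(1, len(per_epoch_diff) + 1)
    epochs = [
        Epoch(int(ti), "A", np.full(n, base_left),
              np.full(n, base_left + d))
        for ti, d in zip(trial_indices, per_epoch_diff)
    ]
    return EpochSet(rel_time, fs, epochs, normalized=True,
                    baseline_corrected=True)


def raw_epochset(left_epochs, right_epochs, fs=25.0, window=(-10.0, 28.0)):
    """EpochSet built from explicit raw channel arrays (pre-normalization,
    pre-baseline); arrays may be shorter than the default window, in which
    case the grid is shrunk to match."""
    n = len(left_epochs[0])
    pre = window[0]
    rel_time = pre + np.arange(n) / fs
    epochs = [
        Epoch(i + 1, "A", np.asarray(l, float).copy(),
              np.asarray(r, float).copy())
        for i, (l, r) in enumerate(zip(left_epochs, right_epochs))
    ]
    return EpochSet(rel_time, fs, epochs)
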