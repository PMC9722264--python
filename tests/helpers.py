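"""Shared helpers for the test suite."""

import numpy as np

from cortexwave import (
    detect_events,
    find_quiet_baseline,
    lowpass_gaussian,
    normalize_dff,
)


def preprocess(trace):
    """Standard pipeline: df/f on the quietest second, 20-Hz low-pass."""
    return lowpass_gaussian(normalize_dff(trace, find_quiet_baseline(trace)))


def detect(trace, **kwargs):
    return detect_events(preprocess(trace), **kwargs)


def match_rates(detected_onsets, true_onsets, tol_s=0.3):
    """(recall, precision) of detected vs true onsets within a tolerance."""
    detected_onsets = np.asarray(detected_onsets)
    true_onsets = np.asarray(true_onsets)
    if len(detected_onsets) == 0 or len(true_onsets) == 0:
        return 0.0, 0.0
    d = np.abs(detected_onsets[:, None] - true_onsets[None, :])
    recall = float((d.min(axis=0) < tol_s).mean())
    precision = float((d.min(axis=1) < tol_s).mean())
    return recall, precision
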