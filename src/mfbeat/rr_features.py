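"""Causal dynamic-normalized RR-interval features.

For beat *i* the pre-RR interval ends at its peak and the post-RR interval
starts there; both are normalized by trailing means of the RR sequence
computed from past intervals only (local window of 80 intervals, global
window of 400).  The first and last beats of a record have no pre-/post-RR
and are flagged invalid rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOCAL_WINDOW = 80
GLOBAL_WINDOW = 400

FEATURE_NAMES = ("pre_rr_local", "pre_rr_global", "post_rr_local", "post_rr_global")


@dataclass(frozen=True)
class RRFeatures:
    pre_rr_local: float
    pre_rr_global: float
    post_rr_local: float
    post_rr_global: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pre_rr_local, self.pre_rr_global, self.post_rr_local, self.post_rr_global]
        )


def rr_intervals(peaks: np.ndarray, fs: float) -> np.ndarray:
    """Consecutive peak differences in seconds (length ``n_peaks - 1``)."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise ValueError("need at least two peaks for RR intervals")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return np.diff(peaks) / fs


def dynamic_means(
    rr: np.ndarray, local_w: int = LOCAL_WINDOW, global_w: int = GLOBAL_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing inclusive means of the RR sequence.

    ``local[i]`` / ``global[i]`` is the mean of up to the last ``local_w`` /
    ``global_w`` intervals ending at interval ``i`` (fewer while history is
    short), so only past and current values enter each mean.
    """
    rr = np.asarray(rr, dtype=np.float64)
    if rr.size == 0:
        raise ValueError("rr must be non-empty")
    if local_w < 1 or global_w < 1:
        raise ValueError("window sizes must be >= 1")

    csum = np.concatenate([[0.0], np.cumsum(rr)])
    idx = np.arange(1, rr.size + 1)

    def trailing(w: int) -> np.ndarray:
        lo = np.maximum(idx - w, 0)
        return (csum[idx] - csum[lo]) / (idx - lo)

    return trailing(local_w), trailing(global_w)


def normalized_rr(
    beat_index: int,
    rr: np.ndarray,
    local_mean: np.ndarray,
    global_mean: np.ndarray,
) -> RRFeatures:
    """The four normalized ratios for one beat.

    ``rr[beat_index - 1]`` is the pre-RR interval and ``rr[beat_index]`` the
    post-RR interval; both are divided by the local and global means available
    at the beat, i.e. the trailing means ending at the pre-RR interval.
    """
    rr = np.asarray(rr)
    if beat_index < 1 or beat_index > rr.size - 1:
        raise ValueError(
            f"beat {beat_index} lacks a predecessor or successor peak "
            f"(valid range 1..{rr.size - 1})"
        )
    pre = rr[beat_index - 1]
    post = rr[beat_index]
    loc = local_mean[beat_index - 1]
    glo = global_mean[beat_index - 1]
    return RRFeatures(pre / loc, pre / glo, post / loc, post / glo)


def compute_rr_features(
    peaks: np.ndarray,
    fs: float,
    local_w: int = LOCAL_WINDOW,
    global_w: int = GLOBAL_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat feature matrix for a whole record.

    Returns
    -------
    features : ndarray of shape (n_beats, 4)
        ``(pre_local, pre_global, post_local, post_global)`` rows; NaN where
        undefined.
    valid : ndarray of bool, shape (n_beats,)
        False for the first and last beat of the record (no pre-/post-RR).
    """
    peaks = np.asarray(peaks)
    n = peaks.size
    features = np.full((n, 4), np.nan)
    valid = np.zeros(n, dtype=bool)
    if n < 3:
        return features, valid
    rr = rr_intervals(peaks, fs)
    local_mean, global_mean = dynamic_means(rr, local_w, global_w)
    for i in range(1, n - 1):
        features[i] = normalized_rr(i, rr, local_mean, global_mean).as_array()
        valid[i] = True
    return features, valid
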