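"""Matched-filter template extraction and the classical correlator receiver.

A template is the arithmetic mean of all training windows of a group (one
group per sub-class, per super-class, or per record x sub-class).  Templates
can be computed on the raw windows or on their first derivatives, and
cropped to their central samples to shorten the correlator kernels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import correlate as _correlate

from .beat_dataset import BeatSegment

GRANULARITIES = ("sub_class", "super_class", "per_record_sub_class")
FEATURE_KINDS = ("signal", "derivative")


def first_derivative(window: np.ndarray) -> np.ndarray:
    """Discrete first difference along the last axis (length shrinks by one)."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape[-1] < 2:
        raise ValueError("window must have at least 2 samples")
    return np.diff(window, axis=-1)


def central_crop(kernel: np.ndarray, nk: int) -> np.ndarray:
    """Crop a kernel to its ``nk`` central samples along the last axis.

    For an odd surplus the extra discarded sample comes from the right edge
    (length 63 -> 32 keeps indices [15, 47)).
    """
    length = kernel.shape[-1]
    if nk > length:
        raise ValueError(f"cannot crop length-{length} kernel to {nk} samples")
    start = (length - nk) // 2
    return kernel[..., start : start + nk]


def correlate(x: np.ndarray, h: np.ndarray, padding: str = "same") -> np.ndarray:
    """Sliding cross-correlation of signal ``x`` with template ``h``, stride 1.

    With ``padding="same"`` the input is zero-padded by ``(K-1)//2`` on the
    left and ``K//2`` on the right so the output has the input's length:
    ``y[n] = sum_k x[n - (K-1)//2 + k] * h[k]``.  This is the alignment used
    by the model's convolutional layer, so the two stay interchangeable.
    """
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if x.ndim != 1 or h.ndim != 1:
        raise ValueError("correlate expects 1-D inputs")
    if h.size > x.size:
        raise ValueError(f"template length {h.size} exceeds signal length {x.size}")
    if padding == "valid":
        return _correlate(x, h, mode="valid")
    if padding == "same":
        pl = (h.size - 1) // 2
        pr = h.size // 2
        xp = np.pad(x, (pl, pr))
        return _correlate(xp, h, mode="valid")
    raise ValueError(f"unknown padding {padding!r}")


@dataclass
class TemplateBank:
    """Matched-filter templates: one fixed-length kernel per group label."""

    labels: list[str]
    kernels: np.ndarray  # (n_templates, nk)
    granularity: str
    feature_kind: str

    def __post_init__(self) -> None:
        self.kernels = np.atleast_2d(np.asarray(self.kernels, dtype=np.float64))
        if len(self.labels) != self.kernels.shape[0]:
            raise ValueError("one label per kernel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels must be unique")
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"granularity must be one of {GRANULARITIES}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")

    @property
    def n_templates(self) -> int:
        return self.kernels.shape[0]

    @property
    def nk(self) -> int:
        return self.kernels.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "granularity": self.granularity,
            "feature_kind": self.feature_kind,
            "nk": self.nk,
            "templates": [
                {"label": lbl, "kernel": kern.tolist()}
                for lbl, kern in zip(self.labels, self.kernels)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TemplateBank":
        payload = json.loads(Path(path).read_text())
        return cls(
            labels=[t["label"] for t in payload["templates"]],
            kernels=np.array([t["kernel"] for t in payload["templates"]]),
            granularity=payload["granularity"],
            feature_kind=payload["feature_kind"],
        )


def _group_key(segment: BeatSegment, granularity: str) -> str:
    if granularity == "sub_class":
        return segment.sub_label
    if granularity == "super_class":
        return segment.super_label
    return f"{segment.record_id}:{segment.sub_label}"


def extract_templates(
    segments: list[BeatSegment],
    granularity: str = "sub_class",
    feature_kind: str = "signal",
    nk: int | None = None,
) -> TemplateBank:
    """Average training windows per group into a template bank.

    Groups with no examples are simply absent.  When ``nk`` is smaller than
    the feature length, templates are cropped to their central ``nk`` samples.
    """
    if not segments:
        raise ValueError("cannot extract templates from an empty segment list")
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")

    groups: dict[str, list[np.ndarray]] = {}
    for seg in segments:
        feat = seg.window if feature_kind == "signal" else first_derivative(seg.window)
        groups.setdefault(_group_key(seg, granularity), []).append(feat)

    labels = sorted(groups)
    kernels = np.stack([np.mean(groups[lbl], axis=0) for lbl in labels])
    if nk is not None:
        kernels = central_crop(kernels, nk)
    return TemplateBank(labels, kernels, granularity, feature_kind)


@dataclass
class MFDecision:
    """Outcome of the matched-filter receiver for one window."""

    best_label: str
    scores: dict[str, float]


def mf_classify(window: np.ndarray, bank: TemplateBank) -> MFDecision:
    """Classify one window as the template with the largest peak correlation.

    ``scores[label]`` is the maximum of the same-padded correlation between
    the window and that label's kernel; ties break toward the lexicographically
    smallest label.  The window must carry the bank's ``feature_kind``.
    """
    window = np.asarray(window, dtype=np.float64)
    scores = {
        lbl: float(np.max(correlate(window, kern, padding="same")))
        for lbl, kern in zip(bank.labels, bank.kernels)
    }
    best = max(sorted(scores), key=lambda lbl: scores[lbl])
    # max() keeps the first (lexicographically smallest) of tied labels
    return MFDecision(best_label=best, scores=scores)
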