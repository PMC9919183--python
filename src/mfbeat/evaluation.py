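"""Per-class and macro metrics, confusion matrices, and the noise-robustness sweep."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mf_cnn import BeatArrays, MFModel, MFModelSpec, TrainConfig, build_model, train
from .matched_filters import TemplateBank
from .synthetic_ecg import add_awgn

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = predicted) with derived metrics."""

    classes: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    zero_division_classes: list[str] = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "zero_division_classes": self.zero_division_classes,
        }

    def pretty(self) -> str:
        width = max(6, max(len(c) for c in self.classes) + 1)
        lines = ["truth \\ pred".rjust(12) + "".join(c.rjust(width) for c in self.classes)]
        for i, c in enumerate(self.classes):
            lines.append(c.rjust(12) + "".join(str(int(v)).rjust(width) for v in self.confusion[i]))
        lines.append(
            f"accuracy={self.accuracy:.4f}  macro F1={self.macro['F1']:.4f}  "
            f"macro SEN={self.macro['SEN']:.4f}  macro PREC={self.macro['PREC']:.4f}"
        )
        return "\n".join(lines)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple[str, ...]
) -> EvalReport:
    """Metrics from truth/prediction label indices.

    Per-class precision, sensitivity and F1 come from one-vs-rest TP/FP/FN of
    the confusion matrix; undefined (0/0) metrics are reported as 0 and the
    class is flagged.  Macro scores are unweighted means over classes with
    non-zero support.
    """
    n = len(classes)
    cm = confusion_matrix(y_true, y_pred, n)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0

    per_class: dict[str, dict[str, float]] = {}
    flagged: list[str] = []
    support_mask = cm.sum(axis=1) > 0
    for i, name in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        sen = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * sen / (prec + sen) if (prec + sen) else 0.0
        if (tp + fp) == 0 or (tp + fn) == 0 or (prec + sen) == 0:
            flagged.append(name)
        per_class[name] = {"PREC": float(prec), "SEN": float(sen), "F1": float(f1)}

    if not np.all(support_mask):
        absent = [classes[i] for i in np.where(~support_mask)[0]]
        logger.warning("classes with zero test support excluded from macro mean: %s", absent)
    macro_classes = [classes[i] for i in np.where(support_mask)[0]] or list(classes)
    macro = {
        m: float(np.mean([per_class[c][m] for c in macro_classes]))
        for m in ("PREC", "SEN", "F1")
    }
    return EvalReport(tuple(classes), cm, per_class, macro, accuracy, flagged)


def evaluate(model: MFModel, data: BeatArrays) -> EvalReport:
    """Predict ``data`` with ``model`` and score against its labels."""
    y_pred = model.predict(data.windows, data.rr)
    return evaluate_predictions(data.y, y_pred, model.spec.classes)


def _with_noisy_windows(data: BeatArrays, noise_percent: float, seed: int) -> BeatArrays:
    if noise_percent == 0:
        return data
    noisy = add_awgn(data.windows.ravel(), noise_percent, seed).reshape(data.windows.shape)
    return BeatArrays(noisy, data.rr, data.y, data.record_ids)


def noise_sweep(
    spec: MFModelSpec,
    train_data: BeatArrays,
    val_data: BeatArrays,
    test_data: BeatArrays,
    grid: list[float],
    mode: str = "test_only",
    bank: TemplateBank | dict[str, TemplateBank] | None = None,
    hyper: TrainConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Accuracy / macro-F1 versus additive-noise power percentage.

    Noise is always applied to the raw signal windows (differencing, when the
    model takes derivative input, happens afterwards inside the model).  In
    ``"test_only"`` mode one model is trained on clean data and evaluated on
    increasingly noisy test sets; in ``"train_and_test"`` mode the model is
    retrained at every grid point with seed ``base_seed + index``.

    Returns a tidy table with columns
    ``noise_percent, mode, seed, accuracy, macro_f1``.
    """
    if mode not in ("test_only", "train_and_test"):
        raise ValueError("mode must be 'test_only' or 'train_and_test'")
    if any(not 0 <= g <= 100 for g in grid):
        raise ValueError("noise grid must lie within [0, 100]")
    hyper = hyper or TrainConfig()

    rows = []
    if mode == "test_only":
        model = build_model(spec, bank)
        train(model, train_data, val_data, hyper)
        for i, pct in enumerate(grid):
            report = evaluate(model, _with_noisy_windows(test_data, pct, base_seed + 1000 + i))
            rows.append((pct, mode, hyper.seed, report.accuracy, report.macro["F1"]))
    else:
        for i, pct in enumerate(grid):
            seed = base_seed + i
            point_hyper = TrainConfig(**{**hyper.__dict__, "seed": seed})
            model = build_model(spec, bank)
            noisy_train = _with_noisy_windows(train_data, pct, seed + 2000)
            noisy_val = _with_noisy_windows(val_data, pct, seed + 3000)
            train(model, noisy_train, noisy_val, point_hyper)
            report = evaluate(model, _with_noisy_windows(test_data, pct, seed + 4000))
            rows.append((pct, mode, seed, report.accuracy, report.macro["F1"]))

    return pd.DataFrame(rows, columns=["noise_percent", "mode", "seed", "accuracy", "macro_f1"])
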