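"""The fused correlator-bank classifier: architecture, parameter accounting, training.

One wide 1-D correlation layer (optionally initialized from matched-filter
templates and optionally frozen) followed by batch normalization, tanh and a
global max over time yields one peak-correlation score per template; a small
dense stack embeds the four normalized RR ratios; both are concatenated into
a softmax head.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .beat_dataset import AAMI_CLASSES
from .matched_filters import TemplateBank, first_derivative

#: Default number of conv kernels per class-count (= template count on the
#: reference training set: 11 sub-classes for {N,SVEB,VEB}, +F, +Q).
DEFAULT_NF = {3: 11, 4: 12, 5: 13}

WINDOW_LEN = 64
RR_WIDTHS = (32, 16, 8)
N_RR_FEATURES = 4

INPUT_FEATURES = ("signal", "derivative", "both")


@dataclass(frozen=True)
class MFModelSpec:
    """All architecture and training-variant knobs."""

    n_classes: int = 3
    nk: int = 32
    nf: int | None = None  # default: template count for n_classes
    input_feature: str = "derivative"
    conv_trainable: bool = True
    conv_init: str = "mf_templates"  # or "default"
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (3, 4, 5):
            raise ValueError("n_classes must be 3, 4 or 5")
        if self.nk not in (32, 64):
            raise ValueError("nk must be 32 or 64")
        if self.input_feature not in INPUT_FEATURES:
            raise ValueError(f"input_feature must be one of {INPUT_FEATURES}")
        if self.conv_init not in ("mf_templates", "default"):
            raise ValueError("conv_init must be 'mf_templates' or 'default'")

    @property
    def n_filters(self) -> int:
        return self.nf if self.nf is not None else DEFAULT_NF[self.n_classes]

    @property
    def cin(self) -> int:
        return 2 if self.input_feature == "both" else 1

    @property
    def classes(self) -> tuple[str, ...]:
        return AAMI_CLASSES[: self.n_classes]


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self) -> None:
        assert self.total == self.trainable + self.non_trainable


def count_params(spec: MFModelSpec) -> ParamCount:
    """Closed-form parameter accounting for any spec.

    conv: ``nf*nk*cin + nf``; BN: ``4*nf`` of which the two moving statistics
    (``2*nf``) are never trainable; RR branch: 64 + 528 + 136; head:
    ``(nf + 32) * n_classes + n_classes``.  Freezing the conv layer moves its
    parameters to the non-trainable count.
    """
    nf, nk, c = spec.n_filters, spec.nk, spec.n_classes
    conv = nf * nk * spec.cin + nf
    bn = 4 * nf
    rr = (1 * RR_WIDTHS[0] + RR_WIDTHS[0]) \
        + (RR_WIDTHS[0] * RR_WIDTHS[1] + RR_WIDTHS[1]) \
        + (RR_WIDTHS[1] * RR_WIDTHS[2] + RR_WIDTHS[2])
    head = (nf + N_RR_FEATURES * RR_WIDTHS[2]) * c + c
    total = conv + bn + rr + head
    non_trainable = 2 * nf + (0 if spec.conv_trainable else conv)
    return ParamCount(total=total, trainable=total - non_trainable, non_trainable=non_trainable)


def prepare_beat_input(windows: np.ndarray, input_feature: str) -> np.ndarray:
    """Turn raw (B, 64) signal windows into the model's (B, 64, cin) input.

    The 63-long first derivative is front-padded with one repeated edge value
    back to 64 samples; ``"both"`` stacks signal and padded derivative as two
    channels.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    if windows.shape[1] != WINDOW_LEN:
        raise ValueError(f"expected {WINDOW_LEN}-sample windows, got {windows.shape[1]}")
    if input_feature == "signal":
        return windows[:, :, None]
    deriv = first_derivative(windows)
    deriv = np.concatenate([deriv[:, :1], deriv], axis=1)
    if input_feature == "derivative":
        return deriv[:, :, None]
    if input_feature == "both":
        return np.stack([windows, deriv], axis=2)
    raise ValueError(f"unknown input_feature {input_feature!r}")


class MFModel:
    """The assembled two-branch network (see :func:`build_model`)."""

    def __init__(self, spec: MFModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        nf = spec.n_filters
        self.conv = _nn.Conv1DSame(spec.nk, spec.cin, nf, rng, trainable=spec.conv_trainable)
        self.bn = _nn.BatchNorm(nf)
        self.tanh = _nn.Tanh()
        self.gmp = _nn.GlobalMaxPool()
        self.rr_dense = [
            _nn.Dense(1, RR_WIDTHS[0], rng, "rr1"),
            _nn.Dense(RR_WIDTHS[0], RR_WIDTHS[1], rng, "rr2"),
            _nn.Dense(RR_WIDTHS[1], RR_WIDTHS[2], rng, "rr3"),
        ]
        self.rr_relu = [_nn.ReLU() for _ in RR_WIDTHS]
        self.head = _nn.Dense(nf + N_RR_FEATURES * RR_WIDTHS[2], spec.n_classes, rng, "head")
        self._rng = rng

    # -- plumbing ---------------------------------------------------------

    def params(self) -> list[_nn.Param]:
        out = self.conv.params() + self.bn.params()
        for d in self.rr_dense:
            out += d.params()
        return out + self.head.params()

    def param_count(self) -> ParamCount:
        trainable = sum(p.size for p in self.params() if p.trainable)
        frozen = sum(p.size for p in self.params() if not p.trainable)
        return ParamCount(trainable + frozen, trainable, frozen)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value = w.copy()

    # -- forward / backward ----------------------------------------------

    def forward(self, xbeat: np.ndarray, xrr: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities for (B, 64, cin) beat input and (B, 4) RR input."""
        h = self.conv.forward(xbeat, training)
        h = self.bn.forward(h, training)
        h = self.tanh.forward(h, training)
        beat_feat = self.gmp.forward(h, training)

        r = np.asarray(xrr, dtype=np.float64)[:, :, None]  # (B, 4, 1)
        for dense, relu in zip(self.rr_dense, self.rr_relu):
            r = relu.forward(dense.forward(r, training), training)
        rr_feat = r.reshape(r.shape[0], -1)  # (B, 32)

        self._nf = beat_feat.shape[1]
        fused = np.concatenate([beat_feat, rr_feat], axis=1)
        self._logits = self.head.forward(fused, training)
        return _nn.softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        dbeat, drr = dfused[:, : self._nf], dfused[:, self._nf :]

        dh = self.gmp.backward(dbeat)
        dh = self.tanh.backward(dh)
        dh = self.bn.backward(dh)
        self.conv.backward(dh)

        dr = drr.reshape(drr.shape[0], N_RR_FEATURES, RR_WIDTHS[2])
        for dense, relu in zip(reversed(self.rr_dense), reversed(self.rr_relu)):
            dr = dense.backward(relu.backward(dr))

    # -- inference --------------------------------------------------------

    def predict_proba(self, windows: np.ndarray, rr: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        xbeat = prepare_beat_input(windows, self.spec.input_feature)
        out = []
        for i in range(0, xbeat.shape[0], batch_size):
            out.append(self.forward(xbeat[i : i + batch_size], rr[i : i + batch_size], training=False))
        return np.concatenate(out, axis=0)

    def predict(self, windows: np.ndarray, rr: np.ndarray) -> np.ndarray:
        return self.predict_proba(windows, rr).argmax(axis=1)


def build_model(spec: MFModelSpec, bank: TemplateBank | dict[str, TemplateBank] | None = None) -> MFModel:
    """Assemble the network, optionally seeding the conv kernels from a bank.

    For ``input_feature="both"`` with template initialization, pass a dict
    with ``"signal"`` and ``"derivative"`` banks sharing the same labels; each
    feeds one input channel of the single conv layer.
    """
    if spec.conv_init == "mf_templates":
        if bank is None:
            raise ValueError("conv_init='mf_templates' requires a template bank")
    elif bank is not None:
        raise ValueError("a bank was given but conv_init is 'default'")

    model = MFModel(spec)
    if bank is None:
        return model

    if spec.input_feature == "both":
        if not isinstance(bank, dict) or set(bank) != {"signal", "derivative"}:
            raise ValueError("'both' input needs {'signal': bank, 'derivative': bank}")
        sig, der = bank["signal"], bank["derivative"]
        if sig.labels != der.labels:
            raise ValueError("signal and derivative banks must share labels")
        _check_bank(spec, sig)
        _check_bank(spec, der)
        kernels = np.stack([sig.kernels, der.kernels], axis=2)  # (nf, nk, 2)
    else:
        if isinstance(bank, dict):
            bank = bank[spec.input_feature]
        expected = {"signal": "signal", "derivative": "derivative"}[spec.input_feature]
        if bank.feature_kind != expected:
            raise ValueError(
                f"bank feature_kind {bank.feature_kind!r} does not match "
                f"input_feature {spec.input_feature!r}"
            )
        _check_bank(spec, bank)
        kernels = bank.kernels
    model.conv.set_kernels(kernels)
    return model


def _check_bank(spec: MFModelSpec, bank: TemplateBank) -> None:
    if bank.n_templates != spec.n_filters or bank.nk != spec.nk:
        raise ValueError(
            f"template bank mismatch: expected nf={spec.n_filters}, nk={spec.nk}; "
            f"found nf={bank.n_templates}, nk={bank.nk}"
        )


# -- training -------------------------------------------------------------


@dataclass
class BeatArrays:
    """Column arrays for one data part: raw windows, RR features, labels."""

    windows: np.ndarray  # (n, 64)
    rr: np.ndarray  # (n, 4)
    y: np.ndarray  # (n,) integer class indices
    record_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return self.y.shape[0]


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 512
    learning_rate: float = 1e-3
    early_stopping_patience: int = 20
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    min_learning_rate: float = 1e-5
    seed: int = 0
    verbose: bool = False


def class_weights(counts: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights ``N_total / (n_classes * N_c)``."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts == 0):
        raise ValueError("class weights undefined for classes with zero examples")
    return counts.sum() / (counts.size * counts)


@dataclass
class History:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def train(
    model: MFModel,
    train_data: BeatArrays,
    val_data: BeatArrays,
    hyper: TrainConfig | None = None,
) -> History:
    """Fit the model with class-weighted cross-entropy, Adam and early stopping.

    Learning rate halves after ``plateau_patience`` epochs without validation
    loss improvement (floored at ``min_learning_rate``); training stops after
    ``early_stopping_patience`` such epochs, restoring the best weights.
    """
    hyper = hyper or TrainConfig()
    spec = model.spec
    counts = np.bincount(train_data.y, minlength=spec.n_classes)
    if np.any(counts == 0):
        missing = [spec.classes[i] for i in np.where(counts == 0)[0]]
        raise ValueError(f"classes absent from training data: {missing}")

    if spec.class_weighting:
        weights = class_weights(counts)
    else:
        weights = np.ones(spec.n_classes)

    xb_train = prepare_beat_input(train_data.windows, spec.input_feature)
    xb_val = prepare_beat_input(val_data.windows, spec.input_feature)
    frozen_conv = None
    if not spec.conv_trainable:
        frozen_conv = model.conv.W.value.copy()

    opt = _nn.Adam(model.params(), lr=hyper.learning_rate)
    rng = np.random.default_rng(hyper.seed)
    history = History()
    best_val = np.inf
    best_weights = model.get_weights()
    since_improve = 0
    since_plateau = 0

    n = len(train_data)
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            xb, xr, y = xb_train[idx], train_data.rr[idx], train_data.y[idx]
            probs = model.forward(xb, xr, training=True)
            loss, dlogits = _nn.weighted_cross_entropy(probs, y, weights[y])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == y).sum())

        val_probs = model.predict_proba(val_data.windows, val_data.rr)
        val_loss, _ = _nn.weighted_cross_entropy(val_probs, val_data.y, weights[val_data.y])
        val_acc = float((val_probs.argmax(axis=1) == val_data.y).mean())

        history.loss.append(epoch_loss / n)
        history.accuracy.append(correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.lr.append(opt.lr)
        if hyper.verbose:  # pragma: no cover - logging only
            print(
                f"epoch {epoch + 1}: loss={epoch_loss / n:.4f} "
                f"val_loss={val_loss:.4f} val_acc={val_acc:.4f} lr={opt.lr:.2g}"
            )

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
            if since_plateau >= hyper.plateau_patience:
                opt.lr = max(opt.lr * hyper.plateau_factor, hyper.min_learning_rate)
                since_plateau = 0
            if since_improve >= hyper.early_stopping_patience:
                history.stopped_epoch = epoch + 1
                break

    model.set_weights(best_weights)
    if frozen_conv is not None:
        # trainability contract: frozen kernels must be bit-identical
        assert np.array_equal(model.conv.W.value, frozen_conv)
    return history


def clone_model(model: MFModel) -> MFModel:
    """Deep copy (weights included) of a model."""
    return copy.deepcopy(model)
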