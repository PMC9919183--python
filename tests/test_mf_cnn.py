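import numpy as np
import pytest

from mfbeat.matched_filters import TemplateBank, correlate
from mfbeat.mf_cnn import (
    BeatArrays,
    MFModelSpec,
    TrainConfig,
    build_model,
    class_weights,
    count_params,
    prepare_beat_input,
    train,
)


def random_bank(rng, nf=3, nk=32, feature_kind="derivative"):
    labels = [f"c{i}" for i in range(nf)]
    return TemplateBank(labels, rng.normal(size=(nf, nk)), "sub_class", feature_kind)


class TestCountParams:
    # full Table-3 grid: (classes, nk) -> (conv, total, trainable-frozen, non-trainable-frozen)
    TABLE = {
        (3, 32): (363, 1267, 882, 385),
        (3, 64): (715, 1619, 882, 737),
        (4, 32): (396, 1352, 932, 420),
        (4, 64): (780, 1736, 932, 804),
        (5, 32): (429, 1439, 984, 455),
        (5, 64): (845, 1855, 984, 871),
    }

    @pytest.mark.parametrize("n_classes,nk", sorted(TABLE))
    def test_reference_grid_frozen(self, n_classes, nk):
        conv, total, trainable, non_trainable = self.TABLE[(n_classes, nk)]
        spec = MFModelSpec(n_classes=n_classes, nk=nk, conv_trainable=False, conv_init="default")
        pc = count_params(spec)
        assert pc.total == total
        assert pc.trainable == trainable
        assert pc.non_trainable == non_trainable

    @pytest.mark.parametrize("n_classes,nk", sorted(TABLE))
    def test_reference_grid_trainable(self, n_classes, nk):
        conv, total, _, _ = self.TABLE[(n_classes, nk)]
        spec = MFModelSpec(n_classes=n_classes, nk=nk, conv_trainable=True, conv_init="default")
        pc = count_params(spec)
        assert pc.total == total
        assert pc.non_trainable == 2 * spec.n_filters  # BN moving statistics only
        assert pc.trainable == total - 2 * spec.n_filters

    def test_trainable_nk64_variant(self):
        pc = count_params(MFModelSpec(n_classes=3, nk=64, conv_trainable=True, conv_init="default"))
        assert pc.trainable == 1597

    def test_two_channel_input_matches_nk64_total(self):
        # one conv layer with 2 input channels doubles only the kernel weights
        pc = count_params(MFModelSpec(n_classes=3, nk=32, input_feature="both", conv_init="default"))
        assert pc.total == 1619

    @pytest.mark.parametrize("n_classes,nk", sorted(TABLE))
    @pytest.mark.parametrize("conv_trainable", [True, False])
    def test_matches_built_network_introspection(self, n_classes, nk, conv_trainable):
        spec = MFModelSpec(
            n_classes=n_classes, nk=nk, conv_trainable=conv_trainable, conv_init="default"
        )
        model = build_model(spec)
        assert model.param_count() == count_params(spec)

    def test_concatenated_width_and_head(self):
        spec = MFModelSpec(n_classes=3, nk=32, conv_init="default")
        assert spec.n_filters + 32 == 43
        head = (spec.n_filters + 32) * 3 + 3
        assert head == 132


class TestPrepareBeatInput:
    def test_signal_shape(self, rng):
        x = prepare_beat_input(rng.normal(size=(5, 64)), "signal")
        assert x.shape == (5, 64, 1)

    def test_derivative_front_padding(self, rng):
        w = rng.normal(size=(2, 64))
        x = prepare_beat_input(w, "derivative")
        assert x.shape == (2, 64, 1)
        d = np.diff(w, axis=1)
        assert np.array_equal(x[:, 1:, 0], d)
        assert np.array_equal(x[:, 0, 0], d[:, 0])  # repeated edge value

    def test_both_stacks_channels(self, rng):
        w = rng.normal(size=(3, 64))
        x = prepare_beat_input(w, "both")
        assert x.shape == (3, 64, 2)
        assert np.array_equal(x[:, :, 0], w)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError, match="64"):
            prepare_beat_input(rng.normal(size=(3, 50)), "signal")


class TestBuildModel:
    def test_softmax_outputs_sum_to_one(self, rng):
        model = build_model(MFModelSpec(n_classes=5, nk=64, conv_init="default", seed=3))
        probs = model.predict_proba(rng.normal(size=(7, 64)), rng.normal(size=(7, 4)))
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_bank_mismatch_reports_expected_and_found(self, rng):
        bank = random_bank(rng, nf=4, nk=32)
        spec = MFModelSpec(n_classes=3, nk=32, nf=3, conv_init="mf_templates")
        with pytest.raises(ValueError, match="nf=3.*nf=4"):
            build_model(spec, bank)

    def test_bank_required_for_mf_init(self):
        with pytest.raises(ValueError, match="requires a template bank"):
            build_model(MFModelSpec(conv_init="mf_templates"))

    def test_feature_kind_mismatch_rejected(self, rng):
        bank = random_bank(rng, feature_kind="signal")
        spec = MFModelSpec(n_classes=3, nk=32, nf=3, input_feature="derivative")
        with pytest.raises(ValueError, match="feature_kind"):
            build_model(spec, bank)

    def test_frozen_conv_equals_correlate_plus_bias(self, rng):
        """The correlator-layer output must equal correlate() + bias channel-wise."""
        bank = random_bank(rng, nf=3, nk=32, feature_kind="derivative")
        spec = MFModelSpec(
            n_classes=3, nk=32, nf=3, input_feature="derivative",
            conv_trainable=False, conv_init="mf_templates", seed=0,
        )
        model = build_model(spec, bank)
        model.conv.b.value = rng.normal(size=3)  # non-trivial bias
        windows = rng.normal(size=(4, 64))
        xbeat = prepare_beat_input(windows, "derivative")
        out = model.conv.forward(xbeat)
        for b in range(4):
            for t in range(3):
                expected = correlate(xbeat[b, :, 0], bank.kernels[t]) + model.conv.b.value[t]
                assert np.max(np.abs(out[b, :, t] - expected)) < 1e-5

    def test_both_channel_kernels_from_two_banks(self, rng):
        sig = random_bank(rng, nf=3, nk=32, feature_kind="signal")
        der = TemplateBank(sig.labels, rng.normal(size=(3, 32)), "sub_class", "derivative")
        spec = MFModelSpec(n_classes=3, nk=32, nf=3, input_feature="both",
                           conv_init="mf_templates")
        model = build_model(spec, {"signal": sig, "derivative": der})
        assert np.allclose(model.conv.W.value[:, 0, :].T, sig.kernels)
        assert np.allclose(model.conv.W.value[:, 1, :].T, der.kernels)

    def test_seeded_build_is_reproducible(self):
        spec = MFModelSpec(conv_init="default", seed=5)
        a, b = build_model(spec), build_model(spec)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestClassWeights:
    def test_formula(self):
        w = class_weights(np.array([90, 5, 5]))
        assert w == pytest.approx([100 / 270, 100 / 15, 100 / 15])

    def test_balanced_counts_give_unit_weights(self):
        assert class_weights(np.array([10, 10, 10])) == pytest.approx([1, 1, 1])

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.array([5, 0]))


def _toy_arrays(rng, n=300, n_classes=3):
    y = rng.integers(0, n_classes, size=n)
    windows = rng.normal(size=(n, 64)) * 0.05
    for i in range(n):
        windows[i, 20 + 8 * y[i] : 28 + 8 * y[i]] += 2.0  # class-coded bump
    rr = rng.normal(1.0, 0.05, size=(n, 4)) + 0.3 * y[:, None]
    return BeatArrays(windows, rr, y)


class TestTrain:
    def test_missing_class_rejected_before_training(self, rng):
        data = _toy_arrays(rng)
        data.y[:] = 0
        model = build_model(MFModelSpec(conv_init="default", seed=0))
        with pytest.raises(ValueError, match="absent"):
            train(model, data, data, TrainConfig(epochs=1))

    def test_frozen_kernels_bit_identical_after_training(self, rng):
        bank = random_bank(rng, nf=3, nk=32)
        spec = MFModelSpec(n_classes=3, nk=32, nf=3, input_feature="derivative",
                           conv_trainable=False, conv_init="mf_templates", seed=1)
        model = build_model(spec, bank)
        before = model.conv.W.value.copy()
        train(model, _toy_arrays(rng), _toy_arrays(rng), TrainConfig(epochs=3, batch_size=64))
        assert np.array_equal(model.conv.W.value, before)

    def test_trainable_conv_actually_moves(self, rng):
        model = build_model(MFModelSpec(conv_init="default", seed=1))
        before = model.conv.W.value.copy()
        train(model, _toy_arrays(rng), _toy_arrays(rng), TrainConfig(epochs=3, batch_size=64))
        assert not np.array_equal(model.conv.W.value, before)

    def test_history_shape_and_early_stop_restores_best(self, rng):
        model = build_model(MFModelSpec(conv_init="default", seed=2))
        tr, va = _toy_arrays(rng), _toy_arrays(rng)
        h = train(model, tr, va, TrainConfig(epochs=30, batch_size=64,
                                             early_stopping_patience=5, seed=2))
        assert len(h.loss) == len(h.val_loss) == len(h.accuracy) == len(h.val_accuracy)
        assert len(h.loss) <= 30

    def test_synthetic_validation_accuracy(self, trained_frozen_model):
        _, history = trained_frozen_model
        assert max(history.val_accuracy[:100]) > 0.9

    def test_training_is_seed_reproducible(self, rng):
        tr, va = _toy_arrays(rng), _toy_arrays(rng)
        outs = []
        for _ in range(2):
            model = build_model(MFModelSpec(conv_init="default", seed=3))
            train(model, tr, va, TrainConfig(epochs=4, batch_size=64, seed=3))
            outs.append(model.get_weights())
        for a, b in zip(*outs):
            assert np.array_equal(a, b)
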