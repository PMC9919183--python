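import numpy as np
import pytest

from mfbeat.app import frame_to_segments
from mfbeat.beat_dataset import BeatSegment
from mfbeat.matched_filters import (
    TemplateBank,
    central_crop,
    correlate,
    extract_templates,
    first_derivative,
    mf_classify,
)


def oracle_correlate_same(x, h):
    """Explicit double-loop correlation with the layer's 'same' alignment."""
    n, k = len(x), len(h)
    pl = (k - 1) // 2
    out = np.zeros(n)
    for i in range(n):
        for j in range(k):
            src = i - pl + j
            if 0 <= src < n:
                out[i] += x[src] * h[j]
    return out


class TestFirstDerivative:
    def test_constant_is_zero(self):
        assert np.array_equal(first_derivative(np.full(10, 3.0)), np.zeros(9))

    def test_small_example(self):
        assert np.array_equal(first_derivative(np.array([0.0, 1, 3, 6])), [1, 2, 3])

    def test_ramp_plus_step_symbolic(self):
        # d/dn (a*n + c + s*1[n>=m]) = a + s*delta[n==m]
        n = np.arange(20.0)
        a, c, s, m = 0.5, 2.0, 4.0, 12
        window = a * n + c + s * (n >= m)
        expected = np.full(19, a)
        expected[m - 1] += s
        assert np.allclose(first_derivative(window), expected)

    def test_too_short(self):
        with pytest.raises(ValueError):
            first_derivative(np.array([1.0]))


class TestCorrelate:
    def test_unit_impulse_reproduces_input(self, rng):
        x = rng.normal(size=50)
        h = np.zeros(5)
        h[(len(h) - 1) // 2] = 1.0  # impulse at the 'same' anchor tap
        assert np.allclose(correlate(x, h), x)

    def test_autocorrelation_peak_is_energy(self, rng):
        x = rng.normal(size=33)
        x /= np.linalg.norm(x)
        y = correlate(x, x)
        assert np.max(y) == pytest.approx(1.0)  # unit energy
        assert np.argmax(y) == (len(x) - 1) // 2  # the aligned lag

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 80))
            k = int(rng.integers(2, n + 1))
            x = rng.normal(size=n)
            h = rng.normal(size=k)
            assert np.max(np.abs(correlate(x, h) - oracle_correlate_same(x, h))) < 1e-9

    def test_linear_in_both_arguments(self, rng):
        x1, x2 = rng.normal(size=40), rng.normal(size=40)
        h1, h2 = rng.normal(size=16), rng.normal(size=16)
        a, b = 2.5, -1.25
        assert np.allclose(correlate(a * x1 + b * x2, h1), a * correlate(x1, h1) + b * correlate(x2, h1))
        assert np.allclose(correlate(x1, a * h1 + b * h2), a * correlate(x1, h1) + b * correlate(x1, h2))

    def test_template_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            correlate(np.ones(4), np.ones(8))


class TestCentralCrop:
    def test_frozen_derivative_offsets(self):
        kernel = np.arange(63.0)
        out = central_crop(kernel, 32)
        assert np.array_equal(out, np.arange(15.0, 47.0))

    def test_even_to_even(self):
        assert np.array_equal(central_crop(np.arange(64.0), 32), np.arange(16.0, 48.0))

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            central_crop(np.arange(10.0), 20)


def _segments(windows, subs, rid="r0"):
    return [
        BeatSegment(rid, 100 * i, np.asarray(w, dtype=float), s, {"N": "N", "A": "SVEB", "V": "VEB"}[s])
        for i, (w, s) in enumerate(zip(windows, subs))
    ]


class TestExtractTemplates:
    def test_mean_of_identical_windows(self, rng):
        w = rng.normal(size=64)
        bank = extract_templates(_segments([w, w, w], ["N", "N", "N"]))
        assert bank.n_templates == 1
        assert np.allclose(bank.kernels[0], w)

    def test_group_mean(self, rng):
        w1, w2 = rng.normal(size=64), rng.normal(size=64)
        bank = extract_templates(_segments([w1, w2], ["V", "V"]))
        assert np.allclose(bank.kernels[0], (w1 + w2) / 2)

    def test_permutation_invariance(self, rng):
        windows = rng.normal(size=(20, 64))
        subs = list("NAV") * 6 + ["N", "N"]
        a = extract_templates(_segments(windows, subs))
        order = rng.permutation(20)
        b = extract_templates(_segments(windows[order], [subs[i] for i in order]))
        assert a.labels == b.labels
        assert np.allclose(a.kernels, b.kernels)

    def test_template_count_is_nonempty_group_count(self, rng):
        windows = rng.normal(size=(5, 64))
        bank = extract_templates(_segments(windows, ["N", "N", "V", "V", "V"]))
        assert bank.labels == ["N", "V"]

    def test_granularities(self, rng):
        segs = _segments(rng.normal(size=(4, 64)), ["N", "A", "V", "V"], rid="rA") + _segments(
            rng.normal(size=(2, 64)), ["N", "V"], rid="rB"
        )
        assert extract_templates(segs, "sub_class").n_templates == 3
        assert extract_templates(segs, "super_class").n_templates == 3
        assert extract_templates(segs, "per_record_sub_class").n_templates == 5

    def test_derivative_then_average_equals_average_then_derivative(self, rng):
        windows = rng.normal(size=(9, 64))
        segs = _segments(windows, ["N"] * 9)
        by_diff = extract_templates(segs, feature_kind="derivative")
        by_mean = first_derivative(extract_templates(segs, feature_kind="signal").kernels[0])
        assert np.allclose(by_diff.kernels[0], by_mean)

    def test_nk_crop(self, rng):
        bank = extract_templates(_segments(rng.normal(size=(3, 64)), ["N"] * 3),
                                 feature_kind="derivative", nk=32)
        assert bank.nk == 32

    def test_nk_too_long_rejected(self, rng):
        with pytest.raises(ValueError, match="crop"):
            extract_templates(_segments(rng.normal(size=(3, 64)), ["N"] * 3),
                              feature_kind="derivative", nk=64)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_templates([])

    def test_save_load_round_trip(self, rng, tmp_path):
        bank = extract_templates(_segments(rng.normal(size=(6, 64)), list("NAVNAV")), nk=32)
        bank.save(tmp_path / "bank.json")
        back = TemplateBank.load(tmp_path / "bank.json")
        assert back.labels == bank.labels
        assert np.allclose(back.kernels, bank.kernels)
        assert (back.granularity, back.feature_kind) == (bank.granularity, bank.feature_kind)


class TestMfClassify:
    def test_recovers_matching_kernel(self, rng):
        kernels = np.linalg.qr(rng.normal(size=(64, 3)))[0].T  # near-orthonormal rows
        bank = TemplateBank(["a", "b", "c"], kernels, "sub_class", "signal")
        decision = mf_classify(kernels[1], bank)
        assert decision.best_label == "b"

    def test_zero_window_ties_break_lexicographically(self):
        bank = TemplateBank(["z", "m", "a"], np.ones((3, 8)), "sub_class", "signal")
        decision = mf_classify(np.zeros(16), bank)
        assert decision.best_label == "a"
        assert all(v == 0.0 for v in decision.scores.values())

    def test_synthetic_three_class_accuracy(self, synth_frames, synth_banks):
        bank = synth_banks["signal"]
        segments = frame_to_segments(synth_frames["test"])
        hits = sum(mf_classify(s.window, bank).best_label == s.sub_label for s in segments)
        assert hits / len(segments) > 0.9

    def test_best_label_is_argmax_of_scores(self, rng):
        bank = TemplateBank(["x", "y"], rng.normal(size=(2, 16)), "sub_class", "signal")
        d = mf_classify(rng.normal(size=64), bank)
        assert d.scores[d.best_label] == max(d.scores.values())
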