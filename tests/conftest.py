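import numpy as np
import pytest

from mfbeat.app import RunConfig, build_segment_store, frame_to_arrays, make_banks
from mfbeat.synthetic_ecg import SyntheticConfig, synthesize_record


@pytest.fixture(scope="session")
def small_record():
    """One clean 3-class synthetic record at 360 Hz (~75 beats)."""
    return synthesize_record(SyntheticConfig(fs=360.0, duration=60.0, seed=11))


def _part_records(part: str, offset: int, duration: float = 600.0, n: int = 3):
    return [
        synthesize_record(
            SyntheticConfig(
                fs=360.0,
                duration=duration,
                seed=7 + offset + i,
                record_id=f"syn-{part}-{i}",
            )
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def synth_frames():
    """Segment stores for train/val/test parts, ~2400 beats each, fixed seeds."""
    return {
        part: build_segment_store(_part_records(part, offset))
        for part, offset in (("train", 100), ("val", 200), ("test", 300))
    }


@pytest.fixture(scope="session")
def synth_arrays(synth_frames):
    return {part: frame_to_arrays(frame, 3) for part, frame in synth_frames.items()}


@pytest.fixture(scope="session")
def synth_banks(synth_frames):
    cfg = RunConfig(nk=32, input_feature="both", seed=7)
    return make_banks(synth_frames["train"], cfg)


@pytest.fixture(scope="session")
def trained_frozen_model(synth_arrays, synth_banks):
    """Frozen-conv MF-initialized derivative model trained on the synthetic set."""
    from mfbeat.mf_cnn import MFModelSpec, TrainConfig, build_model, train

    bank = synth_banks["derivative"]
    spec = MFModelSpec(
        n_classes=3,
        nk=32,
        nf=bank.n_templates,
        input_feature="derivative",
        conv_trainable=False,
        conv_init="mf_templates",
        seed=7,
    )
    model = build_model(spec, bank)
    history = train(
        model,
        synth_arrays["train"],
        synth_arrays["val"],
        TrainConfig(epochs=150, batch_size=256, seed=7),
    )
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
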