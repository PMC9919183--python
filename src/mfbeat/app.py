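"""End-to-end pipeline: segment -> features -> templates -> build -> train -> evaluate.

A run is driven by a :class:`RunConfig` (defaults match the best-F1 model
variant: 3 classes, derivative input, 32-tap kernels initialized from
templates, trainable conv, no class weighting) and leaves behind a manifest
with every knob needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beat_dataset import (
    AAMI_CLASSES,
    TARGET_FS,
    WINDOW_LEN,
    BeatSegment,
    resample_record,
    segment_beats,
)
from .matched_filters import TemplateBank, extract_templates
from .mf_cnn import (
    BeatArrays,
    MFModel,
    MFModelSpec,
    TrainConfig,
    build_model,
    count_params,
    train,
)
from .evaluation import EvalReport, evaluate
from .record_io import BeatRecord, read_fixture
from .rr_features import compute_rr_features
from .synthetic_ecg import SyntheticConfig, synthesize_record

logger = logging.getLogger(__name__)


# -- segment store ---------------------------------------------------------


def segments_to_frame(record: BeatRecord, window_len: int = WINDOW_LEN) -> pd.DataFrame:
    """Segment one record (already at the target rate) into a tidy table.

    Columns: ``record_id, center_index, sub_label, super_label, rr_valid``,
    the four RR features ``rr_pre_local, rr_pre_global, rr_post_local,
    rr_post_global`` and the window samples ``w000..w063``.
    """
    segments = segment_beats(record, window_len)
    rr, valid = compute_rr_features(record.peaks, record.fs)
    pos = {int(p): i for i, p in enumerate(record.peaks)}
    rows = []
    for seg in segments:
        i = pos[seg.center_index]
        rows.append(
            {
                "record_id": seg.record_id,
                "center_index": seg.center_index,
                "sub_label": seg.sub_label,
                "super_label": seg.super_label,
                "rr_valid": bool(valid[i]),
                "rr_pre_local": rr[i, 0],
                "rr_pre_global": rr[i, 1],
                "rr_post_local": rr[i, 2],
                "rr_post_global": rr[i, 3],
                **{f"w{j:03d}": seg.window[j] for j in range(window_len)},
            }
        )
    return pd.DataFrame(rows)


def build_segment_store(records: list[BeatRecord], target_fs: float = TARGET_FS,
                        window_len: int = WINDOW_LEN) -> pd.DataFrame:
    frames = []
    for record in records:
        if record.fs != target_fs:
            record = resample_record(record, target_fs)
        frames.append(segments_to_frame(record, window_len))
    return pd.concat(frames, ignore_index=True)


def frame_to_segments(frame: pd.DataFrame) -> list[BeatSegment]:
    wcols = sorted(c for c in frame.columns if c.startswith("w") and c[1:].isdigit())
    windows = frame[wcols].to_numpy()
    return [
        BeatSegment(
            record_id=str(row.record_id),
            center_index=int(row.center_index),
            window=windows[i],
            sub_label=str(row.sub_label),
            super_label=str(row.super_label),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]


def frame_to_arrays(frame: pd.DataFrame, n_classes: int) -> BeatArrays:
    """Trainable arrays from a segment store: valid-RR beats of the head's classes."""
    classes = AAMI_CLASSES[:n_classes]
    keep = frame["rr_valid"] & frame["super_label"].isin(classes)
    sub = frame[keep]
    wcols = sorted(c for c in frame.columns if c.startswith("w") and c[1:].isdigit())
    class_index = {c: i for i, c in enumerate(classes)}
    return BeatArrays(
        windows=sub[wcols].to_numpy(dtype=np.float64),
        rr=sub[["rr_pre_local", "rr_pre_global", "rr_post_local", "rr_post_global"]].to_numpy(
            dtype=np.float64
        ),
        y=sub["super_label"].map(class_index).to_numpy(dtype=np.int64),
        record_ids=sub["record_id"].astype(str).to_numpy(),
    )


# -- model persistence -----------------------------------------------------


def save_model(model: MFModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(
        json.dumps(dataclasses.asdict(model.spec), indent=2) + "\n"
    )
    weights = {p.name + f"#{i}": p.value.tolist() for i, p in enumerate(model.params())}
    (directory / "weights.json").write_text(json.dumps(weights) + "\n")


def load_model(directory: str | Path) -> MFModel:
    directory = Path(directory)
    spec = MFModelSpec(**json.loads((directory / "spec.json").read_text()))
    model = MFModel(spec)
    weights = json.loads((directory / "weights.json").read_text())
    model.set_weights([np.array(v) for v in weights.values()])
    return model


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    # data: "synthetic" generates records; "fixtures" reads fixture-dialect paths
    data_source: str = "synthetic"
    fixture_train: list[str] = field(default_factory=list)
    fixture_val: list[str] = field(default_factory=list)
    fixture_test: list[str] = field(default_factory=list)
    synthetic_duration: float = 300.0
    synthetic_records: int = 3  # per part (train/val/test)
    synthetic_noise_percent: float = 0.0
    class_mix: dict[str, float] = field(default_factory=lambda: {"N": 0.70, "A": 0.15, "V": 0.15})

    target_fs: float = TARGET_FS
    window_len: int = WINDOW_LEN

    # model (defaults: best-F1 variant)
    n_classes: int = 3
    nk: int = 32
    input_feature: str = "derivative"
    conv_trainable: bool = True
    conv_init: str = "mf_templates"
    class_weighting: bool = False
    template_granularity: str = "sub_class"

    # training
    epochs: int = 500
    batch_size: int = 512
    learning_rate: float = 1e-3
    early_stopping_patience: int = 20

    seed: int = 0
    out_dir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def model_spec(self, nf: int | None = None) -> MFModelSpec:
        return MFModelSpec(
            n_classes=self.n_classes,
            nk=self.nk,
            nf=nf,
            input_feature=self.input_feature,
            conv_trainable=self.conv_trainable,
            conv_init=self.conv_init,
            class_weighting=self.class_weighting,
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            early_stopping_patience=self.early_stopping_patience,
            seed=self.seed,
        )


def _synthetic_part(config: RunConfig, part: str, offset: int) -> list[BeatRecord]:
    records = []
    for i in range(config.synthetic_records):
        sc = SyntheticConfig(
            fs=360.0,
            duration=config.synthetic_duration,
            class_mix=dict(config.class_mix),
            noise_percent=config.synthetic_noise_percent,
            seed=config.seed + offset + i,
            record_id=f"syn-{part}-{i}",
        )
        records.append(synthesize_record(sc))
    return records


def _load_part(config: RunConfig, part: str) -> list[BeatRecord]:
    if config.data_source == "synthetic":
        offset = {"train": 100, "val": 200, "test": 300}[part]
        return _synthetic_part(config, part, offset)
    paths = getattr(config, f"fixture_{part}")
    if not paths:
        raise ValueError(f"data_source='fixtures' but fixture_{part} is empty")
    return [read_fixture(p) for p in paths]


def make_banks(frame: pd.DataFrame, config: RunConfig) -> dict[str, TemplateBank]:
    """Template banks on the training part, for signal and derivative features."""
    arrays_frame = frame[frame["super_label"].isin(AAMI_CLASSES[: config.n_classes])]
    segments = frame_to_segments(arrays_frame)
    kinds = ("signal", "derivative") if config.input_feature == "both" else (config.input_feature,)
    return {
        kind: extract_templates(segments, config.template_granularity, kind, nk=config.nk)
        for kind in kinds
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write a manifest; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def _fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    stage = "segment"
    try:
        t0 = time.perf_counter()
        frames = {
            part: build_segment_store(
                _load_part(config, part), config.target_fs, config.window_len
            )
            for part in ("train", "val", "test")
        }
        for part, frame in frames.items():
            frame.to_csv(out / f"segments_{part}.csv", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "beats": {part: int(len(f)) for part, f in frames.items()},
        }

        stage = "templates"
        t0 = time.perf_counter()
        banks = make_banks(frames["train"], config)
        bank_for_model: TemplateBank | dict[str, TemplateBank] | None
        if config.conv_init == "mf_templates":
            if config.input_feature == "both":
                bank_for_model = banks
            else:
                bank_for_model = banks[config.input_feature]
        else:
            bank_for_model = None
        for kind, bank in banks.items():
            bank.save(out / f"templates_{kind}.json")
        n_templates = next(iter(banks.values())).n_templates
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_templates": n_templates,
            "granularity": config.template_granularity,
        }

        stage = "build"
        spec = config.model_spec(nf=n_templates if config.conv_init == "mf_templates" else None)
        model = build_model(spec, bank_for_model)
        counts = count_params(spec)
        assert model.param_count() == counts
        manifest["stages"][stage] = {
            "param_count": dataclasses.asdict(counts),
            "spec": dataclasses.asdict(spec),
        }

        stage = "train"
        t0 = time.perf_counter()
        arrays = {p: frame_to_arrays(frames[p], config.n_classes) for p in frames}
        history = train(model, arrays["train"], arrays["val"], config.train_config())
        save_model(model, out / "model")
        (out / "model" / "history.json").write_text(
            json.dumps(dataclasses.asdict(history), indent=2) + "\n"
        )
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "epochs_run": len(history.loss),
            "stopped_epoch": history.stopped_epoch,
            "best_val_loss": min(history.val_loss) if history.val_loss else None,
        }

        stage = "evaluate"
        t0 = time.perf_counter()
        report = evaluate(model, arrays["test"])
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        logger.info("confusion matrix:\n%s", report.pretty())
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "metrics": {"accuracy": report.accuracy, "macro": report.macro},
        }
    except Exception as exc:
        _fail(stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def write_report(report: EvalReport, base: str | Path) -> None:
    """Emit an evaluation report as JSON plus a per-class CSV."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    base.with_suffix(".json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    rows = [
        {"class": c, **{m.lower(): v for m, v in metrics.items()}}
        for c, metrics in report.per_class.items()
    ]
    pd.DataFrame(rows).to_csv(base.with_suffix(".csv"), index=False)
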