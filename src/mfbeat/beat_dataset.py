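"""Fixed-length labeled beat segments: resampling, windowing, AAMI mapping, splits."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .record_io import BeatRecord

logger = logging.getLogger(__name__)

#: Sub-class annotation symbol -> AAMI super-class.
AAMI_MAPPING: dict[str, str] = {
    # Normal
    "N": "N", "R": "N", "L": "N", "e": "N", "j": "N",
    # Supraventricular ectopic
    "A": "SVEB", "S": "SVEB", "J": "SVEB", "a": "SVEB",
    # Ventricular ectopic
    "E": "VEB", "V": "VEB",
    # Fusion
    "F": "F",
    # Unknown / paced
    "Q": "Q", "f": "Q", "/": "Q",
}

#: Super-class order used for model heads of 3, 4 and 5 classes.
AAMI_CLASSES: tuple[str, ...] = ("N", "SVEB", "VEB", "F", "Q")

#: Inter-patient division of the MIT-BIH arrhythmia database.
DS1_RECORDS: tuple[str, ...] = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119", "122",
    "124", "201", "203", "205", "207", "208", "209", "215", "220", "223", "230",
)
DS2_RECORDS: tuple[str, ...] = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202", "210",
    "212", "213", "214", "219", "221", "222", "228", "231", "232", "233", "234",
)

#: Default segment geometry: 0.5 s at 128 Hz.
TARGET_FS = 128.0
WINDOW_LEN = 64


def map_to_aami(symbol: str) -> str:
    """Map a sub-class beat symbol to its AAMI super-class."""
    try:
        return AAMI_MAPPING[symbol]
    except KeyError:
        raise KeyError(f"unknown beat symbol {symbol!r}") from None


@dataclass
class BeatSegment:
    """One fixed-length window centered on an annotated R-peak."""

    record_id: str
    center_index: int
    window: np.ndarray
    sub_label: str
    super_label: str


@dataclass(frozen=True)
class SplitSpec:
    """Record-id lists of the inter-patient split plus the train/val rule."""

    ds1_records: tuple[str, ...] = DS1_RECORDS
    ds2_records: tuple[str, ...] = DS2_RECORDS
    train_val_threshold: int = 200

    def __post_init__(self) -> None:
        overlap = set(self.ds1_records) & set(self.ds2_records)
        if overlap:
            raise ValueError(f"records in both DS1 and DS2: {sorted(overlap)}")


def resample_record(record: BeatRecord, target_fs: float = TARGET_FS) -> BeatRecord:
    """Resample a record to ``target_fs`` with polyphase anti-aliased filtering.

    Peak indices are rescaled by ``target_fs / fs`` and rounded half-to-even,
    then clipped into the resampled signal's range.
    """
    if record.fs < target_fs:
        raise ValueError(
            f"upsampling not supported: record fs {record.fs} < target {target_fs}"
        )
    if record.fs == target_fs:
        return record

    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(record.fs).limit_denominator(10**6)
    signal = resample_poly(record.signal, ratio.numerator, ratio.denominator)
    scale = float(ratio)
    peaks = np.rint(record.peaks * scale).astype(np.int64)
    peaks = np.clip(peaks, 0, signal.size - 1)
    # rounding can only collide peaks closer than one output sample; keep order strict
    for i in range(1, peaks.size):
        if peaks[i] <= peaks[i - 1]:
            peaks[i] = peaks[i - 1] + 1
    return BeatRecord(record.record_id, target_fs, signal, peaks, record.symbols)


def segment_beats(record: BeatRecord, window_len: int = WINDOW_LEN) -> list[BeatSegment]:
    """Cut one window per annotated beat, edge-padding at record boundaries.

    The window spans ``[peak - L//2, peak + L - L//2)`` so the R-peak sits at
    index ``L//2``; out-of-range samples repeat the nearest edge value.  Beats
    whose symbol has no AAMI mapping are skipped (counted in a warning).
    """
    half = window_len // 2
    offsets = np.arange(window_len) - half
    segments: list[BeatSegment] = []
    skipped = 0
    for peak, symbol in zip(record.peaks, record.symbols):
        if symbol not in AAMI_MAPPING:
            skipped += 1
            continue
        idx = np.clip(peak + offsets, 0, record.signal.size - 1)
        segments.append(
            BeatSegment(
                record_id=record.record_id,
                center_index=int(peak),
                window=record.signal[idx].copy(),
                sub_label=symbol,
                super_label=AAMI_MAPPING[symbol],
            )
        )
    if skipped:
        logger.warning("record %s: skipped %d beats with unknown symbols", record.record_id, skipped)
    return segments


@dataclass
class DatasetSplit:
    ds1_train: list = field(default_factory=list)
    ds1_val: list = field(default_factory=list)
    ds2_test: list = field(default_factory=list)


def split_inter_patient(segments: list[BeatSegment], spec: SplitSpec | None = None) -> DatasetSplit:
    """Partition segments by record id into DS1-train, DS1-validation, DS2-test.

    DS1 records with a numeric id below ``spec.train_val_threshold`` go to the
    training part, the remaining DS1 records to validation, and DS2 records to
    test.  A segment whose record id is in neither list is an error.
    """
    spec = spec or SplitSpec()
    ds1 = set(spec.ds1_records)
    ds2 = set(spec.ds2_records)
    out = DatasetSplit()
    for seg in segments:
        rid = seg.record_id
        if rid in ds1:
            try:
                numeric = int(rid)
            except ValueError:
                numeric = spec.train_val_threshold  # non-numeric ids -> validation
            (out.ds1_train if numeric < spec.train_val_threshold else out.ds1_val).append(seg)
        elif rid in ds2:
            out.ds2_test.append(seg)
        else:
            raise ValueError(f"record id {rid!r} is in neither DS1 nor DS2")
    return out
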