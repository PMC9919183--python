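"""Annotated single-lead ECG records: in-memory type, fixture dialect, WFDB reading.

The fixture dialect is a trio of plain-text files sharing a base path:

``<base>.json``
    header with ``record_id``, ``fs`` and ``n_samples``
``<base>.signal.csv``
    two columns, ``index,value``
``<base>.ann.csv``
    two columns, ``peak_index,symbol``

It exists so every downstream stage is testable and diffable without any
binary database download.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import wfdb_io

logger = logging.getLogger(__name__)

#: Beat annotation symbols recognised as heartbeats; anything else found in a
#: source record (rhythm changes, signal-quality notes, ...) is dropped.
BEAT_SYMBOLS = frozenset("NLRejASJaEVFQf/")


class RecordError(ValueError):
    """Raised for malformed or inconsistent record data."""


@dataclass
class BeatRecord:
    """A continuous single-lead ECG signal with annotated beat positions.

    Parameters
    ----------
    record_id : str
        Source identifier (e.g. the MIT-BIH record number as a string).
    fs : float
        Sampling rate in Hz.
    signal : ndarray of shape (n_samples,)
        Single-lead samples, in whatever scale the source provides.
    peaks : ndarray of int
        Strictly increasing 0-based sample indices of annotated R-peaks.
    symbols : list of str
        One single-character beat annotation symbol per peak.
    """

    record_id: str
    fs: float
    signal: np.ndarray
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.peaks = np.asarray(self.peaks, dtype=np.int64)
        self.symbols = list(self.symbols)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise RecordError(f"fs must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise RecordError("signal must be a non-empty 1-D array")
        if len(self.peaks) != len(self.symbols):
            raise RecordError(
                f"peaks ({len(self.peaks)}) and symbols ({len(self.symbols)}) "
                "must have equal length"
            )
        if len(self.peaks) > 0:
            if np.any(np.diff(self.peaks) <= 0):
                raise RecordError("peaks must be strictly increasing")
            if self.peaks[0] < 0 or self.peaks[-1] >= self.signal.size:
                raise RecordError("peak indices must lie inside the signal")

    @property
    def n_beats(self) -> int:
        return len(self.peaks)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.signal.size / self.fs


def _fixture_paths(path: str | Path) -> tuple[Path, Path, Path]:
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    return (
        base.with_suffix(".json"),
        base.with_name(base.name + ".signal.csv"),
        base.with_name(base.name + ".ann.csv"),
    )


def write_fixture(record: BeatRecord, path: str | Path) -> None:
    """Write ``record`` in the plain-text fixture dialect under base ``path``."""
    header_p, signal_p, ann_p = _fixture_paths(path)
    header_p.parent.mkdir(parents=True, exist_ok=True)
    header_p.write_text(
        json.dumps(
            {
                "record_id": record.record_id,
                "fs": record.fs,
                "n_samples": int(record.signal.size),
            },
            indent=2,
        )
        + "\n"
    )
    with signal_p.open("w") as fh:
        fh.write("index,value\n")
        for i, v in enumerate(record.signal):
            fh.write(f"{i},{float(v)!r}\n")
    with ann_p.open("w") as fh:
        fh.write("peak_index,symbol\n")
        for p, s in zip(record.peaks, record.symbols):
            fh.write(f"{p},{s}\n")


def read_fixture(path: str | Path) -> BeatRecord:
    """Read a fixture-dialect record written by :func:`write_fixture`.

    Raises
    ------
    RecordError
        On any malformed file, with file and line context in the message.
    """
    header_p, signal_p, ann_p = _fixture_paths(path)
    for p in (header_p, signal_p, ann_p):
        if not p.exists():
            raise RecordError(f"fixture file missing: {p}")

    try:
        header = json.loads(header_p.read_text())
        record_id = str(header["record_id"])
        fs = float(header["fs"])
        n_samples = int(header["n_samples"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise RecordError(f"{header_p}: malformed header ({exc})") from exc

    signal = np.empty(n_samples, dtype=np.float64)
    with signal_p.open() as fh:
        first = fh.readline()
        if first.strip() != "index,value":
            raise RecordError(f"{signal_p}:1: expected header 'index,value'")
        count = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                idx_s, val_s = line.split(",")
                idx = int(idx_s)
                signal[idx] = float(val_s)
            except (ValueError, IndexError) as exc:
                raise RecordError(f"{signal_p}:{lineno}: bad row {line!r}") from exc
            count += 1
    if count != n_samples:
        raise RecordError(
            f"{signal_p}: {count} samples read, header promises {n_samples}"
        )

    peaks: list[int] = []
    symbols: list[str] = []
    with ann_p.open() as fh:
        first = fh.readline()
        if first.strip() != "peak_index,symbol":
            raise RecordError(f"{ann_p}:1: expected header 'peak_index,symbol'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                p_s, sym = line.split(",")
                peaks.append(int(p_s))
                symbols.append(sym)
            except ValueError as exc:
                raise RecordError(f"{ann_p}:{lineno}: bad row {line!r}") from exc

    try:
        return BeatRecord(record_id, fs, signal, np.array(peaks, dtype=np.int64), symbols)
    except RecordError as exc:
        raise RecordError(f"{path}: {exc}") from exc


def read_wfdb_record(path: str | Path, lead_name: str = "MLII") -> BeatRecord:
    """Read one lead of a WFDB record plus its beat annotations.

    Parameters
    ----------
    path : str or Path
        Record path without extension (``.hea``, ``.dat`` and ``.atr`` are
        resolved from it).
    lead_name : str
        Signal description to select, e.g. ``"MLII"`` or ``"V1"``.

    Returns
    -------
    BeatRecord
        Samples of the requested lead in physical units, with only beat
        annotations retained (symbols outside :data:`BEAT_SYMBOLS` dropped).
    """
    base = Path(path)
    header = wfdb_io.read_header(base.with_suffix(".hea"))
    names = [s.description for s in header.signals]
    if lead_name not in names:
        raise RecordError(
            f"lead {lead_name!r} not in record {header.record_name!r}; "
            f"available leads: {names}"
        )
    chan = names.index(lead_name)
    signal = wfdb_io.read_signal(base, header, chan)

    atr = base.with_suffix(".atr")
    if not atr.exists():
        raise RecordError(f"annotation file missing: {atr}")
    annotations = wfdb_io.read_annotations(atr)

    peaks: list[int] = []
    symbols: list[str] = []
    dropped = 0
    for sample, symbol in annotations:
        if symbol in BEAT_SYMBOLS and 0 <= sample < signal.size:
            peaks.append(sample)
            symbols.append(symbol)
        else:
            dropped += 1
            logger.debug("dropping non-beat annotation %r at sample %d", symbol, sample)
    if dropped:
        logger.debug("record %s: dropped %d non-beat annotations", header.record_name, dropped)

    return BeatRecord(
        header.record_name,
        header.fs,
        signal,
        np.array(peaks, dtype=np.int64),
        symbols,
    )
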