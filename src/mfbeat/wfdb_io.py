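"""Minimal reader for PhysioNet WFDB records (header, signal, annotations).

Supports the subset of the WFDB spec needed for the MIT-BIH-style arrhythmia
databases: single-segment records, signal formats 212 and 16 with all signals
interleaved in one ``.dat`` file, and MIT-format annotation files.  Samples
are converted to physical units via ``(adc - baseline) / gain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class WFDBFormatError(ValueError):
    """Raised when a WFDB file cannot be parsed."""


#: WFDB annotation code -> annotation symbol (ecgcodes subset).
ANNOTATION_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_CODES = {v: k for k, v in ANNOTATION_SYMBOLS.items()}

# pseudo-annotation codes
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class Header:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    signals: list[SignalSpec]


def read_header(path: str | Path) -> Header:
    """Parse a ``.hea`` header file."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WFDBFormatError(f"{path}: empty header")
    top = lines[0].split()
    if len(top) < 2:
        raise WFDBFormatError(f"{path}: bad record line {lines[0]!r}")
    record_name = top[0].split("/")[0]
    n_signals = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    n_samples = int(top[3]) if len(top) > 3 else 0

    signals: list[SignalSpec] = []
    for ln in lines[1 : 1 + n_signals]:
        tok = ln.split()
        if len(tok) < 2:
            raise WFDBFormatError(f"{path}: bad signal line {ln!r}")
        file_name = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        adc_zero = 0
        if len(tok) > 2:
            gspec = tok[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gspec, bspec = gspec.split("(", 1)
                baseline = int(bspec.rstrip(")"))
                has_baseline = True
            else:
                has_baseline = False
            gain = float(gspec) if gspec else 200.0
            if gain == 0:
                gain = 200.0
            if len(tok) > 4:
                adc_zero = int(tok[4])
            if not has_baseline:
                baseline = adc_zero
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalSpec(file_name, fmt, gain, baseline, units, description))
    return Header(record_name, n_signals, fs, n_samples, signals)


def _decode_212(raw: np.ndarray, n_signals: int) -> np.ndarray:
    """Unpack format-212 byte triplets into an (n_frames, n_signals) array."""
    if raw.size % 3:
        raw = raw[: raw.size - raw.size % 3]
    triplets = raw.reshape(-1, 3).astype(np.int32)
    s1 = ((triplets[:, 1] & 0x0F) << 8) | triplets[:, 0]
    s2 = ((triplets[:, 1] & 0xF0) << 4) | triplets[:, 2]
    out = np.empty(triplets.shape[0] * 2, dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096  # sign-extend 12-bit
    n_frames = out.size // n_signals
    return out[: n_frames * n_signals].reshape(n_frames, n_signals)


def read_signal(base: str | Path, header: Header, channel: int) -> np.ndarray:
    """Read one channel of the record's ``.dat`` file in physical units."""
    spec = header.signals[channel]
    dat = Path(base).parent / spec.file_name
    if not dat.exists():
        raise WFDBFormatError(f"signal file missing: {dat}")
    raw = np.fromfile(dat, dtype=np.uint8)
    if spec.fmt == 212:
        adc = _decode_212(raw, header.n_signals)
    elif spec.fmt == 16:
        adc = raw.view("<i2").astype(np.int32)
        n_frames = adc.size // header.n_signals
        adc = adc[: n_frames * header.n_signals].reshape(n_frames, header.n_signals)
    else:
        raise WFDBFormatError(f"unsupported WFDB signal format {spec.fmt}")
    if header.n_samples:
        adc = adc[: header.n_samples]
    return (adc[:, channel] - spec.baseline) / spec.gain


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read a MIT-format annotation file into (sample, symbol) pairs."""
    data = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        b0, b1 = data[i], data[i + 1]
        i += 2
        code = b1 >> 2
        interval = ((b1 & 0x03) << 8) | b0
        if code == 0 and interval == 0:
            break  # EOF
        if code == _SKIP:
            if i + 3 >= n:
                raise WFDBFormatError(f"{path}: truncated SKIP")
            high = int.from_bytes(data[i : i + 2], "little")
            low = int.from_bytes(data[i + 2 : i + 4], "little")
            t += (high << 16) | low
            i += 4
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += interval + (interval & 1)
        else:
            t += interval
            symbol = ANNOTATION_SYMBOLS.get(code)
            if symbol is not None:
                out.append((t, symbol))
    return out


# -- writing (test/fixture support; real MIT-BIH files are read-only inputs) --

def write_record(
    base: str | Path,
    fs: float,
    signals: np.ndarray,
    descriptions: list[str],
    annotations: list[tuple[int, str]],
    gain: float = 200.0,
    fmt: int = 212,
) -> None:
    """Write a minimal WFDB record (header + format-212 dat + atr).

    ``signals`` is (n_samples, n_signals) in physical units.  Exists so the
    reader can be exercised end-to-end without downloaded data.
    """
    base = Path(base)
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    if signals.shape[0] < signals.shape[1]:
        raise ValueError("signals must be (n_samples, n_signals)")
    n_samples, n_signals = signals.shape
    if fmt != 212:
        raise ValueError("only format 212 writing is supported")

    adc = np.clip(np.round(signals * gain), -2048, 2047).astype(np.int32)
    flat = adc.reshape(-1)
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    u = np.where(flat < 0, flat + 4096, flat).astype(np.uint32)
    s1, s2 = u[0::2], u[1::2]
    packed = np.empty((s1.size, 3), dtype=np.uint8)
    packed[:, 0] = s1 & 0xFF
    packed[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
    packed[:, 2] = s2 & 0xFF
    (base.parent / (base.name + ".dat")).write_bytes(packed.tobytes())

    lines = [f"{base.name} {n_signals} {fs:g} {n_samples}"]
    for k in range(n_signals):
        lines.append(
            f"{base.name}.dat 212 {gain:g}(0)/mV 12 0 0 0 0 {descriptions[k]}"
        )
    (base.parent / (base.name + ".hea")).write_text("\n".join(lines) + "\n")

    buf = bytearray()
    t = 0
    for sample, symbol in sorted(annotations):
        code = SYMBOL_CODES[symbol]
        dt = sample - t
        if dt < 0:
            raise ValueError("annotations must be in ascending sample order")
        if dt > 1023:
            buf += bytes([0, _SKIP << 2])
            buf += int(dt >> 16).to_bytes(2, "little")
            buf += int(dt & 0xFFFF).to_bytes(2, "little")
            dt = 0
        buf += bytes([dt & 0xFF, (code << 2) | ((dt >> 8) & 0x03)])
        t = sample
    buf += bytes([0, 0])
    (base.parent / (base.name + ".atr")).write_bytes(bytes(buf))
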