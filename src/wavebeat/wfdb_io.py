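"""Minimal WFDB record support: format-16 signals and MIT annotation files.

Implements the subset of the WFDB specification this package needs: a
single-segment header (``.hea``), one interleaved 16-bit little-endian signal
file shared by all channels, and the standard MIT annotation coding (2-byte
words, SKIP/NUM/SUB/CHN/AUX pseudo-annotations). Samples are converted to
physical units via ``(digital - baseline) / gain``; annotation times are
returned as 0-based sample indices.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .records import BeatAnnotations, SignalRecord

PathLike = Union[str, os.PathLike]

# MIT annotation code -> mnemonic symbol (subset: codes that occur in beat files)
ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
ANN_CODES = {s: c for c, s in ANN_SYMBOLS.items()}

#: Annotation symbols that mark a beat (AAMI-style beat set).
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ?")

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _parse_header(hea_path: str):
    with open(hea_path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise IOError(f"{hea_path}: empty header")
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    nsig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    nsamp = int(rec[3]) if len(rec) > 3 else None
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = tok[2] if len(tok) > 2 else "200"
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        if "(" in gain_field:
            g, b = gain_field.split("(")
            gain = float(g)
            baseline = int(b.rstrip(")"))
        else:
            gain = float(gain_field)
            baseline = int(tok[4]) if len(tok) > 4 else 0  # adc zero
        if gain == 0:
            gain = 200.0  # WFDB convention for unspecified gain
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}"
        specs.append(_SignalSpec(tok[0], fmt, gain, baseline, units, desc))
    return name, nsig, fs, nsamp, specs


def read_wfdb_record(
    record: PathLike,
    channel: Union[int, str] = 0,
    modality: str = "ecg",
    annotator: str = "atr",
) -> tuple[SignalRecord, Optional[BeatAnnotations]]:
    """Read one channel of a WFDB record plus its beat annotations, if any.

    Parameters
    ----------
    record : path
        Record base name (no extension); ``record.hea`` and the signal file
        it names must exist.
    channel : int or str
        Channel index or its description string from the header.
    annotator : str
        Annotation file extension to look for (default ``atr``). Only
        beat-type symbols (:data:`BEAT_SYMBOLS`) are returned.

    Returns
    -------
    (SignalRecord, BeatAnnotations or None)
    """
    base = os.fspath(record)
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise IOError(f"header file not found: {hea}")
    name, nsig, fs, nsamp, specs = _parse_header(hea)

    if isinstance(channel, str):
        matches = [i for i, s in enumerate(specs) if s.description == channel]
        if not matches:
            raise ValueError(
                f"channel {channel!r} not in record {name} "
                f"(have {[s.description for s in specs]})"
            )
        ch = matches[0]
    else:
        ch = int(channel)
        if not 0 <= ch < nsig:
            raise ValueError(f"channel index {ch} out of range for {nsig} signals")

    spec = specs[ch]
    if spec.fmt != 16:
        raise NotImplementedError(f"only WFDB format 16 is supported, got {spec.fmt}")
    if any(s.file_name != spec.file_name for s in specs):
        raise NotImplementedError("multi-file signal groups are not supported")

    dat = os.path.join(os.path.dirname(base), spec.file_name)
    if not os.path.exists(dat):
        raise IOError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)
    if nsamp is not None:
        raw = raw[:nsamp]
    physical = (raw[:, ch].astype(float) - spec.baseline) / spec.gain
    rec_out = SignalRecord(physical, fs=fs, modality=modality,
                           label=f"{name}:{spec.description}")

    ann_path = base + "." + annotator
    ann = None
    if os.path.exists(ann_path):
        idx, _sym = read_wfdb_annotations(ann_path, symbols=BEAT_SYMBOLS)
        idx = idx[idx < len(rec_out)]
        ann = BeatAnnotations(idx, fs=fs)
    return rec_out, ann


def read_wfdb_annotations(
    path: PathLike, symbols: Optional[frozenset] = None
) -> tuple[np.ndarray, list[str]]:
    """Decode a MIT annotation file into (sample indices, symbols).

    ``symbols``, if given, filters the output to that set (e.g.
    :data:`BEAT_SYMBOLS`).
    """
    data = np.fromfile(os.fspath(path), dtype=np.uint8)
    times: list[int] = []
    syms: list[str] = []
    t = 0
    i = 0
    pending = 0
    while i + 1 < data.size:
        a, b = int(data[i]), int(data[i + 1])
        i += 2
        code = b >> 2
        interval = ((b & 0x03) << 8) | a
        if code == 0 and interval == 0:
            break  # end of file
        if code == _SKIP:
            if i + 3 >= data.size:
                break
            hi = int(data[i]) | (int(data[i + 1]) << 8)
            lo = int(data[i + 2]) | (int(data[i + 3]) << 8)
            i += 4
            pending += struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
        elif code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifiers; ignored
        else:
            t += interval + pending
            pending = 0
            sym = ANN_SYMBOLS.get(code, "?")
            if symbols is None or sym in symbols:
                times.append(t)
                syms.append(sym)
    return np.asarray(times, dtype=np.int64), syms


def write_wfdb_annotations(path: PathLike, indices: Sequence[int],
                           symbols: Optional[Sequence[str]] = None) -> None:
    """Encode annotations in MIT format (SKIP words for long intervals)."""
    indices = np.asarray(indices, dtype=np.int64)
    if symbols is None:
        symbols = ["N"] * indices.size
    out = bytearray()
    prev = 0
    for t, sym in zip(indices, symbols):
        code = ANN_CODES.get(sym, 13)  # unknown -> Q
        delta = int(t - prev)
        prev = int(t)
        if delta > 1023 or delta < 0:
            u = struct.unpack("<I", struct.pack("<i", delta))[0]
            out += bytes([0, _SKIP << 2])
            out += struct.pack("<HH", (u >> 16) & 0xFFFF, u & 0xFFFF)
            delta = 0
        out += bytes([delta & 0xFF, (code << 2) | ((delta >> 8) & 0x03)])
    out += bytes([0, 0])
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def write_wfdb_record(
    record: PathLike,
    signals: Sequence[SignalRecord],
    gain: float = 1000.0,
    annotations: Optional[BeatAnnotations] = None,
    ann_symbols: Optional[Sequence[str]] = None,
    annotator: str = "atr",
) -> None:
    """Write channels as a format-16 WFDB record (plus optional annotations).

    Digital values are ``round(physical * gain)`` clipped to int16, so the
    round-trip is exact to 1/gain quantization.
    """
    base = os.fspath(record)
    name = os.path.basename(base)
    fs = signals[0].fs
    n = min(len(s) for s in signals)
    if any(s.fs != fs for s in signals):
        raise ValueError("all channels must share one sampling rate")
    dig = np.empty((n, len(signals)), dtype="<i2")
    for k, s in enumerate(signals):
        d = np.round(s.samples[:n] * gain)
        dig[:, k] = np.clip(d, -32768, 32767).astype("<i2")
    dig.tofile(base + ".dat")
    with open(base + ".hea", "w", encoding="utf-8") as fh:
        fh.write(f"{name} {len(signals)} {fs:g} {n}\n")
        for k, s in enumerate(signals):
            fh.write(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(dig[0, k])} 0 0 "
                     f"{s.label or f'ch{k}'}\n")
    if annotations is not None:
        write_wfdb_annotations(base + "." + annotator, annotations.indices,
                               ann_symbols)
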