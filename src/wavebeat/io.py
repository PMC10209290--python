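"""Plain-text signal and annotation I/O.

CSV signals hold one numeric sample per line ('#' comments allowed, or a
single named header line); annotations are TSV ``index<TAB>seconds``.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np

from .records import BeatAnnotations, SignalRecord

PathLike = Union[str, os.PathLike]


def read_signal_csv(path: PathLike, fs: float, modality: str, label: str = "") -> SignalRecord:
    """Read a one-sample-per-line text signal.

    Lines starting with '#' are skipped. A single non-numeric first line is
    tolerated as a column header; any other non-numeric row raises a
    ``ValueError`` naming the offending line number.
    """
    if not (fs > 0):
        raise ValueError(f"sampling rate must be positive, got {fs}")
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            # allow "t,v" style rows: take the last comma-separated field
            field = line.split(",")[-1].strip()
            try:
                values.append(float(field))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # named column header
                raise ValueError(
                    f"{os.fspath(path)}: line {lineno} is not numeric: {line!r}"
                ) from None
    if len(values) < 2:
        raise ValueError(f"{os.fspath(path)}: needs at least 2 samples, found {len(values)}")
    return SignalRecord(np.asarray(values), fs=fs, modality=modality,
                        label=label or os.path.basename(os.fspath(path)))


def write_signal_csv(path: PathLike, rec: SignalRecord) -> None:
    """Write a record as one sample per line with a '#' metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs} modality={rec.modality} label={rec.label}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def write_annotations(path: PathLike, ann: BeatAnnotations) -> None:
    """Write beats as TSV ``index<TAB>seconds`` (seconds to 6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# beat annotations: sample_index\ttime_s (fs={ann.fs} Hz)\n")
        for idx in ann.indices:
            fh.write(f"{int(idx)}\t{idx / ann.fs:.6f}\n")


def read_annotations(path: PathLike, fs: float) -> BeatAnnotations:
    """Read a TSV annotation file written by :func:`write_annotations`."""
    indices: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                indices.append(int(line.split("\t")[0]))
            except ValueError:
                raise ValueError(
                    f"{os.fspath(path)}: line {lineno} is not an annotation row: {line!r}"
                ) from None
    return BeatAnnotations(np.asarray(indices, dtype=np.int64), fs=fs)
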