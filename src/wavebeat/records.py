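"""Core containers: signals and beat annotations.

All sample positions are 0-based integers; a position ``i`` corresponds to
time ``i / fs`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("ecg", "ppg", "dppg")


@dataclass
class SignalRecord:
    """A uniformly sampled single-channel physiological time series.

    Parameters
    ----------
    samples : array_like
        Signal values in arbitrary amplitude units (e.g. mV).
    fs : float
        Sampling rate in Hz; must be positive.
    modality : {'ecg', 'ppg', 'dppg'}
        What the samples represent. ``dppg`` is the first derivative of a
        photoplethysmogram, the ECG-like signal derived from it.
    label : str
        Free-text identifier (record name, channel, ...).
    """

    samples: np.ndarray
    fs: float
    modality: str
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a signal needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatAnnotations:
    """Sorted beat sample positions (detector output or reference truth)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.indices.size:
            if self.indices[0] < 0:
                raise ValueError("beat indices must be nonnegative")
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("beat indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    def times(self) -> np.ndarray:
        """Beat times in seconds (index / fs)."""
        return self.indices / self.fs
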