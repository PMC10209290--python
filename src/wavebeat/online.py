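"""Buffered online beat detection.

The stream is processed over a sliding window (default 7.5 s, shifted every
750 ms). Each window is split, oldest to newest, into *processed*, *active*
and *shift* zones; the full offline pipeline runs on the window but only
beats falling in the 750 ms active zone are emitted. The processed zone
gives the envelopes left context, the shift zone right context, so the
adaptive threshold is well fitted where beats are confirmed. With a 7.5 s
window a subject at 40 BPM still puts at least 5 beats in every window.

Processing cadence is data-driven (every ``shift_s`` of new samples), so the
emitted beat sequence is a pure function of the sample stream — chunk sizes
do not matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detector import DetectorConfig, detect, min_sep_samples
from .records import BeatAnnotations, SignalRecord

log = logging.getLogger(__name__)


@dataclass
class OnlineConfig:
    """Sliding-buffer geometry, in seconds."""

    window_s: float = 7.5
    shift_s: float = 0.75
    active_s: float = 0.75

    def __post_init__(self) -> None:
        if min(self.window_s, self.shift_s, self.active_s) <= 0:
            raise ValueError("all zone lengths must be positive")
        if self.window_s < self.active_s + self.shift_s:
            raise ValueError("window must cover the active and shift zones")

    @property
    def processed_s(self) -> float:
        return self.window_s - self.active_s - self.shift_s


def min_beats_per_window(hr_bpm: float, config: OnlineConfig | None = None) -> int:
    """Guaranteed beat count per buffer at a steady heart rate.

    A window of ``window_s`` seconds holds at least
    ``floor(window_s / (60 / hr_bpm))`` beats — 5 at 40 BPM with the
    default 7.5 s buffer, which is what sizes the buffer: the envelopes
    need several beats to fit the amplitude trend.
    """
    cfg = config or OnlineConfig()
    return int(cfg.window_s / (60.0 / hr_bpm))


class OnlineDetector:
    """Streaming wrapper around :func:`wavebeat.detector.detect`.

    Push sample chunks with :meth:`push`; each call returns the beats newly
    confirmed in the active zone as absolute sample indices. Call
    :meth:`flush` once at end of stream to confirm the tail.
    """

    def __init__(
        self,
        fs: float,
        modality: str = "ecg",
        config: OnlineConfig | None = None,
        detector: DetectorConfig | None = None,
    ) -> None:
        self.fs = float(fs)
        self.modality = modality
        self.config = config or OnlineConfig()
        self.detector = detector or DetectorConfig()
        self._window = int(round(self.config.window_s * fs))
        self._shift = int(round(self.config.shift_s * fs))
        self._active = int(round(self.config.active_s * fs))
        self._min_sep = min_sep_samples(fs, self.detector.min_sep_s)
        self._buffer = np.empty(0)
        self._buffer_start = 0  # absolute index of buffer[0]
        self._n_total = 0
        self._next_end = self._window  # absolute end of the next window to run
        self._emitted: list[int] = []
        self._flushed = False

    @property
    def emitted(self) -> np.ndarray:
        """All beats confirmed so far (absolute indices, increasing)."""
        return np.asarray(self._emitted, dtype=np.int64)

    def _run_window(self, start: int, end: int, active_lo: int, active_hi: int) -> list[int]:
        """Detect on absolute span [start, end); emit beats in [active_lo, active_hi)."""
        seg = self._buffer[start - self._buffer_start : end - self._buffer_start]
        if seg.size < 2:
            return []
        try:
            rec = SignalRecord(seg, fs=self.fs, modality=self.modality)
            beats = detect(rec, self.detector).indices + start
        except ValueError:
            return []  # window degenerate (e.g. constant tail)
        fresh: list[int] = []
        for b in beats:
            b = int(b)
            if not active_lo <= b < active_hi:
                continue
            if self._emitted and b - self._emitted[-1] < self._min_sep:
                continue  # same beat re-found by an overlapping window
            self._emitted.append(b)
            fresh.append(b)
        return fresh

    def push(self, chunk) -> list[int]:
        """Append samples; return beats newly confirmed in the active zone."""
        chunk = np.asarray(chunk, dtype=float).ravel()
        if chunk.size:
            self._buffer = np.concatenate([self._buffer, chunk])
            self._n_total += chunk.size
        out: list[int] = []
        while self._n_total >= self._next_end:
            end = self._next_end
            start = end - self._window
            active_hi = end - self._shift
            active_lo = active_hi - self._active
            out += self._run_window(start, end, active_lo, active_hi)
            self._next_end += self._shift
            # drop samples no window will need again
            keep_from = self._next_end - self._window
            if keep_from > self._buffer_start:
                self._buffer = self._buffer[keep_from - self._buffer_start :]
                self._buffer_start = keep_from
        return out

    def flush(self) -> list[int]:
        """Process the final partial window once; idempotent."""
        if self._flushed or self._n_total < 2:
            self._flushed = True
            return []
        self._flushed = True
        end = self._n_total
        start = max(self._buffer_start, end - self._window)
        if end - start >= self._window:
            # full window: confirm the remaining active + shift span
            active_lo = end - self._shift - self._active
        else:
            # stream shorter than one window: confirm everything we can
            active_lo = start
        return self._run_window(start, end, active_lo, end)

    def annotations(self) -> BeatAnnotations:
        return BeatAnnotations(self.emitted, fs=self.fs)


def detect_online(
    rec: SignalRecord,
    chunk_s: float = 0.25,
    config: OnlineConfig | None = None,
    detector: DetectorConfig | None = None,
) -> BeatAnnotations:
    """Convenience: stream a whole record through the online detector."""
    det = OnlineDetector(rec.fs, rec.modality, config, detector)
    step = max(1, int(round(chunk_s * rec.fs)))
    for i in range(0, len(rec), step):
        det.push(rec.samples[i : i + step])
    det.flush()
    return det.annotations()
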