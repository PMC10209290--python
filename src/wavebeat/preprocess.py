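"""PPG-to-ECG-like preprocessing.

A photoplethysmogram is converted to its first derivative (dPPG), whose
positive bells line up with QRS complexes, then band-limited with a 30 Hz
zero-phase low-pass. ECG records pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .records import SignalRecord

log = logging.getLogger(__name__)

LOWPASS_CUTOFF_HZ = 30.0
LOWPASS_ORDER = 4


def first_difference(rec: SignalRecord) -> SignalRecord:
    """Forward first difference of a PPG record (length-preserving).

    ``out[n] = x[n+1] - x[n]``; the last sample is replicated so the output
    keeps the input length. Returns a ``dppg`` record.
    """
    if rec.modality != "ppg":
        raise ValueError(f"first_difference expects a ppg record, got {rec.modality!r}")
    d = np.empty_like(rec.samples)
    d[:-1] = np.diff(rec.samples)
    d[-1] = d[-2]
    return replace(rec, samples=d, modality="dppg")


def lowpass_30hz(rec: SignalRecord) -> SignalRecord:
    """Zero-phase 4th-order Butterworth low-pass at 30 Hz (unit DC gain).

    If the sampling rate puts 30 Hz at or above Nyquist (fs <= 60), the
    filter is skipped with a warning: the band is already limited.
    """
    if rec.fs <= 2 * LOWPASS_CUTOFF_HZ:
        log.warning("fs=%g Hz <= %g Hz: 30 Hz low-pass skipped (already band-limited)",
                    rec.fs, 2 * LOWPASS_CUTOFF_HZ)
        return replace(rec, samples=rec.samples.copy())
    sos = butter(LOWPASS_ORDER, LOWPASS_CUTOFF_HZ, btype="low", fs=rec.fs, output="sos")
    y = sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=y)


def prepare_input(rec: SignalRecord) -> SignalRecord:
    """Detector front-end: ECG is passed through; PPG becomes filtered dPPG."""
    if rec.modality == "ecg":
        return rec
    if rec.modality == "ppg":
        return lowpass_30hz(first_difference(rec))
    raise ValueError(f"cannot prepare modality {rec.modality!r} (expected ecg or ppg)")
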