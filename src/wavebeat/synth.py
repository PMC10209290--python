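"""Synthetic ECG and PPG with exact beat ground truth.

The generator emulates the features the detector has to cope with: a
quasi-periodic train of narrow biphasic QRS-like complexes with beat-to-beat
amplitude variability, broader P/T-like low-frequency bumps, sinusoidal
baseline wander, and additive white noise. The PPG variant is a slow
asymmetric pulse (fast ~150 ms systolic rise, slow decay) whose first
derivative shows one dominant positive bell per beat, mirroring the
structural similarity between dPPG and ECG.

Ground truth: ECG truth is the QRS template center; PPG truth is the
steepest-ascent sample of each pulse, which is where dPPG peaks and where a
detector working on dPPG is expected to fire.

All randomness comes from ``numpy.random.default_rng(seed)``, so records
are bit-reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import BeatAnnotations, SignalRecord


@dataclass
class SynthConfig:
    """Study conditions for one synthetic record.

    fs : sampling rate, Hz (>= 40).
    duration_s : record length, s.
    hr_bpm : mean heart rate, beats/min (30..240).
    hr_sd_s : SD of the inter-beat interval, s (heart-rate variability).
        ``None`` (the default) uses ``0.06 * rr**2`` with ``rr`` the mean
        interval in seconds — about 44 ms at 70 BPM, 7 ms at 180 BPM —
        mirroring the cycle-length dependence of real HRV, which shrinks
        sharply under the sympathetic drive of high heart rates.
    amp_cv : coefficient of variation of per-beat amplitudes.
    noise_sd : white-noise SD relative to the nominal QRS amplitude.
    wander_amp : baseline-wander amplitude relative to the QRS amplitude.
    wander_hz : wander frequency, Hz (respiratory-range default 0.3).
    seed : RNG seed.
    """

    fs: float = 250.0
    duration_s: float = 60.0
    hr_bpm: float = 70.0
    hr_sd_s: float | None = None
    amp_cv: float = 0.10
    noise_sd: float = 0.05
    wander_amp: float = 0.20
    wander_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 40:
            raise ValueError(f"fs must be >= 40 Hz, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 30 <= self.hr_bpm <= 240:
            raise ValueError(f"hr_bpm must be in [30, 240], got {self.hr_bpm}")
        if self.hr_sd_s is None:
            self.hr_sd_s = 0.06 * (60.0 / self.hr_bpm) ** 2
        if min(self.hr_sd_s, self.amp_cv, self.noise_sd,
               self.wander_amp, self.wander_hz) < 0:
            raise ValueError("variability parameters must be nonnegative")


def default_ecg_config(**overrides) -> SynthConfig:
    """Study conditions for synthetic ECG: 2% white noise (a clean Holter
    recording, ~34 dB broadband SNR), 20% baseline wander, 10%
    beat-amplitude variation, cycle-length-dependent interval jitter."""
    kw = dict(noise_sd=0.02)
    kw.update(overrides)
    return SynthConfig(**kw)


def default_ppg_config(**overrides) -> SynthConfig:
    """Study conditions for synthetic PPG.

    White sensor noise is set at 0.2% of the pulse amplitude — the
    broadband noise floor of a laboratory-grade transmissive finger PPG,
    whose front-ends oversample and average heavily; the dominant
    real-world disturbances (motion artifacts) are outside this
    generator's scope. Broadband noise costs PPG detection far more than
    the same relative level costs ECG, because the derivative step that
    makes PPG QRS-like also tilts the noise spectrum upward — which is
    why the pipeline low-passes dPPG at 30 Hz.
    """
    kw = dict(noise_sd=0.002)
    kw.update(overrides)
    return SynthConfig(**kw)


#: Shortest allowed inter-beat interval, s; keeps truth compatible with the
#: detector's 300 ms minimum-separation assumption (HR > 200 BPM is outside
#: the method's intended range).
MIN_INTERVAL_S = 0.3

_EDGE_S = 0.25  # keep beat morphology clear of the record edges


def beat_times(cfg: SynthConfig) -> BeatAnnotations:
    """Beat sample indices: cumulative jittered inter-beat intervals.

    Intervals are ``max(0.3 s, Normal(60/hr_bpm, hr_sd_s))``; the train is
    truncated so complete beat shapes fit inside the record.
    """
    rng = np.random.default_rng(cfg.seed)
    mean_rr = 60.0 / cfg.hr_bpm
    n_max = int(np.ceil(cfg.duration_s / MIN_INTERVAL_S)) + 2
    intervals = np.maximum(MIN_INTERVAL_S,
                           rng.normal(mean_rr, cfg.hr_sd_s, size=n_max))
    t = np.cumsum(intervals)
    t = t[t < cfg.duration_s - _EDGE_S]
    idx = np.unique(np.round(t * cfg.fs).astype(np.int64))
    return BeatAnnotations(idx, fs=cfg.fs)


def _beat_amplitudes(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    # clip 3 sigma below the mean so amplitudes stay positive
    return np.maximum(1.0 - 3.0 * cv, 1.0 + cv * rng.standard_normal(n))


def _add_bump(sig: np.ndarray, center: float, amp: float, sigma_s: float, fs: float) -> None:
    half = int(np.ceil(4 * sigma_s * fs))
    c = int(round(center))
    lo, hi = max(0, c - half), min(sig.size, c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) - center) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * (t / sigma_s) ** 2)


def _add_qrs(sig: np.ndarray, center: float, amp: float, fs: float,
             width_s: float = 0.012) -> None:
    """R-dominant biphasic complex, ~90 ms support.

    A tall narrow R-like Gaussian followed by a smaller, slightly broader
    S-like downward deflection — the usual lead-II morphology, whose
    band-passed absolute value has one dominant lobe at the R peak.
    """
    half = int(np.ceil(0.045 * fs))
    c = int(round(center))
    lo, hi = max(0, c - half), min(sig.size, c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) - center) / fs
    r_wave = np.exp(-0.5 * (t / width_s) ** 2)
    s_wave = -0.35 * np.exp(-0.5 * ((t - 1.8 * width_s) / (1.3 * width_s)) ** 2)
    sig[lo:hi] += amp * (r_wave + s_wave)


def synth_ecg(cfg: SynthConfig) -> tuple[SignalRecord, BeatAnnotations]:
    """Synthetic single-lead ECG and its beat truth (QRS centers)."""
    truth = beat_times(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = int(round(cfg.duration_s * cfg.fs))
    sig = np.zeros(n)
    amps = _beat_amplitudes(rng, len(truth), cfg.amp_cv)
    for idx, a in zip(truth.indices, amps):
        _add_qrs(sig, float(idx), a, cfg.fs)
        _add_bump(sig, idx - 0.16 * cfg.fs, 0.15 * a, 0.025, cfg.fs)  # P-like
        _add_bump(sig, idx + 0.26 * cfg.fs, 0.30 * a, 0.06, cfg.fs)   # T-like
    t = np.arange(n) / cfg.fs
    sig += cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_hz * t)
    sig += cfg.noise_sd * rng.standard_normal(n)
    rec = SignalRecord(sig, fs=cfg.fs, modality="ecg",
                       label=f"synth-ecg-{cfg.hr_bpm:g}bpm-seed{cfg.seed}")
    return rec, truth


def _ppg_pulse(fs: float, rise_s: float = 0.15, decay_s: float = 0.30):
    """One unit pulse: fast sigmoid systolic rise, slow exponential decay.

    Returns the template and the offset (samples) of its steepest ascent,
    the point used as beat truth.
    """
    half = int(np.ceil(1.2 * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    rise = 1.0 / (1.0 + np.exp(-t / (rise_s / 6)))
    decay = np.exp(-np.maximum(t, 0.0) / decay_s)
    pulse = rise * decay
    pulse -= pulse[0]
    steepest = int(np.argmax(np.diff(pulse))) - half
    return pulse, half, steepest


def synth_ppg(cfg: SynthConfig) -> tuple[SignalRecord, BeatAnnotations]:
    """Synthetic PPG and its beat truth (steepest-ascent samples)."""
    anchors = beat_times(cfg)  # pulse onsets
    rng = np.random.default_rng(cfg.seed + 2)
    n = int(round(cfg.duration_s * cfg.fs))
    sig = np.zeros(n)
    pulse, half, steepest = _ppg_pulse(cfg.fs)
    amps = _beat_amplitudes(rng, len(anchors), cfg.amp_cv)
    truth_idx = []
    for idx, a in zip(anchors.indices, amps):
        c = int(idx)
        lo, hi = c - half, c + half + 1
        s_lo, s_hi = max(0, lo), min(n, hi)
        sig[s_lo:s_hi] += a * pulse[s_lo - lo : pulse.size - (hi - s_hi)]
        truth_idx.append(c + steepest)
    t = np.arange(n) / cfg.fs
    # wander and noise scaled to the pulse amplitude (unit) like the ECG case
    sig += cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_hz * t)
    sig += cfg.noise_sd * rng.standard_normal(n)
    rec = SignalRecord(sig, fs=cfg.fs, modality="ppg",
                       label=f"synth-ppg-{cfg.hr_bpm:g}bpm-seed{cfg.seed}")
    truth = BeatAnnotations(np.unique(np.asarray(truth_idx, dtype=np.int64)), fs=cfg.fs)
    return rec, truth
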