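"""Beat detection from |cQRS| by iterated peak selection and dual upper
envelopes.

The stages, run in order by :func:`detect`:

1. All local maxima of |cQRS| (``P_A``/``L_A``).
2. Greedy minimum-separation selection: repeatedly keep the highest
   remaining maximum and drop everything closer than 300 ms, giving the
   candidate peaks ``P_C``/``L_C``.
3. Three augmentation passes: remove the already-selected peaks from the
   pool, interpolate the rest into an intermediate signal *midSig*
   (shape-preserving cubic Hermite), and collect midSig's own
   min-separation maxima (``P_ms``/``L_ms``) into the growing anchor set
   ``aux``.
4. Two upper envelopes — one through the local maxima of the candidate
   magnitudes ``P_C`` (tracking beat amplitudes), one from the final-pass
   ``P_ms`` (tracking the secondary-maxima floor) — are averaged into an
   adaptive threshold; every candidate peak strictly above the average is
   a beat.

Every stage is positively homogeneous and the threshold is relative, so the
detector is invariant to amplitude scaling; discarding the wavelet smooth
makes it insensitive to DC offset and baseline wander.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .preprocess import prepare_input
from .records import BeatAnnotations, SignalRecord
from .wavelet import MIN_FS, QRS_BAND, WAVELET, enhance

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Tunables of the detector, with the documented defaults.

    min_sep_s : minimum peak separation in seconds (300 ms).
    n_iter : number of candidate-augmentation passes (3).
    qrs_band : frequency interval of the QRS complex in Hz.
    wavelet : mother wavelet name.
    classify_augmented : threshold the augmented anchor set instead of the
        original candidate peaks (alternative reading; off by default).
    edge_guard : drop a first/last beat whose |cQRS| magnitude is under half
        its neighbor's. The envelopes are extrapolated flat outside their
        outermost anchors, so the record edges are where spurious
        low-amplitude detections occur; this guard removes them.
    """

    min_sep_s: float = 0.3
    n_iter: int = 3
    qrs_band: tuple[float, float] = QRS_BAND
    wavelet: str = WAVELET
    classify_augmented: bool = False
    edge_guard: bool = True


@dataclass
class PeakSet:
    """Parallel peak magnitudes ``P`` and sample locations ``L``."""

    P: np.ndarray
    L: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.L = np.asarray(self.L, dtype=np.int64)
        if self.P.shape != self.L.shape or self.P.ndim != 1:
            raise ValueError("P and L must be 1-D and the same length")
        if self.L.size and np.any(np.diff(self.L) <= 0):
            raise ValueError("peak locations must be strictly increasing")

    def __len__(self) -> int:
        return self.P.size


@dataclass
class EnvelopeSet:
    """Two full-length upper envelopes and their pointwise mean."""

    env_c: np.ndarray
    env_ms: np.ndarray
    mean_env: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mean_env is None:
            self.mean_env = (self.env_c + self.env_ms) / 2.0
        if not (len(self.env_c) == len(self.env_ms) == len(self.mean_env)):
            raise ValueError("envelope components must share one length")


def local_maxima(x: np.ndarray, fs: float) -> PeakSet:
    """All strict local maxima of ``x``; plateaus yield their first sample.

    Endpoints are never maxima. Signals shorter than 3 samples have none.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return PeakSet(np.empty(0), np.empty(0, dtype=np.int64), fs)
    _, props = find_peaks(x, plateau_size=1)
    loc = props["left_edges"].astype(np.int64)
    return PeakSet(x[loc], loc, fs)


def min_sep_samples(fs: float, min_sep_s: float = 0.3) -> int:
    return int(round(min_sep_s * fs))


def min_separation_select(peaks: PeakSet, min_sep_s: float = 0.3) -> PeakSet:
    """Greedy highest-first selection with a minimum separation.

    Repeatedly take the highest remaining peak (ties: earliest index) and
    eliminate every remaining peak strictly closer than
    ``round(min_sep_s * fs)`` samples. Equivalent to keeping a peak iff no
    already-kept (higher or earlier-equal) peak lies within the exclusion
    distance. Survivors are pairwise >= the separation.
    """
    d = min_sep_samples(peaks.fs, min_sep_s)
    n = len(peaks)
    if n == 0:
        return peaks
    order = np.lexsort((peaks.L, -peaks.P))  # height desc, then index asc
    keep = np.zeros(n, dtype=bool)
    kept_locs: list[int] = []
    for i in order:
        li = int(peaks.L[i])
        if all(abs(li - lk) >= d for lk in kept_locs):
            keep[i] = True
            kept_locs.append(li)
    return PeakSet(peaks.P[keep], peaks.L[keep], peaks.fs)


def _interp_full(L: np.ndarray, P: np.ndarray, length: int) -> np.ndarray:
    """Shape-preserving cubic Hermite interpolant through (L, P), evaluated
    on every sample 0..length-1 and held constant outside the anchor span."""
    t = np.arange(length)
    y = PchipInterpolator(L, P)(np.clip(t, L[0], L[-1]))
    return np.asarray(y, dtype=float)


def augment_candidates(
    pa: PeakSet,
    pc: PeakSet,
    length: int,
    n_iter: int = 3,
    min_sep_s: float = 0.3,
) -> tuple[PeakSet, PeakSet]:
    """Iteratively grow the candidate anchor set from the non-selected maxima.

    Starting from ``aux = pc``, each of the ``n_iter`` passes (a) removes
    every ``aux`` member from a working copy of ``pa``, (b) interpolates the
    remaining maxima into *midSig* over the full signal span, (c) takes
    midSig's local maxima at the minimum separation, discarding any at a
    position already in ``aux``, and (d) merges the survivors into ``aux``
    in temporal order. Successive passes therefore collect progressively
    lower tiers of maxima, and the last tier anchors the second envelope
    near the noise/secondary-lobe level.

    Returns the final ``aux`` and the last pass's midSig maxima ``P_ms``.
    If fewer than two anchors remain for interpolation the iteration stops
    early with a warning.
    """
    fs = pa.fs
    aux_L = list(int(v) for v in pc.L)
    aux_P = list(float(v) for v in pc.P)
    pms = PeakSet(np.empty(0), np.empty(0, dtype=np.int64), fs)
    work_L, work_P = pa.L.copy(), pa.P.copy()
    for it in range(n_iter):
        drop = np.isin(work_L, np.asarray(aux_L, dtype=np.int64))
        work_L, work_P = work_L[~drop], work_P[~drop]
        if work_L.size < 2:
            log.warning("augmentation pass %d: only %d free maxima left, stopping",
                        it + 1, work_L.size)
            break
        mid_sig = _interp_full(work_L, work_P, length)
        cand = min_separation_select(local_maxima(mid_sig, fs), min_sep_s)
        if aux_L:
            fresh = ~np.isin(cand.L, np.asarray(aux_L, dtype=np.int64))
            cand = PeakSet(cand.P[fresh], cand.L[fresh], fs)
        pms = cand
        merged = sorted(zip(aux_L + cand.L.tolist(), aux_P + cand.P.tolist()))
        aux_L = [l for l, _ in merged]
        aux_P = [p for _, p in merged]
    aux = PeakSet(np.asarray(aux_P), np.asarray(aux_L, dtype=np.int64), fs)
    return aux, pms


def _upper_envelope(peaks: PeakSet, length: int) -> np.ndarray:
    """Envelope through the local maxima of a peak-magnitude sequence.

    With fewer than two such maxima the envelope degenerates to the constant
    maximum of the available magnitudes (0 for an empty set), so short or
    sparse windows degrade instead of failing.
    """
    if len(peaks) == 0:
        log.warning("empty peak set: envelope degenerates to 0")
        return np.zeros(length)
    seq_max = local_maxima(peaks.P, peaks.fs)  # maxima of the magnitude sequence
    anchor_L = peaks.L[seq_max.L]
    anchor_P = peaks.P[seq_max.L]
    if anchor_L.size < 2:
        const = float(np.max(peaks.P))
        log.warning("fewer than 2 envelope anchors: constant envelope %.4g", const)
        return np.full(length, const)
    return _interp_full(anchor_L, anchor_P, length)


def build_envelopes(pc: PeakSet, pms: PeakSet, length: int) -> EnvelopeSet:
    """The two upper envelopes and their mean, the adaptive threshold.

    ``env_c`` interpolates the local maxima of the candidate magnitudes
    ``P_C``; ``env_ms`` does the same for the midSig maxima ``P_ms`` and,
    being defined on the full sample axis, is in particular defined at every
    candidate location ``L_C``. The threshold is their pointwise average.
    """
    for ps in (pc, pms):
        if len(ps) and int(ps.L[-1]) >= length:
            raise ValueError("peak location beyond signal length")
    env_c = _upper_envelope(pc, length)
    env_ms = _upper_envelope(pms, length)
    return EnvelopeSet(env_c=env_c, env_ms=env_ms)


def classify_beats(pc: PeakSet, env: EnvelopeSet) -> BeatAnnotations:
    """Candidate peaks strictly above the mean envelope are heartbeats."""
    if len(pc) and int(pc.L[-1]) >= len(env.mean_env):
        raise ValueError("envelope does not cover all candidate locations")
    above = pc.P > env.mean_env[pc.L]
    return BeatAnnotations(pc.L[above], fs=pc.fs)


def detect(rec: SignalRecord, config: DetectorConfig | None = None) -> BeatAnnotations:
    """Run the full offline pipeline on an ECG or PPG record.

    Returns beat locations as |cQRS| peak sample indices; all returned
    beats are at least ``round(0.3 * fs)`` samples apart.
    """
    cfg = config or DetectorConfig()
    if rec.fs < MIN_FS:
        raise ValueError(
            f"fs={rec.fs} Hz is below the minimum {MIN_FS:g} Hz needed to "
            f"resolve the {cfg.qrs_band} Hz QRS band"
        )
    prepared = prepare_input(rec)
    cqrs = enhance(prepared, band=cfg.qrs_band, wavelet=cfg.wavelet)
    pa = local_maxima(cqrs, rec.fs)
    if len(pa) == 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), fs=rec.fs)
    pc = min_separation_select(pa, cfg.min_sep_s)
    aux, pms = augment_candidates(pa, pc, len(cqrs), cfg.n_iter, cfg.min_sep_s)
    env = build_envelopes(pc, pms, len(cqrs))
    target = aux if cfg.classify_augmented else pc
    beats = classify_beats(target, env)
    if cfg.edge_guard and len(beats) >= 2:
        mag = dict(zip(target.L.tolist(), target.P.tolist()))
        idx = beats.indices
        lo = 1 if mag[int(idx[0])] < 0.5 * mag[int(idx[1])] else 0
        hi = -1 if mag[int(idx[-1])] < 0.5 * mag[int(idx[-2])] else None
        beats = BeatAnnotations(idx[lo:hi], fs=beats.fs)
    return beats
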