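"""QRS enhancement via the maximal-overlap (undecimated) wavelet transform.

The signal is decomposed with a Symlet-4 mother wavelet into
``N = floor(log2(fs))`` same-length detail levels. Detail level ``j`` has the
nominal dyadic passband ``(fs/2^(j+1), fs/2^j)`` Hz; the levels whose band
overlaps the QRS interval (5, 20) Hz are kept, everything else (including the
smooth, which carries baseline wander and DC) is zeroed, and the absolute
value of the inverse transform is the QRS-enhanced signal |cQRS|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .records import SignalRecord

log = logging.getLogger(__name__)

#: Frequency interval (Hz) associated with QRS complexes.
QRS_BAND = (5.0, 20.0)
#: Symlet with 4 vanishing moments: nearly symmetric, QRS-like shape.
WAVELET = "sym4"
#: Smallest sampling rate for which the QRS band is below Nyquist.
MIN_FS = 2 * QRS_BAND[1]


def min_window_s(band: tuple[float, float] = QRS_BAND) -> float:
    """Shortest record resolving the bottom of the QRS band.

    Spectral resolution 1/T must reach the band's lower edge, so
    ``T >= 1 / f_lo`` (0.2 s for the 5 Hz default). A record shorter than
    this cannot separate the QRS band from slower waves.
    """
    return 1.0 / band[0]


def max_single_beat_bpm(band: tuple[float, float] = QRS_BAND) -> float:
    """Heart rate at which one beat fits in the minimum-resolution window.

    ``60 / min_window_s`` = 300 BPM for the default band: only ventricular
    fibrillation outruns the minimum record length, so in practice any
    record long enough for spectral resolution also contains a beat.
    """
    return 60.0 / min_window_s(band)


def n_levels(fs: float) -> int:
    """Decomposition depth ``floor(log2(fs))`` for a sampling rate in Hz."""
    if fs < 2:
        raise ValueError(f"sampling rate must be >= 2 Hz, got {fs}")
    return int(math.floor(math.log2(fs)))


def level_band(fs: float, j: int) -> tuple[float, float]:
    """Nominal passband (f_lo, f_hi) in Hz of detail level ``j``."""
    if j < 1:
        raise ValueError(f"level must be >= 1, got {j}")
    return fs / 2 ** (j + 1), fs / 2**j


def select_levels(fs: float, n: int, band: tuple[float, float] = QRS_BAND) -> set[int]:
    """Detail levels whose open passband intersects the open QRS band.

    Raises a ``ValueError`` naming the minimum sampling rate when the band
    cannot be covered: the Nyquist frequency must reach the band top, so
    ``fs >= 2 * f_hi`` (40 Hz for the 20 Hz default).
    """
    lo, hi = band
    if fs < 2 * hi:
        raise ValueError(
            f"fs={fs:g} Hz cannot cover the ({lo:g}, {hi:g}) Hz QRS band; "
            f"the minimum supported sampling rate is {2 * hi:g} Hz"
        )
    return {
        j for j in range(1, n + 1)
        if level_band(fs, j)[0] < hi and level_band(fs, j)[1] > lo
    }


@dataclass
class WaveletDecomposition:
    """Undecimated decomposition; every component has the input's length.

    Internally the coefficients live on a reflection-padded axis so the
    inverse transform is free of wrap-around edge artifacts; the public
    ``details``/``smooth`` views are trimmed back to the input span.
    """

    fs: float
    n: int
    wavelet: str
    _coeffs: list = field(repr=False)  # pywt layout: [cA_n, cD_n, ..., cD_1]
    _pad_left: int = field(repr=False)
    _length: int = field(repr=False)

    @property
    def smooth(self) -> np.ndarray:
        return self._coeffs[0][self._pad_left : self._pad_left + self._length]

    def detail(self, j: int) -> np.ndarray:
        if not 1 <= j <= self.n:
            raise ValueError(f"detail level {j} outside 1..{self.n}")
        c = self._coeffs[len(self._coeffs) - j]
        return c[self._pad_left : self._pad_left + self._length]

    @property
    def details(self) -> list[np.ndarray]:
        return [self.detail(j) for j in range(1, self.n + 1)]


def mowt(rec: SignalRecord, n: int | None = None, wavelet: str = WAVELET) -> WaveletDecomposition:
    """Maximal-overlap wavelet transform of a record.

    The depth defaults to ``n_levels(rec.fs)`` and is clamped (with a
    warning) to the deepest level the signal length supports. Reflection
    padding is applied before the transform and trimmed from the public
    views, so boundary coefficients see mirrored data, not wrap-around.
    """
    x = rec.samples
    if n is None:
        n = n_levels(rec.fs)
    filt_len = pywt.Wavelet(wavelet).dec_len
    if len(x) < filt_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {wavelet} filter "
            f"({filt_len} taps)"
        )
    max_n = int(math.floor(math.log2(len(x))))
    if n > max_n:
        log.warning("decomposition depth clamped from %d to %d for a %d-sample signal",
                    n, max_n, len(x))
        n = max_n
    # pad so edges see mirrored signal out to the level-n filter support,
    # then round the total up to a multiple of 2^n as the transform requires
    base = (filt_len - 1) * 2 ** (n - 1)
    block = 2**n
    total = block * math.ceil((len(x) + 2 * base) / block)
    pad_left = base
    pad_right = total - len(x) - pad_left
    xp = pywt.pad(x, (pad_left, pad_right), "reflect")
    coeffs = pywt.swt(xp, wavelet, level=n, trim_approx=True, norm=True)
    return WaveletDecomposition(fs=rec.fs, n=n, wavelet=wavelet, _coeffs=coeffs,
                                _pad_left=pad_left, _length=len(x))


def reconstruct_selected(dec: WaveletDecomposition, levels) -> np.ndarray:
    """Inverse transform keeping only the chosen detail levels.

    The smooth and all unchosen details are zeroed; use :func:`reconstruct`
    with ``include_smooth=True`` for a full inverse.
    """
    return reconstruct(dec, levels, include_smooth=False)


def reconstruct(dec: WaveletDecomposition, levels=None, include_smooth: bool = False) -> np.ndarray:
    """Inverse transform from chosen details, optionally with the smooth."""
    levels = set(range(1, dec.n + 1)) if levels is None else set(levels)
    bad = [j for j in levels if not 1 <= j <= dec.n]
    if bad:
        raise ValueError(f"levels {bad} outside 1..{dec.n}")
    coeffs = [np.zeros_like(c) for c in dec._coeffs]
    if include_smooth:
        coeffs[0] = dec._coeffs[0]
    for j in levels:
        k = len(coeffs) - j
        coeffs[k] = dec._coeffs[k]
    y = pywt.iswt(coeffs, dec.wavelet, norm=True)
    return np.asarray(y)[dec._pad_left : dec._pad_left + dec._length]


def enhance(rec: SignalRecord, band: tuple[float, float] = QRS_BAND,
            wavelet: str = WAVELET) -> np.ndarray:
    """The nonnegative QRS-enhanced signal |cQRS|.

    Absolute value of the band-selected inverse wavelet reconstruction;
    same length as the input. Requires ``rec.fs >= 40`` so some level
    overlaps the QRS band.
    """
    n = n_levels(rec.fs)
    levels = select_levels(rec.fs, n, band)
    dec = mowt(rec, n, wavelet)
    levels = {j for j in levels if j <= dec.n}  # depth may have been clamped
    return np.abs(reconstruct_selected(dec, levels))
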