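"""Beat-by-beat scoring: TP/FP/FN matching and TPR/PPV/ACC.

A detection matches a reference beat when it falls within a time tolerance
(default 150 ms, the conventional beat-by-beat comparison window); matching
is one-to-one. The three percentages are

    TPR = 100 * TP / (TP + FN)      sensitivity to true beats
    PPV = 100 * TP / (TP + FP)      reliability of the detections
    ACC = 100 * TP / (TP + FP + FN) overall agreement

and ACC <= min(TPR, PPV) always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import BeatAnnotations

DEFAULT_TOLERANCE_S = 0.15


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class Metrics:
    """TPR/PPV/ACC percentages; ``None`` marks an undefined ratio."""

    tpr: Optional[float]
    ppv: Optional[float]
    acc: Optional[float]

    def rounded(self, ndigits: int = 3) -> "Metrics":
        rnd = lambda v: None if v is None else round(v, ndigits)
        return Metrics(rnd(self.tpr), rnd(self.ppv), rnd(self.acc))

    def format_row(self) -> str:
        fmt = lambda v: "n/a" if v is None else f"{v:.3f}"
        return f"{fmt(self.tpr)}\t{fmt(self.ppv)}\t{fmt(self.acc)}"


def match(
    detected: BeatAnnotations,
    reference: BeatAnnotations,
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> MatchCounts:
    """One-to-one beat matching within a tolerance.

    Each reference beat, in temporal order, pairs with the nearest unmatched
    detection within ``round(tol_s * fs)`` samples (ties go to the earlier
    detection). Paired beats are TP; leftover detections FP; leftover
    references FN.
    """
    if detected.fs != reference.fs:
        raise ValueError(
            f"annotation sets must share a sampling rate "
            f"({detected.fs} != {reference.fs})"
        )
    tol = int(round(tol_s * detected.fs))
    det = detected.indices
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for r in reference.indices:
        lo = np.searchsorted(det, r - tol, side="left")
        hi = np.searchsorted(det, r + tol, side="right")
        best = -1
        best_dist = tol + 1
        for k in range(lo, hi):
            if used[k]:
                continue
            dist = abs(int(det[k]) - int(r))
            if dist < best_dist:  # strict: ties keep the earlier detection
                best, best_dist = k, dist
        if best >= 0:
            used[best] = True
            tp += 1
    return MatchCounts(tp=tp, fp=int(det.size - tp), fn=int(reference.indices.size - tp))


def metrics(c: MatchCounts) -> Metrics:
    """TPR, PPV and ACC (percent) from match counts; undefined ratios are None."""
    den_tpr = c.tp + c.fn
    den_ppv = c.tp + c.fp
    den_acc = c.tp + c.fp + c.fn
    if den_tpr == 0 and den_ppv == 0:
        raise ValueError("no beats in either annotation set: metrics undefined")
    return Metrics(
        tpr=100.0 * c.tp / den_tpr if den_tpr else None,
        ppv=100.0 * c.tp / den_ppv if den_ppv else None,
        acc=100.0 * c.tp / den_acc if den_acc else None,
    )


def evaluate(
    detected: BeatAnnotations,
    reference: BeatAnnotations,
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> tuple[MatchCounts, Metrics]:
    """Match then score; the usual one-call entry point."""
    c = match(detected, reference, tol_s)
    return c, metrics(c)


def report_tsv(rows: dict[str, tuple[MatchCounts, Metrics]]) -> str:
    """Render ``record -> (counts, metrics)`` as a TSV table (3 decimals)."""
    lines = ["record\ttp\tfp\tfn\ttpr\tppv\tacc"]
    for name, (c, m) in rows.items():
        lines.append(f"{name}\t{c.tp}\t{c.fp}\t{c.fn}\t{m.format_row()}")
    return "\n".join(lines) + "\n"
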