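"""Metric arithmetic on published beat-detector benchmark counts.

The standard beat-level scores are pure functions of the TP/FP/FN tallies:

    TPR = 100 TP / (TP + FN),  PPV = 100 TP / (TP + FP),
    ACC = 100 TP / (TP + FP + FN).

Feeding in the published counts for this detector family (offline and
online variants, ECG and PPG test sets) reproduces the reported
percentages, which is a quick integrity check of any scoring pipeline.
"""

import wavebeat as wb
from wavebeat.evaluation import MatchCounts

ROWS = {
    "offline / PPG": (61387, 289, 69),
    "offline / ECG": (87737, 13, 35),
    "online  / PPG": (61313, 304, 143),
    "online  / ECG": (87739, 16, 33),
}

print(f"{'variant':14s} {'TP':>6s} {'FP':>4s} {'FN':>4s} {'TPR':>8s} {'PPV':>8s} {'ACC':>8s}")
for name, (tp, fp, fn) in ROWS.items():
    m = wb.metrics(MatchCounts(tp, fp, fn))
    print(f"{name:14s} {tp:6d} {fp:4d} {fn:4d} {m.tpr:8.3f} {m.ppv:8.3f} {m.acc:8.3f}")
print("ACC <= min(TPR, PPV) always: one error of either kind costs ACC more.")
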