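# Methods

## Detection model

The detector assumes a single-channel, uniformly sampled signal in which
each heartbeat produces a transient whose energy is concentrated in the
5–20 Hz band: the QRS complex of an ECG, or the systolic-upstroke bell of a
differentiated PPG. It makes no assumption about absolute amplitude,
polarity, baseline level, or slow amplitude trends — those are exactly the
things the envelope threshold adapts to. It does assume beats are at least
300 ms apart (heart rate ≤ 200 BPM); above that, the minimum-separation rule
starts suppressing genuine beats, which is the method's intended operating
limit.

### Stage 1 — band-selected wavelet reconstruction

The undecimated (maximal-overlap) transform is used rather than the
decimated one so every level keeps the input's length and time resolution.
It is computed with PyWavelets' à-trous algorithm in its normalized form
(`swt(..., norm=True)`, filters rescaled by √2 per level), which is the
standard maximal-overlap construction. The Symlet-4 wavelet is fixed by
default — nearly symmetric, 8 taps, QRS-like shape — but exposed in
`DetectorConfig.wavelet` for experimentation.

The depth is `N = ⌊log2(Fs)⌋`, clamped with a warning to `⌊log2(length)⌋`
for records too short to support it. Level selection keeps every detail
level whose open nominal passband `(Fs/2^(j+1), Fs/2^j)` intersects the open
interval (5, 20) Hz. Strict containment of the whole band in one dyadic
level is impossible in general, so intersection is the only workable
reading; it guarantees a non-empty cover for every `Fs ≥ 40`. Below 40 Hz
the Nyquist frequency cannot reach the top of the band and `select_levels`
raises. The smooth is never included: it carries DC and baseline wander.

Boundary handling: the signal is reflection-padded out to the level-`N`
filter support (and to a multiple of `2^N`, as the à-trous algorithm
requires) before the transform, and trimmed after inversion. Circular
convolution without padding would wrap the record's ends into each other
and fabricate edge spikes.

### Stage 2 — candidate peaks

Local maxima use the strict definition with a first-sample plateau rule,
so ties cannot produce duplicate or shifted candidates. The greedy
minimum-separation rule deletes peaks *strictly* closer than
`round(0.3·Fs)` samples to a kept peak — survivors may be exactly 300 ms
apart — and breaks magnitude ties toward the earlier index, making the
selection deterministic. An equivalent one-pass formulation (process peaks
in height-then-index order, keep those not excluded by an earlier keeper)
is what the implementation uses; the test suite checks it against a literal
delete-around-the-highest oracle on a thousand random instances.

### Stage 3 — augmentation and the intermediate signal

Each of the three passes interpolates the *not yet collected* local maxima
with a shape-preserving piecewise-cubic Hermite polynomial (PCHIP —
monotone segments cannot overshoot, so the interpolant behaves like an
envelope rather than a ringing polynomial), evaluates it over the whole
record (held constant outside the outermost anchors), and harvests its
minimum-separation maxima, discarding any that land on a position already
collected. Because the collected positions are removed from the pool before
interpolating, each pass digs out a strictly lower tier of maxima: pass 1
finds the secondary lobes just below the candidates, pass 3 ends near the
noise floor. The final pass's maxima (`P_ms`) are what the second envelope
is built from — that ordering is what places the second envelope near the
floor rather than near the beats. With fewer than two free anchors the
iteration stops early with a warning rather than failing; short online
windows depend on that.

### Stage 4 — envelopes and classification

The first envelope interpolates the local maxima of the *original*
candidate magnitude sequence `P_C` (not of the augmented set: anchoring on
the augmented set would let the tallest noise peak of every long diastolic
gap become its own anchor and therefore its own threshold, which turns
low-heart-rate records into false-positive showers). The second envelope is
built identically from `P_ms` and evaluated on the full sample axis, hence
defined at every candidate location. A candidate is a beat iff its
magnitude strictly exceeds the pointwise mean of the two envelopes. The
beat timestamp is the `|cQRS|` peak location; no refinement to the raw
signal's extremum is applied.

Outside its outermost anchors each envelope is held constant, which leaves
the record's first and last second thresholded by extrapolation. The edge
guard (`DetectorConfig.edge_guard`, on by default) therefore discards a
first or last detected beat whose magnitude is under half its neighbour's —
spurious edge detections are tiny noise peaks, real edge beats are not.
Degenerate inputs (fewer than two envelope anchors) degrade to a constant
envelope at the maximum available magnitude instead of raising, again for
the benefit of short windows.

### Online operation

The streaming detector buffers `window_s` = 7.5 s and re-runs the full
offline pipeline every `shift_s` = 750 ms of new data, emitting only beats
whose window-relative position falls in the 750 ms *active* zone
`[window − active − shift, window − shift)`. The 6 s *processed* zone gives
the envelopes left context; the *shift* zone gives right context, so the
threshold is never extrapolated where beats are confirmed. Cadence is
data-driven, not wall-clock-driven, which makes the emitted sequence a pure
function of the sample stream: the same samples in any chunking give
identical output (asserted in tests). Cross-window duplicates are
suppressed by the same 300 ms proximity rule the detector itself uses,
since a beat re-found by an overlapping window may move by a sample. At
7.5 s/750 ms a 40 BPM subject still has 5 beats per window, which is the
design margin for the envelope fit; `flush()` processes the final partial
window once so tails are not silently dropped.

## Evaluation

Matching is greedy one-to-one in reference order: each reference beat takes
the nearest unmatched detection within `round(0.15·Fs)` samples, ties to
the earlier detection. 150 ms is the conventional beat-by-beat comparison
window; it is a parameter (`tol_s`) everywhere. TPR, PPV and ACC are
reported to 3 decimals and kept at full precision internally; a zero
denominator yields `None` ("not applicable"), never a silent 0.

## Synthetic study conditions

The generator produces what the detector must survive, with exact truth:

| parameter | default | meaning |
| --- | --- | --- |
| `fs` | 250 Hz | sampling rate (40 Hz minimum) |
| `duration_s` | 60 s | record length |
| `hr_bpm` | 70 | mean heart rate |
| `hr_sd_s` | `0.06·rr²` s | inter-beat-interval SD; ~44 ms at 70 BPM, ~7 ms at 180 BPM |
| `amp_cv` | 0.10 | per-beat amplitude coefficient of variation |
| `noise_sd` | 0.02 (ECG) / 0.002 (PPG) | white-noise SD relative to beat amplitude |
| `wander_amp`, `wander_hz` | 0.20, 0.3 Hz | sinusoidal baseline wander |

Inter-beat intervals are `max(0.3 s, Normal(60/hr, hr_sd_s))`; the floor
keeps truth compatible with the detector's separation assumption. The
jitter default scales with the squared cycle length, mirroring the
physiological collapse of heart-rate variability at high rates — a constant
resting-level jitter at 180 BPM would pile intervals onto the 0.3 s floor,
a rhythm no 300 ms-refractory method can resolve.

The ECG template is an R-dominant biphasic complex (narrow R Gaussian plus
a smaller, delayed S deflection, ~90 ms support) with P- and T-like bumps.
R-dominance matters: a perfectly symmetric biphasic template gives the
rectified enhanced signal two near-equal lobes per beat, and which lobe
wins the greedy selection flips randomly — an artifact no real lead
produces. The PPG pulse is a fast sigmoid systolic rise (~150 ms) times a
slow exponential decay; its first derivative has one dominant positive
bell per beat, and the beat truth is the steepest-ascent sample, which is
where the detector is expected to fire on dPPG.

**Noise floors.** The white-noise defaults are the documented floors at
which the detector holds TPR ≥ 99% and PPV ≥ 99% on 60 s records across
`fs ∈ {128, 250, 360}` Hz × HR ∈ {45, 70, 120, 180} BPM, both modalities.
The two floors differ by an order of magnitude because the PPG derivative
step tilts the noise spectrum upward into the QRS band: broadband noise
costs dPPG detection roughly six times what the same relative level costs
ECG. Measured sensitivity beyond the floors: at 5% ECG noise the only
degradation is ~1 false positive per minute in 45 BPM records at 128 Hz
(extreme-value noise peaks in 1.3 s diastolic gaps clear the second
envelope); at 0.5% PPG noise the 120–180 BPM cells lose 1–2% of beats.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate: arrhythmic morphology (ectopic beats, flutter, fusion),
motion artifacts and electrode pops, colored or power-line noise, dicrotic
notches, and the PPG's blood-pressure-dependent pulse-arrival jitter. The
synthetic results say the algorithm is implemented correctly and behaves as
designed under controlled conditions; they are not a clinical validation.

## Known limitations

- The 300 ms separation bounds usable heart rate at 200 BPM by design.
- At 180 BPM PPG, wavelet-filter interference between pulses 0.33 s apart
  modulates enhanced-signal beat amplitudes by up to ~35%; a beat
  occasionally falls a few percent below the mean-envelope threshold, so a
  small fraction of 60 s records dip to ~98% TPR regardless of noise level.
- Records shorter than ~2 beats cannot anchor envelopes and degrade to a
  constant threshold.
- WFDB support covers format-16, single-segment, single-signal-file records
  and standard MIT annotation coding only; CSV is the first-class path.
- The online detector's output is deterministic in the data, not in wall
  time; real-time scheduling and acquisition latency are out of scope.
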