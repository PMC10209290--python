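"""Peak selection, envelopes, classification and the full offline detector."""

import numpy as np
import pytest

import wavebeat as wb
from wavebeat.detector import (
    EnvelopeSet,
    PeakSet,
    _upper_envelope,
    augment_candidates,
    min_sep_samples,
)


def peaks(P, L, fs=1000.0):
    return PeakSet(np.asarray(P, dtype=float), np.asarray(L, dtype=np.int64), fs)


class TestLocalMaxima:
    @pytest.mark.parametrize(
        "x, P, L",
        [
            ([0, 1, 0, 2, 0], [1, 2], [1, 3]),
            ([0, 1, 2, 3, 4], [], []),          # monotone ramp
            ([0, 1, 1, 0], [1], [1]),           # plateau: first sample wins
            ([5, 0, 5], [], []),                # endpoints are never maxima
        ],
    )
    def test_conventions(self, x, P, L):
        got = wb.local_maxima(np.asarray(x, dtype=float), fs=100)
        assert got.P.tolist() == P and got.L.tolist() == L

    def test_too_short_gives_empty(self):
        assert len(wb.local_maxima(np.array([1.0, 2.0]), fs=100)) == 0


def _reference_greedy(P, L, d):
    """Independent oracle: literal repeated delete-around-the-highest.

    Take the highest remaining peak (earliest on ties), remove every peak
    strictly closer than d samples, repeat until the pool is empty.
    """
    pool = list(zip(L, P))
    kept = []
    while pool:
        best = max(pool, key=lambda lp: (lp[1], -lp[0]))
        kept.append(best)
        pool = [lp for lp in pool if abs(lp[0] - best[0]) >= d]
    return sorted(kept)


class TestMinSeparationSelect:
    def test_greedy_hand_example(self):
        got = wb.min_separation_select(peaks([1.0, 0.5, 0.8], [100, 250, 600]))
        assert got.P.tolist() == [1.0, 0.8] and got.L.tolist() == [100, 600]

    def test_single_peak_and_empty(self):
        one = peaks([2.0], [42])
        got = wb.min_separation_select(one)
        assert got.L.tolist() == [42]
        assert len(wb.min_separation_select(peaks([], []))) == 0

    def test_equal_heights_earlier_wins(self):
        got = wb.min_separation_select(peaks([1.0, 1.0], [500, 600]))
        assert got.L.tolist() == [500]

    def test_survivors_respect_separation(self, rng):
        for _ in range(50):
            n = rng.integers(1, 30)
            L = np.sort(rng.choice(5000, size=n, replace=False))
            got = wb.min_separation_select(peaks(rng.random(n), L, fs=1000))
            if len(got) > 1:
                assert np.diff(got.L).min() >= 300

    def test_matches_brute_force_reference(self, rng):
        d = 300
        for _ in range(300):
            n = int(rng.integers(1, 16))
            L = np.sort(rng.choice(3000, size=n, replace=False)).tolist()
            P = rng.random(n).round(3).tolist()  # rounding provokes ties
            expect = _reference_greedy(P, L, d)
            got = wb.min_separation_select(peaks(P, L, fs=1000), min_sep_s=0.3)
            assert list(zip(got.L.tolist(), got.P.tolist())) == expect


class TestAugmentCandidates:
    def test_no_free_maxima_returns_pc_unchanged(self):
        pa = peaks([1.0, 2.0, 1.5], [100, 500, 900])
        aux, pms = augment_candidates(pa, pa, length=1000)
        assert aux.L.tolist() == pa.L.tolist()
        assert len(pms) == 0

    def test_matches_step_by_step_reference(self, rng):
        # 20 maxima, 5 selected; reference is a literal reading of the
        # four steps using scipy pchip directly
        from scipy.interpolate import PchipInterpolator

        fs, length, d = 100.0, 2000, 30
        L = np.sort(rng.choice(np.arange(10, length - 10), 20, replace=False))
        P = rng.random(20) + 0.2
        pa = peaks(P, L, fs)
        pc = wb.min_separation_select(pa, min_sep_s=0.3)

        aux = sorted(zip(pc.L.tolist(), pc.P.tolist()))
        work = sorted(zip(L.tolist(), P.tolist()))
        last_pms = []
        for _ in range(3):
            aux_locs = {l for l, _ in aux}
            work = [lp for lp in work if lp[0] not in aux_locs]
            if len(work) < 2:
                break
            xs = [l for l, _ in work]
            ys = [p for _, p in work]
            t = np.arange(length)
            mid = PchipInterpolator(xs, ys)(np.clip(t, xs[0], xs[-1]))
            cand = wb.min_separation_select(wb.local_maxima(mid, fs), 0.3)
            fresh = [(l, p) for l, p in zip(cand.L.tolist(), cand.P.tolist())
                     if l not in aux_locs]
            last_pms = fresh
            aux = sorted(aux + fresh)

        got_aux, got_pms = augment_candidates(pa, pc, length)
        assert list(zip(got_aux.L.tolist(), got_aux.P.tolist())) == aux
        assert list(zip(got_pms.L.tolist(), got_pms.P.tolist())) == sorted(last_pms)

    def test_stops_early_when_anchors_run_out(self):
        pa = peaks([1.0, 2.0, 0.5, 1.5], [100, 500, 700, 900])
        pc = wb.min_separation_select(pa)
        aux, _ = augment_candidates(pa, pc, length=1000, n_iter=3)
        assert set(pc.L.tolist()) <= set(aux.L.tolist())


class TestEnvelopes:
    def test_passes_exactly_through_anchors(self):
        pc = peaks([1.0, 3.0, 1.0, 3.0, 1.0], [100, 300, 500, 700, 900])
        env = wb.build_envelopes(pc, pc, length=1000)
        # anchors are the two interior 3.0 maxima of the magnitude sequence
        assert abs(env.env_c[300] - 3.0) < 1e-9
        assert abs(env.env_c[700] - 3.0) < 1e-9

    def test_identical_inputs_give_identical_envelopes(self, rng):
        L = np.sort(rng.choice(2000, 15, replace=False))
        pc = peaks(rng.random(15), L)
        env = wb.build_envelopes(pc, pc, length=2100)
        np.testing.assert_array_equal(env.env_c, env.env_ms)
        np.testing.assert_allclose(env.mean_env, env.env_c)

    def test_mean_is_pointwise_average(self, rng):
        a = peaks(rng.random(12), np.sort(rng.choice(1500, 12, replace=False)))
        b = peaks(rng.random(9), np.sort(rng.choice(1500, 9, replace=False)))
        env = wb.build_envelopes(a, b, length=1600)
        np.testing.assert_allclose(env.mean_env, (env.env_c + env.env_ms) / 2)

    def test_monotone_anchors_no_overshoot(self, rng):
        # shape-preserving cubic Hermite: monotone data -> monotone curve
        for _ in range(20):
            n = int(rng.integers(4, 12))
            L = np.sort(rng.choice(np.arange(10, 990), n, replace=False))
            P = np.sort(rng.random(n))
            curve = _upper_envelope(peaks(P, L), length=1000)
            inner = curve[L[0] : L[-1] + 1]
            assert np.all(np.diff(inner) >= -1e-12)

    def test_degenerate_inputs_become_constant(self):
        env = _upper_envelope(peaks([2.0, 5.0], [100, 200]), length=400)
        np.testing.assert_array_equal(env, np.full(400, 5.0))
        assert np.array_equal(_upper_envelope(peaks([], []), 300), np.zeros(300))


class TestClassify:
    def test_zero_threshold_accepts_everything(self):
        pc = peaks([1.0, 2.0, 0.5], [10, 400, 900])
        env = EnvelopeSet(np.zeros(1000), np.zeros(1000))
        got = wb.classify_beats(pc, env)
        assert got.indices.tolist() == [10, 400, 900]

    def test_threshold_at_max_rejects_everything(self):
        pc = peaks([1.0, 2.0], [10, 400])
        env = EnvelopeSet(np.full(500, 2.0), np.full(500, 2.0))
        assert len(wb.classify_beats(pc, env)) == 0  # strict inequality

    def test_output_is_subset_of_candidates(self, rng):
        L = np.sort(rng.choice(900, 10, replace=False))
        pc = peaks(rng.random(10), L)
        env = EnvelopeSet(np.full(1000, 0.5), rng.random(1000))
        got = wb.classify_beats(pc, env)
        assert set(got.indices.tolist()) <= set(L.tolist())


class TestDetect:
    def test_featureless_signal_has_no_beats(self):
        rec = wb.SignalRecord(np.zeros(2000), fs=128, modality="ecg")
        assert len(wb.detect(rec)) == 0

    def test_amplitude_scale_invariance(self, ecg_record):
        rec, _ = ecg_record
        for a in (0.01, 1000.0):
            scaled = wb.SignalRecord(a * rec.samples, fs=rec.fs, modality="ecg")
            np.testing.assert_array_equal(wb.detect(scaled).indices,
                                          wb.detect(rec).indices)

    def test_dc_offset_invariance(self, ecg_record):
        rec, _ = ecg_record
        shifted = wb.SignalRecord(rec.samples + 500.0, fs=rec.fs, modality="ecg")
        np.testing.assert_array_equal(wb.detect(shifted).indices,
                                      wb.detect(rec).indices)

    def test_minimum_beat_spacing_holds(self, ecg_record, ppg_record):
        for rec, _ in (ecg_record, ppg_record):
            beats = wb.detect(rec)
            assert np.diff(beats.indices).min() >= min_sep_samples(rec.fs)

    @pytest.mark.parametrize("modality", ["ecg", "ppg"])
    def test_recovers_ground_truth_on_study_conditions(self, modality, ecg_record, ppg_record):
        rec, truth = ecg_record if modality == "ecg" else ppg_record
        counts, m = wb.evaluate(wb.detect(rec), truth)
        assert m.tpr >= 99.0 and m.ppv >= 99.0

    def test_low_sampling_rate_rejected(self):
        rec = wb.SignalRecord(np.zeros(200), fs=30, modality="ecg")
        with pytest.raises(ValueError, match="40"):
            wb.detect(rec)
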