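"""Acoustic detection: calls, buzzes, mastication, success, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from batforage import acoustics
from batforage.acoustics import AttackEvent, BuzzEvent, CallSeries


def _tone_burst(fs, freq, dur, amp, decay=0.002):
    """Damped sinusoid with raised-cosine on/off ramps (band-limited, like
    a real mastication transient rather than a hard-edged step)."""
    n = int(dur * fs)
    t = np.arange(n) / fs
    w = amp * np.exp(-t / decay) * np.sin(2 * np.pi * freq * t)
    edge = max(2, int(0.0005 * fs))
    env = np.ones(n)
    env[:edge] = 0.5 - 0.5 * np.cos(np.pi * np.arange(edge) / edge)
    env[-edge:] = env[:edge][::-1]
    return w * env


def _audio_with_calls(fs, call_times, snr_db=20.0, seed=0, chew_specs=()):
    """Synthetic audio: 30 kHz 2 ms call pips at given times plus optional
    (time, freq, amp) transients, over Gaussian noise at the given SNR."""
    rng = np.random.default_rng(seed)
    dur = max(call_times, default=1.0) + 1.0
    amp = 0.4
    audio = rng.normal(0, amp / 10 ** (snr_db / 20), int(dur * fs))
    n = int(0.002 * fs)
    pip = np.sin(2 * np.pi * 30000 * np.arange(n) / fs) * np.hanning(n)
    for tc in call_times:
        i = int(tc * fs)
        audio[i : i + n] += amp * pip[: max(0, len(audio) - i)][: n]
    for tc, freq, a in chew_specs:
        w = _tone_burst(fs, freq, 0.008, a)
        i = int(tc * fs)
        audio[i : i + len(w)] += w[: max(0, len(audio) - i)]
    return audio


class TestDetectCalls:
    def test_silence_gives_empty(self):
        rng = np.random.default_rng(0)
        calls = acoustics.detect_calls(rng.normal(0, 0.005, 94000 * 2), 94000.0)
        assert len(calls) == 0

    def test_100_calls_at_20db_mostly_recovered(self):
        fs = 94000.0
        times = 0.5 + 0.1 * np.arange(100)
        audio = _audio_with_calls(fs, times, snr_db=20.0)
        calls = acoustics.detect_calls(audio, fs)
        mid = times + 0.001  # detector reports the envelope peak (call midpoint)
        d = np.abs(calls.call_times[:, None] - mid[None, :])
        assert (d.min(axis=0) < 0.001).sum() >= 95

    def test_chew_only_audio_gives_no_calls(self):
        fs = 94000.0
        rng = np.random.default_rng(1)
        audio = rng.normal(0, 0.005, int(fs))  # the tag's ambient noise floor
        w = _tone_burst(fs, 7000, 0.008, 0.6)
        audio[40000 : 40000 + len(w)] += w
        assert len(acoustics.detect_calls(audio, fs)) == 0

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            acoustics.detect_calls(np.zeros(1000), 44100.0)

    def test_generator_scene_calls_recovered(self, small_scene, small_scene_calls):
        _, _, log = small_scene
        truth_mid = log.of_kind("call")["t"].to_numpy() + 0.001
        d = np.abs(small_scene_calls.call_times[:, None] - truth_mid[None, :])
        assert (d.min(axis=0) < 0.001).mean() > 0.95


def _brute_force_buzzes(ici, max_ici=0.008, min_run=7):
    """Oracle: scan every maximal run of consecutive short intervals."""
    runs = []
    i = 0
    while i < len(ici):
        if ici[i] < max_ici:
            j = i
            while j < len(ici) and ici[j] < max_ici:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


class TestDetectBuzzes:
    def test_all_long_intervals_no_buzz(self):
        calls = CallSeries(np.cumsum([0.05] * 30))
        assert acoustics.detect_buzzes(calls) == []

    def test_seven_short_intervals_is_one_buzz(self):
        ici = [0.05, 0.006, 0.006, 0.006, 0.006, 0.006, 0.006, 0.006, 0.05]
        calls = CallSeries(np.concatenate([[0.0], np.cumsum(ici)]))
        buzzes = acoustics.detect_buzzes(calls)
        assert len(buzzes) == 1
        assert buzzes[0].n_short_intervals == 7

    def test_exactly_six_short_intervals_is_no_buzz(self):
        ici = [0.05] + [0.006] * 6 + [0.05]
        calls = CallSeries(np.concatenate([[0.0], np.cumsum(ici)]))
        assert acoustics.detect_buzzes(calls) == []

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.001, max_value=0.02), min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, ici):
        calls = CallSeries(np.concatenate([[0.0], np.cumsum(ici)]))
        got = [(b.start, b.end, b.n_short_intervals) for b in acoustics.detect_buzzes(calls)]
        t = calls.call_times
        want = [(t[i], t[j], j - i) for i, j in _brute_force_buzzes(np.asarray(ici))]
        assert got == pytest.approx(want) if got or want else got == want


class TestExcludeLandingBuzzes:
    def test_buzz_before_landing_excluded(self):
        buzzes = [BuzzEvent(9.0, 9.5, 8)]
        assert acoustics.exclude_landing_buzzes(buzzes, [10.0]) == []

    def test_buzz_far_from_landing_retained(self):
        buzzes = [BuzzEvent(3.0, 3.5, 8)]
        assert len(acoustics.exclude_landing_buzzes(buzzes, [10.0])) == 1

    def test_buzz_outside_flight_excluded(self):
        from batforage.motion import FlightEpoch

        buzzes = [BuzzEvent(3.0, 3.5, 8)]
        assert acoustics.exclude_landing_buzzes(buzzes, [], epochs=[FlightEpoch(10.0, 60.0)]) == []


class TestDetectMastication:
    FS = 94000.0

    def _interval_calls(self):
        return CallSeries(np.arange(0.5, 3.0, 0.08))

    def _run(self, chew_specs, seed=0):
        calls = self._interval_calls()
        audio = _audio_with_calls(self.FS, list(calls.call_times), snr_db=38.0, seed=seed, chew_specs=chew_specs)
        return acoustics.detect_mastication(audio, self.FS, calls, (0.5, 2.9))

    def test_silent_intervals_negative(self):
        iv = self._run([])
        assert len(iv) > 0 and not iv["chew"].any()

    def test_7khz_transient_positive(self):
        iv = self._run([(1.0 + 0.04, 7000, 0.6)])
        assert iv["chew"].sum() == 1
        hit = iv[iv["chew"]]
        assert abs(hit["chew_time"].iloc[0] - 1.04) < 0.02
        assert 5000 < hit["peak_freq"].iloc[0] < 20000

    def test_25khz_transient_negative(self):
        iv = self._run([(1.0 + 0.04, 25000, 0.6)])
        assert not iv["chew"].any()

    def test_weak_transient_below_threshold_negative(self):
        # ~10x weaker than the standard chew: smoothed amplitude < 0.012
        iv = self._run([(1.0 + 0.04, 7000, 0.06)])
        assert not iv["chew"].any()

    def test_polarity_flip_invariant(self):
        calls = self._interval_calls()
        audio = _audio_with_calls(self.FS, list(calls.call_times), chew_specs=[(1.04, 7000, 0.6)])
        a = acoustics.detect_mastication(audio, self.FS, calls, (0.5, 2.9))
        b = acoustics.detect_mastication(-audio, self.FS, calls, (0.5, 2.9))
        assert list(a["chew"]) == list(b["chew"])

    def test_out_of_band_energy_invariant(self):
        calls = self._interval_calls()
        audio = _audio_with_calls(self.FS, list(calls.call_times), chew_specs=[(1.04, 7000, 0.6)])
        t = np.arange(len(audio)) / self.FS
        loud = np.clip(audio + 0.3 * np.sin(2 * np.pi * 30000 * t), -1, 1)
        a = acoustics.detect_mastication(audio, self.FS, calls, (0.5, 2.9))
        b = acoustics.detect_mastication(loud, self.FS, calls, (0.5, 2.9))
        assert list(a["chew"]) == list(b["chew"])

    def test_empty_window_empty_result(self):
        calls = self._interval_calls()
        audio = _audio_with_calls(self.FS, list(calls.call_times))
        iv = acoustics.detect_mastication(audio, self.FS, calls, (2.95, 2.96))
        assert len(iv) == 0


class TestCharacterizeMastication:
    def test_eleven_evenly_spaced_chews(self):
        chews = 100.0 + np.arange(11.0)
        ct = acoustics.characterize_mastication(100.0, chews)
        assert ct.onset == pytest.approx(1.0)
        assert ct.duration == pytest.approx(8.0)
        assert ct.handling_time == pytest.approx(9.0)
        assert ct.count == 11

    def test_single_chew_degenerate(self):
        ct = acoustics.characterize_mastication(100.0, np.array([103.0]))
        assert ct.onset == pytest.approx(3.0)
        assert ct.duration == 0.0
        assert ct.handling_time == pytest.approx(3.0)

    def test_zero_chews_rejected(self):
        with pytest.raises(ValueError):
            acoustics.characterize_mastication(0.0, np.array([]))

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_handling_monotone_in_late_chews(self, extra):
        base = 10.0 + np.arange(10.0)
        a = acoustics.characterize_mastication(10.0, base)
        b = acoustics.characterize_mastication(10.0, np.append(base[:-1], base[-1] + extra))
        assert b.handling_time >= a.handling_time - 1e-9


class TestClassifySuccess:
    def test_success_window_rules(self, small_scene, small_scene_calls):
        """Chews inside the window mean success; the window closes at the
        next attack or 100 s."""
        _, rec, log = small_scene
        attacks = log.of_kind("attack")
        att = [AttackEvent(float(r.t), str(r.strategy)) for r in attacks.itertuples()]
        pred, trains = acoustics.analyze_attacks(rec.audio, rec.audio_fs, small_scene_calls, att)
        for p, t in zip(pred, attacks.itertuples()):
            assert p.success == bool(t.success)

    def test_chew_beyond_100s_window_is_failure(self):
        fs = 94000.0
        calls = CallSeries(np.arange(0.5, 130.0, 0.08))
        # silence everywhere: evaluating a (0, 100 s) window finds nothing
        rng = np.random.default_rng(0)
        audio = rng.normal(0, 0.005, int(102 * fs))
        win = acoustics.mastication_window(1.0, None, len(audio) / fs)
        assert win == (1.0, 101.0)
        iv = acoustics.detect_mastication(audio, fs, calls, win)
        assert not acoustics.classify_success(iv)


class TestChewCounts:
    def test_truth_count_medians_match_configured(self):
        """Sampled per-capture chew counts reproduce the configured medians
        (75 ground, 23 aerial) within 10%."""
        rng = np.random.default_rng(0)
        from batforage.synth import ChewParams

        p = ChewParams()
        for prey, med in (("ground", 75.0), ("aerial", 23.0)):
            counts = np.round(rng.lognormal(np.log(p.count_median[prey]), p.count_sigma[prey], 2000))
            assert abs(np.median(counts) - med) / med < 0.10

    def test_detected_counts_match_truth_counts(self, small_scene, small_scene_calls):
        _, rec, log = small_scene
        attacks = log.of_kind("attack")
        att = [AttackEvent(float(r.t), str(r.strategy)) for r in attacks.itertuples()]
        _, trains = acoustics.analyze_attacks(rec.audio, rec.audio_fs, small_scene_calls, att)
        chews = log.of_kind("chew")["t"].to_numpy()
        for tr in trains:
            nxt = attacks["t"][attacks["t"] > tr.attack_time]
            end = float(nxt.min()) if len(nxt) else np.inf
            truth_n = int(((chews > tr.attack_time) & (chews < end)).sum())
            assert abs(tr.count - truth_n) <= max(1, 0.05 * truth_n)


class TestEvaluation:
    def test_perfect_agreement(self):
        truth = [AttackEvent(float(i), "hawk", i % 2 == 0) for i in range(10)]
        ev = acoustics.evaluate_detector(truth, truth)
        assert ev.ppv == 1.0 and ev.fnr == 0.0

    def test_ppv_fnr_arithmetic(self):
        truth = [AttackEvent(float(i), "hawk", True) for i in range(99)]
        pred = [AttackEvent(float(i), "hawk", i < 90) for i in range(99)]
        ev = acoustics.evaluate_detector(pred, truth)
        assert ev.tp == 90 and ev.fp == 0 and ev.fn == 9
        assert ev.ppv == 1.0
        assert ev.fnr == pytest.approx(0.0909, abs=1e-4)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            acoustics.evaluate_detector([AttackEvent(0.0, "hawk", True)], [])

    def test_stratified_one_entry_per_strategy(self):
        truth = [AttackEvent(0.0, "hawk", True), AttackEvent(10.0, "glean", False)]
        out = acoustics.evaluate_by_strategy(truth, truth)
        assert set(out) == {"hawk", "glean"}


class TestCompareEventSets:
    def test_identical_sets(self):
        t = np.arange(10.0)
        frac, off = acoustics.compare_event_sets(t, t)
        assert frac == 0.0 and off == 0.0

    def test_constant_shift_recovered(self):
        t = np.arange(0.0, 100.0, 10.0)
        frac, off = acoustics.compare_event_sets(t + 0.9, t)
        assert frac == 0.0
        assert off == pytest.approx(0.9)

    def test_missing_event_counted(self):
        t = np.arange(10.0) * 10
        frac, _ = acoustics.compare_event_sets(t[:-1], t)
        assert frac == pytest.approx(0.1)
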