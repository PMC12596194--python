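"""PAT extraction: R-peak detection, tangent-intersection onsets, pairing,
plausibility filtering and Hanning smoothing."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patflow.config import FilterBounds, SynthConfig
from patflow.core import BeatSeries, WaveformRecord
from patflow.extract import (
    compute_pat,
    detect_pulse_onset,
    detect_r_peaks,
    extract_beats,
    filter_nonphysiological,
    smooth_hanning,
)
from patflow.synth import build_beat_schedule, render_waveforms


def _match_to_truth(detected_times, detected_vals, truth_times, truth_vals):
    """Pair each detection with its nearest ground-truth beat."""
    idx = np.clip(np.searchsorted(truth_times, detected_times), 0, truth_times.size - 1)
    prev = np.clip(idx - 1, 0, truth_times.size - 1)
    use_prev = np.abs(truth_times[prev] - detected_times) < np.abs(
        truth_times[idx] - detected_times
    )
    nearest = np.where(use_prev, prev, idx)
    return detected_vals - truth_vals[nearest]


class TestDetectRPeaks:
    def test_flat_signal_empty(self):
        rec = WaveformRecord(np.zeros(5120), np.zeros(5120), fs=512.0)
        assert detect_r_peaks(rec).size == 0

    def test_low_fs_rejected(self):
        rec = WaveformRecord(np.zeros(500), np.zeros(500), fs=50.0)
        with pytest.raises(ValueError):
            detect_r_peaks(rec)

    def test_clean_recovery_within_one_sample(self, clean_config):
        beats = build_beat_schedule(clean_config)
        rec, _ = render_waveforms(beats, np.full(beats.size, 233.0), clean_config)
        detected = detect_r_peaks(rec)
        assert detected.size == beats.size
        err = _match_to_truth(detected, detected, beats, beats)
        assert np.max(np.abs(err)) <= 1.0 / clean_config.fs + 1e-12

    def test_two_beats_rr_recovered(self, clean_config):
        cfg = dataclasses.replace(clean_config, session_duration=4.0)
        rec, _ = render_waveforms(
            np.array([1.0, 2.0]), np.array([233.0, 233.0]), cfg
        )
        detected = detect_r_peaks(rec)
        assert detected.size == 2
        assert np.diff(detected)[0] == pytest.approx(1.0, abs=1.0 / cfg.fs)


class TestDetectPulseOnset:
    def test_piecewise_linear_exact(self):
        fs = 512.0
        t = np.arange(0, 0.6, 1 / fs)
        seg = np.where(t < 0.30, 0.20, 0.20 + 8.0 * (t - 0.30))
        res = detect_pulse_onset(seg, fs)
        assert res.reason is None
        assert res.time == pytest.approx(0.30, abs=1e-9)

    def test_raised_cosine_matches_oversampled_oracle(self):
        # oracle: same two tangents evaluated on a 100x oversampled grid
        fs = 512.0
        t0, tau, amp = 0.25, 0.15, 1.0

        def pulse(t):
            y = np.zeros_like(t)
            rising = (t >= t0) & (t < t0 + tau)
            y[rising] = amp * 0.5 * (1 - np.cos(np.pi * (t[rising] - t0) / tau))
            y[t >= t0 + tau] = amp
            return y

        t_dense = np.arange(0, 0.6, 1 / (100 * fs))
        y_dense = pulse(t_dense)
        slope_dense = np.gradient(y_dense) * 100 * fs
        m = int(np.argmax(slope_dense))
        y_min = float(np.min(y_dense[: m + 1]))
        oracle = t_dense[m] - (y_dense[m] - y_min) / slope_dense[m]

        t = np.arange(0, 0.6, 1 / fs)
        res = detect_pulse_onset(pulse(t), fs)
        assert res.reason is None
        assert abs(res.time - oracle) <= 1.0 / fs

    def test_monotone_decreasing_invalid(self):
        seg = np.linspace(1.0, 0.0, 300)
        res = detect_pulse_onset(seg, 512.0)
        assert res.reason == "no_upstroke"
        assert np.isnan(res.time)

    def test_too_short_segment(self):
        assert detect_pulse_onset(np.array([0.0, 1.0]), 512.0).reason == "too_short"


class TestComputePat:
    def test_simple_pairing(self):
        beats = compute_pat(np.array([10.0]), np.array([10.233]))
        assert beats.pat[0] == pytest.approx(233.0)
        assert beats.valid[0]

    def test_unpaired_beat_flagged(self):
        # second beat's onset arrives only after the third R-peak
        beats = compute_pat(
            np.array([1.0, 2.0, 3.0]), np.array([1.233, 3.233])
        )
        assert not beats.valid[1]
        assert beats.reason[1] == "unpaired"
        assert beats.valid[0] and beats.valid[2]

    def test_onset_must_follow_r_peak(self):
        beats = compute_pat(np.array([1.0]), np.array([0.9]))
        assert not beats.valid[0]

    def test_end_to_end_recovery_against_truth(self, clean_config, rng):
        cfg = dataclasses.replace(clean_config, session_duration=600.0)
        beats = build_beat_schedule(cfg)
        pat = 233.0 + rng.normal(0, 3, beats.size)
        rec, truth = render_waveforms(beats, pat, cfg)
        res = extract_beats(rec)
        v = res.beats.valid
        err = _match_to_truth(
            res.beats.r_peak_times[v], res.beats.pat[v], beats, truth.true_pat
        )
        assert np.mean(np.abs(err) <= 2.0) >= 0.99


class TestFilter:
    def _series(self, pat, rr=1.0):
        n = len(pat)
        r = np.arange(n) * rr
        pat = np.asarray(pat, dtype=float)
        return BeatSeries(
            r, r + pat / 1000.0, pat, np.ones(n, bool), np.array([""] * n, object)
        )

    def test_pat_range_removal(self):
        beats = self._series([230.0, 232.0, 950.0, 231.0])
        out, counts = filter_nonphysiological(beats)
        assert counts["pat_range"] == 1
        assert not out.valid[2] and out.reason[2] == "pat_range"
        assert out.valid.sum() == 3

    def test_rr_range_removal(self):
        r = np.array([0.0, 0.10, 1.10])
        pat = np.array([230.0, 231.0, 232.0])
        beats = BeatSeries(
            r, r + pat / 1000, pat, np.ones(3, bool), np.array([""] * 3, object)
        )
        out, counts = filter_nonphysiological(beats)
        assert counts["rr_range"] == 1
        assert out.reason[0] == "rr_range"

    def test_jump_removal(self):
        pat = [230.0, 231.0, 229.0, 300.0, 230.0, 231.0, 229.0]
        out, counts = filter_nonphysiological(self._series(pat))
        assert counts["pat_jump"] == 1
        assert out.reason[3] == "pat_jump"

    def test_clean_session_nothing_removed(self, clean_config):
        beats = build_beat_schedule(clean_config)
        rec, _ = render_waveforms(beats, np.full(beats.size, 233.0), clean_config)
        res = extract_beats(rec)
        assert res.removal_counts == {"rr_range": 0, "pat_range": 0, "pat_jump": 0}
        assert res.beats.valid.all()

    def test_survivors_unchanged(self):
        beats = self._series([230.0, 232.0, 950.0, 231.0])
        out, _ = filter_nonphysiological(beats)
        np.testing.assert_array_equal(out.pat, beats.pat)
        np.testing.assert_array_equal(out.r_peak_times, beats.r_peak_times)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=50.0, max_value=900.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_filter_idempotent(self, pats):
        beats = self._series(pats)
        once, _ = filter_nonphysiological(beats)
        twice, _ = filter_nonphysiological(once)
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_array_equal(once.reason, twice.reason)

    def test_contamination_never_adds_valid_beats(self, clean_config):
        cfg = dataclasses.replace(clean_config, session_duration=300.0)
        beats = build_beat_schedule(cfg)
        pat = np.full(beats.size, 233.0)
        rec_clean, _ = render_waveforms(beats, pat, cfg)
        n_clean = extract_beats(rec_clean).beats.valid.sum()
        dirty_cfg = dataclasses.replace(
            cfg, artifact_rate=30.0, ecg_noise_sd=0.02, ppg_noise_sd=0.01
        )
        for seed in (0, 1, 2):
            rec_dirty, _ = render_waveforms(
                beats, pat, dirty_cfg, np.random.default_rng(seed)
            )
            assert extract_beats(rec_dirty).beats.valid.sum() <= n_clean


class TestSmoothHanning:
    def _series(self, times, pat):
        times = np.asarray(times, dtype=float)
        pat = np.asarray(pat, dtype=float)
        n = times.size
        return BeatSeries(
            times, times + pat / 1000.0, pat, np.ones(n, bool),
            np.array([""] * n, object),
        )

    def test_constant_preserved_exactly(self):
        t = np.arange(0.0, 600.0, 1.0)
        sm = smooth_hanning(self._series(t, np.full(t.size, 233.0)))
        assert np.all(sm.values == pytest.approx(233.0, abs=1e-12))

    def test_respiratory_sinusoid_attenuated(self):
        # 0.25 Hz, 10 ms amplitude at 1 Hz beats: the 180-s window crushes it
        t = np.arange(0.0, 1200.0, 1.0)
        pat = 233.0 + 10.0 * np.sin(2 * np.pi * 0.25 * t)
        sm = smooth_hanning(self._series(t, pat), window_s=180.0)
        interior = (sm.times > 90) & (sm.times < 1110)
        assert np.max(np.abs(sm.values[interior] - 233.0)) < 0.5

    def test_matches_direct_convolution_oracle(self):
        t = np.arange(0.0, 400.0, 1.0)
        rng = np.random.default_rng(7)
        pat = 233.0 + rng.normal(0, 5, t.size)
        sm = smooth_hanning(self._series(t, pat), window_s=180.0)
        for i in (0, 57, 200, 399):  # includes edges
            dt = t - t[i]
            w = np.where(np.abs(dt) <= 90.0, np.cos(np.pi * dt / 180.0) ** 2, 0.0)
            oracle = np.sum(w * pat) / np.sum(w)
            assert sm.values[i] == pytest.approx(oracle, abs=1e-10)

    def test_single_beat_identity(self):
        sm = smooth_hanning(self._series([10.0], [250.0]))
        assert sm.values[0] == 250.0

    def test_bounded_by_raw_extrema(self, rng):
        t = np.sort(rng.uniform(0, 500, 300))
        t = np.unique(t)
        pat = 233.0 + rng.normal(0, 20, t.size)
        sm = smooth_hanning(self._series(t, pat))
        assert np.all(sm.values >= pat.min() - 1e-12)
        assert np.all(sm.values <= pat.max() + 1e-12)

    def test_shift_equivariance(self):
        t = np.arange(0.0, 300.0, 1.0)
        rng = np.random.default_rng(3)
        pat = 233.0 + rng.normal(0, 5, t.size)
        a = smooth_hanning(self._series(t, pat))
        b = smooth_hanning(self._series(t + 1000.0, pat))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_no_valid_beats_empty(self):
        s = self._series([1.0, 2.0], [230.0, 231.0])
        s.valid[:] = False
        assert smooth_hanning(s).n == 0
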