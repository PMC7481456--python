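"""Artifact rules, filtering, resampling, segmentation, breathing rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lagte
from lagte import preprocess as pp


class TestRRFromPeaks:
    def test_definition(self):
        np.testing.assert_allclose(pp.rr_from_peaks([0.0, 0.45, 0.91]),
                                   [0.45, 0.46])

    def test_uniform_peaks(self):
        rr = pp.rr_from_peaks(np.arange(10) * 0.4)
        np.testing.assert_allclose(rr, 0.4)

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            pp.rr_from_peaks([1.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="index 2"):
            pp.rr_from_peaks([0.0, 0.5, 0.4])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=40))
    def test_positive_intervals_and_length(self, gaps):
        t = np.cumsum([0.0] + gaps)
        rr = pp.rr_from_peaks(t)
        assert rr.size == t.size - 1
        assert np.all(rr > 0)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(0, 60, 1 / 200)
        x = np.sin(2 * np.pi * 0.7 * t)
        y = pp.bandpass_resp(x, 200)
        mid = slice(2000, -2000)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        y = pp.bandpass_resp(np.full(200 * 60, 5.0), 200)
        assert np.max(np.abs(y)) < 0.05

    def test_out_of_band_tone_attenuated(self):
        # the 0.05 Hz corner rings for tens of seconds, so judge the
        # steady-state response away from the edges of a long record
        t = np.arange(0, 240, 1 / 200)
        y = pp.bandpass_resp(np.sin(2 * np.pi * 20 * t), 200)
        mid = slice(80 * 200, -80 * 200)
        assert np.max(np.abs(y[mid])) < 10 ** (-20 / 20)

    def test_rate_too_low(self):
        with pytest.raises(ValueError):
            pp.bandpass_resp(np.zeros(100), 5.0)


class TestResampleAtPeaks:
    def test_sine_maximum(self):
        t = np.arange(0, 2, 1 / 200)
        resp = np.sin(2 * np.pi * t)
        v = pp.resample_resp_at_peaks(resp, 200, [0.25, 1.0])
        assert v[0] == pytest.approx(1.0, abs=1e-3)

    def test_grid_point_exact(self):
        resp = np.arange(100.0)
        v = pp.resample_resp_at_peaks(resp, 200, [0.1, 0.2])
        assert v[0] == resp[20]

    def test_midpoint_of_ramp(self):
        resp = np.arange(100.0)          # ramp: interp is exact mid-value
        v = pp.resample_resp_at_peaks(resp, 200, [0.0525, 0.2])
        assert v[0] == pytest.approx(10.5, abs=1e-9)

    def test_peak_outside_span(self):
        with pytest.raises(ValueError, match="span"):
            pp.resample_resp_at_peaks(np.zeros(100), 200, [0.1, 5.0])


class TestArtifactFilter:
    def test_out_of_range_beat_rejected_and_segment_discarded(self):
        mask = pp.artifact_filter([0.45, 0.46, 0.70, 0.45])
        np.testing.assert_array_equal(mask.accepted,
                                      [True, True, False, True])
        assert mask.discard            # 1/4 > 5 %

    def test_change_rule_against_previous_accepted(self):
        mask = pp.artifact_filter([0.45, 0.55, 0.46, 0.46])
        assert not mask.accepted[1]    # 22 % jump
        assert mask.accepted[2]        # 2 % vs the previous ACCEPTED beat

    def test_clean_segment_kept(self):
        rr = np.full(300, 0.45) + 0.001 * np.sin(np.arange(300))
        mask = pp.artifact_filter(rr)
        assert mask.accepted.all() and not mask.discard
        assert mask.rejected_fraction == 0.0

    def test_rejected_cycle_flags_contained_beats(self):
        rr = np.full(20, 0.45)
        peaks = np.concatenate([[0.0], np.cumsum(rr)])
        onsets = np.array([0.0, 1.0, 2.0, 6.0])
        durations = np.array([1.0, 1.0, 4.0, 1.0])   # third cycle too long
        mask = pp.artifact_filter(rr, (onsets, durations), peaks)
        in_bad = (peaks[:-1] >= 2.0) & (peaks[:-1] < 6.0)
        np.testing.assert_array_equal(~mask.accepted, in_bad)

    def test_cycle_durations_from_zero_crossings(self):
        t = np.arange(0, 10, 1 / 200)
        onsets, durations = pp.resp_cycle_durations(np.sin(2 * np.pi * t),
                                                    200)
        assert durations.size >= 8
        np.testing.assert_allclose(durations, 1.0, atol=0.01)


class TestSegmentation:
    def _record(self, n_beats, state_bouts=None, seed=0):
        spec = lagte.PhysioSimSpec(duration=n_beats * 0.45 + 2, seed=seed)
        rec = lagte.simulate_physio(spec)
        if state_bouts is not None:
            rec.sleep_states = state_bouts
        return rec

    def test_two_segments_from_650_clean_beats(self):
        rec = self._record(652)
        rec.sleep_states = [(0.0, rec.rpeak_times[-1] + 1, "QS")]
        segs = pp.segment_and_normalize(rec)
        n_beats = rec.rpeak_times.size - 1
        assert len(segs) == n_beats // 300 >= 2

    def test_299_beats_give_no_segment(self):
        rec = self._record(299)
        rec.sleep_states = [(0.0, rec.rpeak_times[298], "QS")]
        segs = pp.segment_and_normalize(rec, "QS")
        assert segs == []

    def test_normalization_invariants(self):
        rec = self._record(320)
        rec.sleep_states = [(0.0, rec.rpeak_times[-1] + 1, "AS")]
        (seg,) = pp.segment_and_normalize(rec)
        for ch in (seg.rr, seg.resp):
            assert abs(ch.mean()) < 1e-8
            assert abs(ch.std() - 1) < 1e-6

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(300)
        once = pp._znorm(v)
        twice = pp._znorm(once)
        assert np.max(np.abs(once - twice)) < 1e-12

    def test_state_filtering(self):
        rec = self._record(700, seed=1)
        t_end = rec.rpeak_times[-1] + 1
        rec.sleep_states = [(0.0, t_end / 2, "QS"), (t_end / 2, t_end, "AS")]
        qs = pp.segment_and_normalize(rec, "QS")
        assert all(s.sleep_state == "QS" for s in qs)


class TestBreathingRate:
    def test_pure_tone(self):
        t = np.arange(0, 120, 1 / 200)
        f = pp.breathing_rate(np.sin(2 * np.pi * 0.8 * t), 200)
        assert f == pytest.approx(0.8, abs=0.02)

    def test_dominant_of_two_tones(self):
        t = np.arange(0, 120, 1 / 200)
        x = np.sin(2 * np.pi * 0.8 * t) + 0.3 * np.sin(2 * np.pi * 0.3 * t)
        assert pp.breathing_rate(x, 200) == pytest.approx(0.8, abs=0.02)

    def test_white_noise_rejected(self):
        x = np.random.default_rng(0).standard_normal(200 * 120)
        with pytest.raises(ValueError, match="prominent"):
            pp.breathing_rate(x, 200)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            pp.breathing_rate(np.zeros(200 * 30), 200)
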