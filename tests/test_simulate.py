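"""Generators: coupled-AR system, null pairs, synthetic physiology."""

import numpy as np
import pytest

import lagte
from lagte import preprocess
from lagte.simulate import ar_oscillator_coeffs


class TestOscillatorCoeffs:
    def test_closed_form(self):
        a1, a2 = ar_oscillator_coeffs(0.1, 0.95)
        assert a1 == pytest.approx(2 * 0.95 * np.cos(0.2 * np.pi), abs=1e-12)
        assert a1 == pytest.approx(1.5371, abs=1e-4)
        assert a2 == pytest.approx(-0.9025, abs=1e-12)

    def test_quarter_cycle_zeroes_a1(self):
        a1, _ = ar_oscillator_coeffs(0.25, 0.7)
        assert abs(a1) < 1e-12

    def test_vanishing_modulus(self):
        a1, a2 = ar_oscillator_coeffs(0.1, 1e-9)
        assert abs(a1) < 1e-8 and abs(a2) < 1e-8

    @pytest.mark.parametrize("f,rho", [(0.0, 0.5), (0.6, 0.5), (0.1, 1.0)])
    def test_out_of_range(self, f, rho):
        with pytest.raises(ValueError):
            ar_oscillator_coeffs(f, rho)


class TestCoupledAR:
    def test_default_lengths(self):
        pair = lagte.simulate_coupled_ar(seed=0)
        assert len(pair) == 300
        assert pair.x.size == pair.y.size == 300

    def test_seeded_determinism(self):
        a = lagte.simulate_coupled_ar(seed=5)
        b = lagte.simulate_coupled_ar(seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_uncoupled_variance_matches_yule_walker(self):
        spec = lagte.ARSimSpec(b_yx=0.0, c1=0.0, c2=0.0, c3=0.0, n=50_000)
        pair = lagte.simulate_coupled_ar(spec, seed=1)
        a1, a2 = spec.a1, spec.a2
        # AR(2) stationary variance from the Yule-Walker equations
        expected = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
        assert np.var(pair.x) == pytest.approx(expected, rel=0.05)

    def test_unstable_spec_rejected(self):
        spec = lagte.ARSimSpec(a1=2.0, a2=0.1)
        assert spec.spectral_radius() > 1
        with pytest.raises(ValueError, match="unstable"):
            lagte.simulate_coupled_ar(spec)

    def test_stationarity_radius_of_defaults(self):
        assert lagte.ARSimSpec().spectral_radius() < 1


class TestNullPair:
    def test_independence_and_moments(self):
        pair = lagte.simulate_null_pair(300, seed=0)
        r = np.corrcoef(pair.x, pair.y)[0, 1]
        assert abs(r) < 4 / np.sqrt(300)
        assert abs(pair.x.mean()) < 4 / np.sqrt(300)

    def test_determinism(self):
        np.testing.assert_array_equal(lagte.simulate_null_pair(300, 3).x,
                                      lagte.simulate_null_pair(300, 3).x)


class TestPhysioGenerator:
    def test_peak_count_matches_mean_rr(self):
        rec = lagte.simulate_physio(lagte.PhysioSimSpec(duration=600,
                                                        seed=0))
        expected = 600 / 0.45
        assert rec.rpeak_times.size == pytest.approx(expected, rel=0.05)

    def test_determinism(self):
        a = lagte.simulate_physio(lagte.PhysioSimSpec(duration=120, seed=2))
        b = lagte.simulate_physio(lagte.PhysioSimSpec(duration=120, seed=2))
        np.testing.assert_array_equal(a.rpeak_times, b.rpeak_times)
        np.testing.assert_array_equal(a.resp, b.resp)

    def test_waveform_span_and_monotone_peaks(self):
        spec = lagte.PhysioSimSpec(duration=120, seed=3, artifact_rate=0.02)
        rec = lagte.simulate_physio(spec)
        assert rec.resp.size == int(120 * 200)
        assert np.all(np.diff(rec.rpeak_times) > 0)
        assert rec.rpeak_times[-1] <= (rec.resp.size - 1) / rec.resp_fs

    def test_artifact_ground_truth_round_trip(self):
        rec = lagte.simulate_physio(
            lagte.PhysioSimSpec(duration=300, artifact_rate=0.01, seed=5))
        rr = preprocess.rr_from_peaks(rec.rpeak_times)
        mask = preprocess.artifact_filter(rr)
        rejected = set(np.flatnonzero(~mask.accepted).tolist())
        assert rejected == set(rec.ground_truth["artifact_rr_indices"])
        assert len(rejected) > 0

    def test_rsa_coupling_present_and_absent(self):
        spec_on = lagte.PhysioSimSpec(duration=120, seed=7, rsa_gain=0.012,
                                      rr_resp_gain=0.0)
        spec_off = lagte.PhysioSimSpec(duration=120, seed=7, rsa_gain=0.0,
                                       rr_resp_gain=0.0)

        def rsa_corr(rec):
            rr = preprocess.rr_from_peaks(rec.rpeak_times)
            resp = preprocess.resample_resp_at_peaks(
                rec.resp, rec.resp_fs, rec.rpeak_times)
            return np.corrcoef(rr, resp)[0, 1]

        assert rsa_corr(lagte.simulate_physio(spec_on)) > 0.3
        assert abs(rsa_corr(lagte.simulate_physio(spec_off))) < 0.15

    def test_zero_rsa_gives_nonsignificant_te(self):
        """Without RSA coupling the RESP->RR transfer is indistinguishable
        from its time-shift surrogate null (scaled-down replicate count)."""
        nonsig = 0
        n_runs = 6
        for seed in range(n_runs):
            rec = lagte.simulate_physio(lagte.PhysioSimSpec(
                duration=240, seed=100 + seed, rsa_gain=0.0,
                rr_resp_gain=0.0))
            rr = preprocess.rr_from_peaks(rec.rpeak_times)
            resp = preprocess.resample_resp_at_peaks(
                preprocess.bandpass_resp(rec.resp, rec.resp_fs),
                rec.resp_fs, rec.rpeak_times)
            n = min(rr.size, 300)
            pair = lagte.BivariateSeries(resp[:n], rr[:n])
            est, res = lagte.surrogate_test(pair, "x->y", 0, seed=seed)
            nonsig += not res.significant
        assert nonsig >= n_runs - 1

    def test_infeasible_gain_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            lagte.PhysioSimSpec(rsa_gain=0.2)

    def test_ga_graded_gains_ordered(self):
        from lagte.simulate import GA_COUPLING_GAIN
        assert (GA_COUPLING_GAIN["LPT"] < GA_COUPLING_GAIN["ET"]
                < GA_COUPLING_GAIN["FT"])
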