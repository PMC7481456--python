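"""Lagged TE: alignment, decomposition, oracle agreement, surrogates."""

import numpy as np
import pytest

import lagte
from lagte._design import build_design, direction_arrays, shift_role
from lagte.transfer_entropy import te_decomposition_terms
from lagte._rng import substream


class TestShiftAlign:
    @pytest.mark.parametrize("tau,expected", [(0, 290), (15, 275)])
    def test_row_counts(self, ar_pair, tau, expected):
        target, src, tgt = lagte.shift_align(ar_pair, tau, 10)
        assert target.size == src.shape[0] == tgt.shape[0] == expected
        assert src.shape[1] == tgt.shape[1] == 10

    def test_alignment_indices(self):
        # integer ramps make the index arithmetic directly checkable
        N, L, tau = 300, 10, 3
        x = np.arange(N, dtype=float)
        y = np.arange(N, dtype=float) + 10_000
        pair = lagte.BivariateSeries(x, y)
        target, src, tgt = lagte.shift_align(pair, tau, L)
        # row r anchors 0-based i = tau + L + r
        i = tau + L
        assert target[0] == y[i - tau]
        assert list(src[0]) == [x[i - j] for j in range(1, L + 1)]
        assert list(tgt[0]) == [y[i - tau - j] for j in range(1, L + 1)]

    def test_lag1_source_delay1_alignment(self):
        # the row whose target is y_{n-1} carries x_{n-1} as its delay-1
        # source regressor
        N, L = 200, 10
        x = np.arange(N, dtype=float)
        y = np.arange(N, dtype=float)
        pair = lagte.BivariateSeries(x, y)
        target, src, _ = lagte.shift_align(pair, 1, L)
        assert np.all(src[:, 0] == target + 1 - 1)  # x_{n-1} == y_{n-1}

    def test_deferred_source_for_reverse_direction(self):
        N, L, tau = 200, 10, 4
        x = np.arange(N, dtype=float)
        y = np.arange(N, dtype=float) + 5_000
        pair = lagte.BivariateSeries(x, y)
        target, src, tgt = lagte.shift_align(pair, tau, L, "y->x")
        i = tau + L
        assert target[0] == x[i]
        assert list(src[0]) == [y[i - tau - j] for j in range(1, L + 1)]
        assert list(tgt[0]) == [x[i - j] for j in range(1, L + 1)]

    def test_too_short_for_lag(self):
        pair = lagte.BivariateSeries(np.random.default_rng(0).normal(size=70),
                                     np.random.default_rng(1).normal(size=70))
        with pytest.raises(ValueError, match="too short"):
            lagte.shift_align(pair, 15, 10)


class TestTransferEntropy:
    def test_zero_without_source_candidates(self, ar_pair):
        emb = lagte.EmbeddingVector([lagte.Candidate(1, "target")], [0.5], 10)
        est = lagte.transfer_entropy(ar_pair, "x->y", 0, embedding=emb)
        assert est.value == 0.0 and est.raw_value == 0.0

    def test_matches_linear_gaussian_oracle(self, linear_pair):
        est = lagte.transfer_entropy(linear_pair, "x->y", 0, seed=7)
        assert est.value == pytest.approx(0.5 * np.log(1.25), abs=0.02)

    def test_clip_keeps_raw(self, null_pair):
        emb = lagte.EmbeddingVector([lagte.Candidate(4, "source")], [0.1], 10)
        est = lagte.transfer_entropy(null_pair, "x->y", 0, embedding=emb)
        assert est.value >= 0.0
        assert est.value == max(0.0, est.raw_value)

    def test_decomposition_matches_direct_cmi(self, ar_pair):
        """The four shared-radius entropy terms of the conditioning-vector
        form combine to the direct CMI estimate to floating precision."""
        pair = ar_pair.zscored()
        source, target = direction_arrays(pair, "x->y")
        design = build_design(source, target, 0, 10,
                              substream(1, "jitter", "x->y", 0), 50,
                              shift_role("x->y"))
        est = lagte.transfer_entropy(ar_pair, "x->y", 0, seed=1)
        h_yvy, h_vy, h_yv, h_v = te_decomposition_terms(design, est.embedding, 10)
        assert (h_yvy - h_vy - h_yv + h_v) == pytest.approx(
            est.raw_value, abs=1e-9)
        # and against the public estimator on the same jittered columns
        y = design.target
        vx = np.column_stack([design.col(c)
                              for c in est.embedding.source_part])
        vy_cols = [design.col(c) for c in est.embedding.target_part]
        vy = np.column_stack(vy_cols) if vy_cols else None
        direct = lagte.cmi_knn(
            y, vx, vy, params=lagte.EstimatorParams(clip_negative=False))
        assert direct == pytest.approx(est.raw_value, abs=1e-9)


class TestSurrogates:
    def test_deterministic_given_seed(self, null_pair):
        _, a = lagte.surrogate_test(null_pair, "x->y", 0, n_surrogates=20,
                                    seed=3)
        _, b = lagte.surrogate_test(null_pair, "x->y", 0, n_surrogates=20,
                                    seed=3)
        np.testing.assert_array_equal(a.surrogate_values, b.surrogate_values)
        assert a.threshold == b.threshold

    def test_threshold_is_empirical_95th(self, null_pair):
        _, res = lagte.surrogate_test(null_pair, "x->y", 0, n_surrogates=20,
                                      seed=3)
        assert res.threshold == np.quantile(res.surrogate_values, 0.95,
                                            method="higher")

    def test_strong_coupling_significant(self):
        rng = np.random.default_rng(11)
        n = 300
        x = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = rng.standard_normal()
        y[1:] = x[:-1] + 0.05 * rng.standard_normal(n - 1)
        pair = lagte.BivariateSeries(x, y)
        est, res = lagte.surrogate_test(pair, "x->y", 0, seed=4)
        assert res.significant
        assert est.value > res.threshold

    def test_degenerate_source_rejected(self):
        pair = lagte.BivariateSeries(
            np.ones(300), np.random.default_rng(0).standard_normal(300))
        with pytest.raises(ValueError, match="constant"):
            lagte.surrogate_test(pair, "x->y", 0)

    def test_max_shift_validation(self, null_pair):
        with pytest.raises(ValueError):
            lagte.surrogate_test(null_pair, "x->y", 0, max_shift=0)


class TestLagProfile:
    def test_first_cell_bit_identical_to_direct_call(self, ar_pair):
        prof = lagte.lag_profile(ar_pair, tau_max=2, seed=5, surrogates=False)
        direct = lagte.transfer_entropy(ar_pair, "x->y", 0, seed=5)
        cell = prof.estimates[("x->y", 0)]
        assert cell.value == direct.value
        assert cell.raw_value == direct.raw_value
        assert cell.embedding.selected == direct.embedding.selected

    def test_complete_grid_and_frame(self, ar_pair):
        prof = lagte.lag_profile(ar_pair, tau_max=2, seed=5, surrogates=False)
        assert set(prof.estimates) == {(d, t) for d in ("x->y", "y->x")
                                       for t in range(3)}
        frame = prof.to_frame()
        assert len(frame) == 6
        assert {"direction", "lag", "value", "raw_value",
                "n_candidates_source"} <= set(frame.columns)

    def test_tau_max_bounded_by_series_length(self, ar_pair):
        with pytest.raises(ValueError, match="N/4"):
            lagte.lag_profile(ar_pair, tau_max=80, surrogates=False)
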