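"""Windowing, polynomial-map fitting and coefficient distances."""

import numpy as np
import pytest

from eegstates.segmentation import (
    EpochRecord,
    coef_distance,
    design_matrix,
    distance_matrix,
    fit_poly_map,
    fit_segments,
    monomial_exponents,
    n_poly_coefs,
    segment_series,
)
from eegstates.synthetic import RegimeSpec, make_regime_signal


class TestSegmentSeries:
    @pytest.mark.parametrize(
        "n, window, overlap, expected_starts",
        [
            (1000, 200, 0.5, list(range(0, 801, 100))),
            (200, 200, 0.5, [0]),
            (150, 100, 0.0, [0]),
        ],
    )
    def test_window_layout(self, n, window, overlap, expected_starts):
        grid = segment_series(n, window, overlap)
        assert grid.starts.tolist() == expected_starts
        assert grid.starts[-1] + grid.window_len <= n

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            segment_series(199, 200)

    def test_half_overlap_is_default_step(self):
        grid = segment_series(1000, 128)
        assert grid.step == 64


class TestDesignMatrix:
    @pytest.mark.parametrize("m, p, n_cols", [(2, 2, 6), (1, 3, 4), (3, 2, 10)])
    def test_column_count_is_binomial(self, m, p, n_cols):
        X, y = design_matrix(np.arange(30.0), m, p)
        assert X.shape[1] == n_cols == n_poly_coefs(m, p)
        assert len(y) == X.shape[0]

    def test_monomial_basis_m2_p2(self):
        # columns: 1, x[t], x[t-1], x[t]^2, x[t]x[t-1], x[t-1]^2
        x = np.array([2.0, 3.0, 5.0, 7.0])
        X, y = design_matrix(x, 2, 2)
        np.testing.assert_allclose(X[0], [1, 3, 2, 9, 6, 4])
        np.testing.assert_allclose(y, [5.0, 7.0])
        assert monomial_exponents(2, 2) == [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]

    def test_delay_embedding_rows_and_target(self):
        x = np.arange(20.0)
        X, y = design_matrix(x, m=2, p=1, tau=3)
        # predict x[t] from x[t-3], x[t-6]
        assert X.shape == (14, 3)
        np.testing.assert_allclose(y, x[6:])
        np.testing.assert_allclose(X[0], [1.0, x[3], x[0]])


class TestFitPolyMap:
    def test_linear_map_exact_recovery(self):
        # x[n+1] = 0.5 + 0.3 x[n], noise-free, start far from the fixed point
        x = np.empty(60)
        x[0] = -10.0
        for t in range(59):
            x[t + 1] = 0.5 + 0.3 * x[t]
        coefs, rvar, degenerate = fit_poly_map(x, m=1, p=1)
        np.testing.assert_allclose(coefs, [0.5, 0.3], atol=1e-8)
        assert rvar < 1e-16
        assert not degenerate

    def test_logistic_map_polynomial_identity(self):
        regime = RegimeSpec(0, "polynomial_map", (0.0, 3.9, -3.9))
        x, _ = make_regime_signal([regime], dwell_s=128, length_s=128, fs=1.0, seed=3)
        coefs, rvar, _ = fit_poly_map(x, m=1, p=2)
        np.testing.assert_allclose(coefs, [0.0, 3.9, -3.9], atol=1e-6)
        assert rvar < 1e-12

    def test_constant_segment_flagged_degenerate(self):
        coefs, rvar, degenerate = fit_poly_map(np.full(50, 2.5), m=1, p=2)
        assert degenerate
        assert rvar == 0.0
        np.testing.assert_allclose(coefs, [2.5, 0.0, 0.0])

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="under-determined"):
            fit_poly_map(np.arange(5.0), m=2, p=3)

    def test_residual_var_non_increasing_in_poly_order(self, rng):
        x = rng.standard_normal(200)
        rvars = [fit_poly_map(x, m=2, p=p)[1] for p in (1, 2, 3)]
        assert rvars[0] >= rvars[1] - 1e-12
        assert rvars[1] >= rvars[2] - 1e-12

    def test_normalized_fit_is_amplitude_invariant(self, rng):
        x = rng.standard_normal(150) + 5.0
        a1, _, _ = fit_poly_map(x, m=2, p=1, normalize=True)
        a2, _, _ = fit_poly_map(40.0 * x - 7.0, m=2, p=1, normalize=True)
        np.testing.assert_allclose(a1, a2, atol=1e-10)


class TestDistances:
    def test_coef_distance_examples(self):
        assert coef_distance([1.0, 2.0, 2.0], [1.0, 2.0, 2.0]) == 0.0
        assert coef_distance([1.0, 2.0, 2.0], [1.0, 0.0, 2.0]) == 2.0

    def test_coef_distance_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            brute = np.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert abs(coef_distance(a, b) - brute) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ in length"):
            coef_distance([1.0], [1.0, 2.0])

    def test_distance_matrix_properties(self, rng):
        x = rng.standard_normal(600)
        grid = segment_series(len(x), 100)
        models = fit_segments(x, grid, m=2, p=1)
        D = distance_matrix(models)
        assert D.d.shape == (grid.n_windows, grid.n_windows)
        np.testing.assert_allclose(D.d, D.d.T)
        np.testing.assert_allclose(np.diag(D.d), 0.0)
        assert (D.d >= 0).all()

    def test_identical_windows_give_zero_matrix(self):
        x = np.tile(np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False)), 3)
        grid = segment_series(len(x), 100, overlap_fraction=0.0)
        models = fit_segments(x, grid, m=2, p=1)
        D = distance_matrix(models)
        np.testing.assert_allclose(D.d, 0.0, atol=1e-8)

    def test_regime_separation_exceeds_within_regime_spread(self):
        regimes = [
            RegimeSpec(0, "ar2_oscillator", (6.0, 0.95)),
            RegimeSpec(1, "ar2_oscillator", (11.0, 0.95)),
        ]
        x, truth = make_regime_signal(regimes, dwell_s=2.0, length_s=20.0, fs=128.0, seed=0)
        x = x - x.mean()
        grid = segment_series(len(x), 90)
        models = fit_segments(x, grid, m=2, p=1, tau=3, normalize=True)
        D = distance_matrix(models)
        wl = np.array(
            [np.bincount(truth.labels[s : s + 90]).argmax() for s in grid.starts]
        )
        within = np.median(
            np.concatenate(
                [D.d[np.ix_(wl == k, wl == k)].ravel() for k in (0, 1)]
            )
        )
        between = np.median(D.d[np.ix_(wl == 0, wl == 1)])
        assert between > within

    def test_parameter_recovery_on_polynomial_regime(self):
        # noise-free generator output from a polynomial map of order <= p
        regime = RegimeSpec(0, "polynomial_map", (0.05, 3.8, -3.8))
        x, _ = make_regime_signal([regime], dwell_s=300, length_s=300, fs=1.0, seed=1)
        grid = segment_series(len(x), 100, overlap_fraction=0.0)
        models = fit_segments(x, grid, m=1, p=2)
        for row in models.coefs:
            np.testing.assert_allclose(row, [0.05, 3.8, -3.8], atol=1e-6)


class TestEpochRecord:
    def test_demeaned_removes_channel_means(self, rng):
        ep = EpochRecord(data=rng.standard_normal((3, 100)) + 2.0, fs=128.0)
        out = ep.demeaned()
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_channel_name_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel_names"):
            EpochRecord(data=rng.standard_normal((3, 50)), fs=1.0, channel_names=["a"])
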