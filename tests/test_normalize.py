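"""Median polish, B-score scaling and replicate aggregation."""

import statistics

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrgscreen as ms
from mrgscreen.normalize import MAD_SCALE, MedianPolishFit, b_score, b_score_plate


def reference_median_polish(values, mask=None, max_iter=100, tol=1e-6):
    """Plain scalar re-implementation of the polish sweep (test oracle)."""
    n_rows = len(values)
    n_cols = len(values[0])
    resid = [
        [
            values[i][j] if (mask is None or mask[i][j]) else None
            for j in range(n_cols)
        ]
        for i in range(n_rows)
    ]
    resid = [[None if (v is None or v != v) else v for v in row] for row in resid]
    overall = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    converged = False
    for _ in range(max_iter):
        deltas = []
        for i in range(n_rows):
            vals = [v for v in resid[i] if v is not None]
            m = statistics.median(vals) if vals else 0.0
            deltas.append(abs(m))
            row_eff[i] += m
            for j in range(n_cols):
                if resid[i][j] is not None:
                    resid[i][j] -= m
        shift = statistics.median(row_eff)
        row_eff = [r - shift for r in row_eff]
        overall += shift
        for j in range(n_cols):
            vals = [resid[i][j] for i in range(n_rows) if resid[i][j] is not None]
            m = statistics.median(vals) if vals else 0.0
            deltas.append(abs(m))
            col_eff[j] += m
            for i in range(n_rows):
                if resid[i][j] is not None:
                    resid[i][j] -= m
        shift = statistics.median(col_eff)
        col_eff = [c - shift for c in col_eff]
        overall += shift
        if max(deltas) <= tol:
            converged = True
            break
    return overall, row_eff, col_eff, resid, converged


class TestComputeRatio:
    def test_no_response(self):
        assert ms.compute_ratio(ms.RawWellSignal(100, 100)) == 1.0

    def test_arithmetic(self):
        assert ms.compute_ratio(ms.RawWellSignal(100, 250)) == 2.5

    def test_peak_below_baseline_allowed(self):
        assert ms.compute_ratio(ms.RawWellSignal(100, 50)) == 0.5

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            ms.compute_ratio(ms.RawWellSignal(0, 50))


class TestMedianPolish:
    def test_constant_matrix(self):
        fit = ms.median_polish(np.full((4, 5), 7.0))
        assert fit.converged
        assert fit.overall == pytest.approx(7.0)
        np.testing.assert_allclose(fit.row_effects, 0, atol=1e-12)
        np.testing.assert_allclose(fit.col_effects, 0, atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)

    def test_two_by_two(self):
        fit = ms.median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert fit.overall == pytest.approx(2.5)
        np.testing.assert_allclose(fit.row_effects, [-1.0, 1.0])
        np.testing.assert_allclose(fit.col_effects, [-0.5, 0.5])
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)

    def test_pure_additive_model_recovered(self):
        # y_ij = mu + a_i + b_j with median-zero effects -> zero residuals
        rng = np.random.default_rng(5)
        a = rng.normal(0, 2, 7)
        a -= np.median(a)
        b = rng.normal(0, 2, 9)
        b -= np.median(b)
        y = 5.0 + a[:, None] + b[None, :]
        fit = ms.median_polish(y)
        assert fit.converged
        assert fit.overall == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(fit.row_effects, a, atol=1e-6)
        np.testing.assert_allclose(fit.col_effects, b, atol=1e-6)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-6)

    def test_reconstruction_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.normal(1, 0.3, (6, 8))
        fit = ms.median_polish(y)
        recon = fit.overall + fit.row_effects[:, None] + fit.col_effects[None, :]
        np.testing.assert_allclose(recon + fit.residuals, y, atol=1e-9)
        assert abs(np.median(fit.row_effects)) < 1e-6
        assert abs(np.median(fit.col_effects)) < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("shape", [(4, 4), (5, 6), (6, 6)])
    def test_matches_reference_implementation(self, seed, shape):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, shape)
        mask = rng.random(shape) > 0.15
        mask[:2, :2] = True  # keep enough analyzable structure
        fit = ms.median_polish(y, mask)
        overall, row_eff, col_eff, resid, converged = reference_median_polish(
            y.tolist(), mask.tolist()
        )
        assert fit.converged == converged
        assert fit.overall == pytest.approx(overall, abs=1e-6)
        np.testing.assert_allclose(fit.row_effects, row_eff, atol=1e-6)
        np.testing.assert_allclose(fit.col_effects, col_eff, atol=1e-6)
        expected = np.array(
            [[np.nan if v is None else v for v in row] for row in resid]
        )
        np.testing.assert_allclose(fit.residuals, expected, atol=1e-6)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ms.median_polish(np.ones((1, 5)))

    def test_masked_cells_get_no_residual(self):
        y = np.arange(12.0).reshape(3, 4)
        mask = np.ones((3, 4), bool)
        mask[1, 2] = False
        fit = ms.median_polish(y, mask)
        assert np.isnan(fit.residuals[1, 2])
        assert np.isfinite(fit.residuals[mask]).all()


class TestBScore:
    def test_mad_arithmetic(self):
        resid = np.array([[1.0, -1.0], [2.0, -2.0]])
        fit = MedianPolishFit(0.0, np.zeros(2), np.zeros(2), resid, 1, True)
        scored = b_score(fit)
        assert scored.mad == pytest.approx(MAD_SCALE * 1.5)
        assert scored.mad == pytest.approx(2.2239)
        np.testing.assert_allclose(scored.b_scores, resid / 2.2239, rtol=1e-4)

    def test_zero_mad_degenerate_convention(self):
        fit = MedianPolishFit(3.0, np.zeros(2), np.zeros(2), np.zeros((2, 2)), 1, True)
        scored = b_score(fit)
        assert scored.degenerate
        assert scored.mad == 0.0
        np.testing.assert_array_equal(scored.b_scores, 0.0)

    def test_row_and_column_offsets_do_not_change_b_scores(self):
        # exact at convergence; polish run to a tight tolerance here
        rng = np.random.default_rng(7)
        y = rng.normal(1, 0.2, (8, 10))
        base = b_score(ms.median_polish(y, tol=1e-10, max_iter=2000)).b_scores
        shifted = y + rng.normal(0, 3, 8)[:, None] + rng.normal(0, 3, 10)[None, :] + 5.0
        moved = b_score(ms.median_polish(shifted, tol=1e-10, max_iter=2000)).b_scores
        np.testing.assert_allclose(moved, base, atol=1e-6)

    @given(st.floats(0.1, 50.0))
    def test_positive_rescaling_invariance(self, k):
        # the polish is homogeneous of degree 1, so the absolute convergence
        # tolerance is scaled along with the data
        rng = np.random.default_rng(11)
        y = rng.normal(1, 0.2, (6, 7))
        base = b_score(ms.median_polish(y, tol=1e-9)).b_scores
        scaled = b_score(ms.median_polish(k * y, tol=k * 1e-9)).b_scores
        np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_controls_excluded_from_polish(self, small_screen):
        # a huge positive-control column must not perturb library B-scores
        cfg, plates, _ = small_screen
        plate = plates[0]
        scored = b_score_plate(plate)
        assert np.isnan(scored.b_scores[~plate.library_mask]).all()
        spiked = ms.PlateGrid(
            plate.plate_id, plate.cell_line,
            np.where(plate.role_mask(ms.WellRole.POS_CTRL), 1e6, plate.values),
            plate.roles.copy(), plate.compound_ids.copy(),
        )
        rescored = b_score_plate(spiked)
        np.testing.assert_allclose(
            rescored.b_scores[plate.library_mask],
            scored.b_scores[plate.library_mask],
            atol=1e-9,
        )

    def test_library_b_scores_centered_with_unit_scale(self):
        # pure-noise plate: per-replicate B-scores have median ~0, scaled MAD ~1
        rng = np.random.default_rng(13)
        b = b_score(ms.median_polish(rng.normal(1, 0.05, (16, 22)))).b_scores
        assert abs(np.median(b)) < 0.1
        assert MAD_SCALE * np.median(np.abs(b - np.median(b))) == pytest.approx(1.0, abs=1e-6)


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "values,expected,n",
        [
            ((10.0, 12.0, 14.0), 12.0, 3),
            ((10.0, float("nan"), 14.0), 12.0, 2),
            ((7.0,), 7.0, 1),
        ],
    )
    def test_mean_of_finite(self, values, expected, n):
        agg = ms.aggregate_replicates(values)
        assert agg.value == pytest.approx(expected)
        assert agg.n == n

    def test_all_missing(self):
        agg = ms.aggregate_replicates([float("nan"), float("nan")])
        assert np.isnan(agg.value)
        assert agg.n == 0
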