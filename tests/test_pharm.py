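"""4PL dose-response fitting, EC50 comparison and release statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mrgscreen as ms
from mrgscreen.pharm import DoseResponseFit


class TestFourPL:
    def test_midpoint(self):
        assert ms.four_pl(-5.0, 0.0, 100.0, -5.0, 1.3) == pytest.approx(50.0)

    def test_asymptotes(self):
        assert ms.four_pl(30.0, 0.0, 100.0, -5.0, 1.0) == pytest.approx(100.0)
        assert ms.four_pl(-40.0, 0.0, 100.0, -5.0, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_point(self):
        # bottom 0, top 100, midpoint -5, hill 1, at x = -4
        assert ms.four_pl(-4.0, 0.0, 100.0, -5.0, 1.0) == pytest.approx(100 / 1.1)

    @given(
        st.floats(-8, -2),
        st.floats(-8, -2),
        st.floats(0.3, 4.0),
    )
    def test_monotone_increasing_for_positive_hill(self, x1, x2, hill):
        lo, hi = sorted((x1, x2))
        y_lo = ms.four_pl(lo, 0.0, 1.0, -5.0, hill)
        y_hi = ms.four_pl(hi, 0.0, 1.0, -5.0, hill)
        assert y_lo <= y_hi + 1e-12


class TestFitDoseResponse:
    def test_noiseless_recovery(self):
        df = ms.simulate_dose_response(0.0, 2.0, -6.8, 1.0, n_replicates=1)
        fit = ms.fit_dose_response(df)
        assert fit.converged
        assert abs(fit.log_ec50 - (-6.8)) < 1e-4
        assert abs(fit.bottom) < 1e-4
        assert abs(fit.top - 2.0) < 1e-4
        assert abs(fit.hill - 1.0) < 1e-3

    def test_decreasing_curve_canonicalized(self):
        df = ms.simulate_dose_response(0.2, 1.8, -4.6, -1.2, n_replicates=1)
        fit = ms.fit_dose_response(df)
        assert fit.converged
        assert fit.bottom <= fit.top
        assert fit.hill < 0
        assert fit.log_ec50 == pytest.approx(-4.6, abs=1e-3)

    def test_constant_response_degenerate(self):
        x = np.array(ms.DEFAULT_LOG10_CONCENTRATIONS)
        y = np.full_like(x, 5.0)
        fit = ms.fit_dose_response((x, y))
        assert (not fit.converged) or fit.degenerate

    def test_needs_four_distinct_concentrations(self):
        with pytest.raises(ValueError):
            ms.fit_dose_response((np.array([-6, -5, -4.0]), np.array([0, 1, 2.0])))

    def test_noisy_recovery_median_error(self):
        errors = []
        for seed in range(10):
            df = ms.simulate_dose_response(
                0.0, 2.0, -4.8, 1.0, n_replicates=3, noise_sd=0.1, seed=seed
            )
            fit = ms.fit_dose_response(df)
            errors.append(abs(fit.log_ec50 - (-4.8)))
        assert np.median(errors) < 0.1

    def test_extrapolation_flagged(self):
        df = ms.simulate_dose_response(0.0, 2.0, -8.5, 1.0, n_replicates=1)
        fit = ms.fit_dose_response(df)
        assert fit.extrapolated


class TestCompareEC50:
    def _fit(self, log_ec50, se=0.02):
        return DoseResponseFit(
            bottom=0.0, top=1.0, log_ec50=log_ec50, hill=1.0,
            se_log_ec50=se, rss=0.0, n_points=8, converged=True,
        )

    def test_identical_fits(self):
        cmp = ms.compare_ec50(self._fit(-6.5), self._fit(-6.5))
        assert cmp.fold_change == pytest.approx(1.0)
        assert cmp.z == 0.0
        assert cmp.p_value == 1.0

    def test_wt_vs_n62s_fold_change(self):
        # 160 nM vs 283 nM read as log10 molar midpoints
        cmp = ms.compare_ec50(self._fit(np.log10(160e-9)), self._fit(np.log10(283e-9)))
        assert cmp.fold_change == pytest.approx(283 / 160, rel=1e-6)
        assert cmp.fold_change == pytest.approx(1.77, abs=0.01)

    def test_antisymmetric(self):
        a, b = self._fit(-6.8, 0.03), self._fit(-6.45, 0.05)
        fwd = ms.compare_ec50(a, b)
        rev = ms.compare_ec50(b, a)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.fold_change == pytest.approx(1 / fwd.fold_change)

    def test_two_fold_shift_detected_from_fits(self):
        # midpoints inside the tested grid, so both asymptotes are pinned
        # down and the log EC50 standard errors are tight
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            wt = ms.fit_dose_response(
                ms.simulate_dose_response(0, 2, -5.0, 1.0, n_replicates=3,
                                          noise_sd=0.05, seed=seed)
            )
            mut = ms.fit_dose_response(
                ms.simulate_dose_response(0, 2, -5.0 + np.log10(2), 1.0,
                                          n_replicates=3, noise_sd=0.05,
                                          seed=10_000 + seed)
            )
            cmp = ms.compare_ec50(wt, mut)
            if abs(cmp.z) > 2:
                detected += 1
        assert detected >= 0.9 * n_seeds

    def test_unconverged_rejected(self):
        bad = DoseResponseFit(0, 1, -6, 1, float("nan"), 1.0, 8, converged=False)
        with pytest.raises(ValueError):
            ms.compare_ec50(self._fit(-6.0), bad)


class TestPercentRelease:
    @pytest.mark.parametrize(
        "sup,lys,expected", [(50, 50, 50.0), (0, 80, 0.0), (75, 25, 75.0)]
    )
    def test_arithmetic(self, sup, lys, expected):
        assert ms.percent_release(sup, lys) == pytest.approx(expected)

    @given(st.floats(0.01, 1e6), st.floats(0, 1e6), st.floats(0.001, 1e3))
    def test_scale_invariance(self, sup, lys, k):
        assert ms.percent_release(k * sup, k * lys) == pytest.approx(
            ms.percent_release(sup, lys), rel=1e-9
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ms.percent_release(0.0, 0.0)


class TestSidak:
    def test_single_comparison_identity(self):
        assert ms.sidak_adjust(0.037, 1) == pytest.approx(0.037)

    def test_adjustment_formula(self):
        assert ms.sidak_adjust(0.01, 6) == pytest.approx(1 - 0.99**6)

    def test_clipped_at_one(self):
        assert ms.sidak_adjust(0.9, 50) == 1.0


class TestGenotypeEffectTest:
    def test_identical_values_give_null_report(self):
        df = pd.DataFrame(
            {
                "condition": ["a"] * 6 + ["b"] * 6,
                "genotype": (["LAD2"] * 3 + ["KO"] * 3) * 2,
                "percent_release": 10.0,
            }
        )
        report = ms.genotype_effect_test(df)
        assert (report.anova["F"].dropna() == 0).all()
        assert (report.anova["PR(>F)"].dropna() == 1).all()
        assert (report.contrasts["p_sidak"] == 1.0).all()

    def test_strong_genotype_effect_detected(self):
        detected = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = ms.simulate_degranulation(
                {
                    ("vehicle", "LAD2"): 5.0,
                    ("vehicle", "KO"): 5.0,
                    ("drug", "LAD2"): 60.0,   # >= 5 noise SDs above KO
                    ("drug", "KO"): 6.0,
                },
                noise_sd=5.0,
                n=6,
                seed=seed,
            )
            report = ms.genotype_effect_test(df)
            drug = report.contrasts.set_index("condition").loc["drug"]
            if drug["p_sidak"] < 0.01:
                detected += 1
        assert detected >= 0.95 * n_seeds

    def test_vehicle_contrast_stays_null(self):
        df = ms.simulate_degranulation(
            {
                ("vehicle", "LAD2"): 5.0,
                ("vehicle", "KO"): 5.0,
                ("drug", "LAD2"): 60.0,
                ("drug", "KO"): 6.0,
            },
            noise_sd=5.0, n=6, seed=0,
        )
        report = ms.genotype_effect_test(df)
        veh = report.contrasts.set_index("condition").loc["vehicle"]
        assert veh["p_sidak"] > 0.05

    def test_missing_cell_is_error(self):
        df = pd.DataFrame(
            {
                "condition": ["a"] * 4 + ["b"] * 2,
                "genotype": ["x", "x", "y", "y", "x", "x"],
                "percent_release": [1, 2, 3, 4, 5, 6.0],
            }
        )
        with pytest.raises(ValueError, match="missing"):
            ms.genotype_effect_test(df)

    def test_wrong_genotype_count_is_error(self):
        df = pd.DataFrame(
            {
                "condition": ["a"] * 6,
                "genotype": ["x", "x", "y", "y", "z", "z"],
                "percent_release": 1.0,
            }
        )
        with pytest.raises(ValueError, match="genotypes"):
            ms.genotype_effect_test(df)
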