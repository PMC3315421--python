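"""Ct-Ct relative quantification: fits, ratio inversion, time-course recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from regenkit import (
    CtCtQuantModel,
    QpcrSimParams,
    condition_fold_change,
    efficiency_from_slope,
    fit_ctct,
    fit_standard_curve,
    gen_qpcr_dataset,
    gen_qpcr_timecourse,
    gen_standard_curve_series,
    quantify_timecourse,
    ratio_from_intercept,
)
from regenkit.qpcr import CtCtFit, InsufficientDataError

from oracles import ols_normal_equations


class TestStandardCurve:
    def test_perfect_doubling_points(self):
        sc = fit_standard_curve([(0, 30.0), (1, 26.678), (2, 23.356)], "g")
        assert sc.slope_m == pytest.approx(-3.3219, abs=1e-3)
        assert sc.efficiency == pytest.approx(2.0, abs=1e-3)
        assert sc.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_published_slope_maps_to_efficiency(self):
        # a -3.52 cycles/decade curve corresponds to E ~ 1.923
        assert efficiency_from_slope(-3.52) == pytest.approx(1.923, abs=5e-4)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 3, 12)
        x[:4] = [0, 1, 2, 3]  # guarantee distinct dilutions
        y = 30 - 3.4 * x + rng.normal(0, 0.3, 12)
        sc = fit_standard_curve(np.column_stack([x, y]), "g")
        slope, intercept = ols_normal_equations(x, y)
        assert sc.slope_m == pytest.approx(slope, abs=1e-9)
        assert sc.intercept == pytest.approx(intercept, abs=1e-9)

    def test_insufficient_distinct_dilutions(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_curve([(0, 30.0), (0, 30.1), (1, 27.0)], "g")

    def test_rising_curve_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_standard_curve([(0, 20.0), (1, 23.0), (2, 26.0)], "g")

    def test_implausible_efficiency_flagged_not_rejected(self):
        sc = fit_standard_curve([(0, 30.0), (1, 27.0), (2, 24.0)], "g")  # E ~ 2.15
        assert sc.efficiency > 2.1
        assert sc.implausible_efficiency


class TestEfficiencyFromSlope:
    def test_canonical_values(self):
        assert efficiency_from_slope(-3.3219) == pytest.approx(2.0, abs=1e-3)

    def test_steep_slope_limit_approaches_one(self):
        assert efficiency_from_slope(-1000.0) == pytest.approx(1.0023, abs=1e-4)
        assert efficiency_from_slope(-1e6) > 1.0

    def test_nonnegative_slope_is_domain_error(self):
        with pytest.raises(ValueError):
            efficiency_from_slope(0.0)
        with pytest.raises(ValueError):
            efficiency_from_slope(3.3)


class TestCtCtFit:
    def test_equal_efficiencies_slope_one(self):
        p = QpcrSimParams(R_by_condition={"c": 5.0}, E_target=2.0, E_control=2.0,
                          ct_noise_sd=0.0, seed=4)
        table, _ = gen_qpcr_dataset(p)
        wide = table[table["condition"] == "c"].pivot(index="sample_id", columns="gene_name", values="ct")
        fit = fit_ctct(wide[["GAPDH", "CEBP"]].to_numpy(), "c")
        assert fit.slope_m == pytest.approx(1.0, abs=1e-10)

    def test_slope_is_log_efficiency_ratio(self, ct_pairs):
        fit = fit_ctct(ct_pairs, "crush")
        assert fit.slope_m == pytest.approx(math.log(2.0) / math.log(1.9), abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        pairs = rng.normal(25, 2, size=(10, 2))
        fit = fit_ctct(pairs)
        slope, intercept = ols_normal_equations(pairs[:, 0], pairs[:, 1])
        assert fit.slope_m == pytest.approx(slope, abs=1e-9)
        assert fit.y_intercept == pytest.approx(intercept, abs=1e-9)

    def test_no_input_spread_unidentifiable(self):
        with pytest.raises(InsufficientDataError, match="spread"):
            fit_ctct([(25.0, 23.0), (25.0, 24.0), (25.0, 22.0)])

    def test_nonfinite_cts_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_ctct([(25.0, 23.0), (np.nan, 24.0)])


class TestRatioFromIntercept:
    def test_zero_intercept_means_equal_abundance(self):
        assert ratio_from_intercept(0.0, 1.87) == 1.0

    def test_decade_intercept_at_perfect_doubling(self):
        assert ratio_from_intercept(-3.3219, 2.0) == pytest.approx(10.0, rel=1e-4)

    def test_reciprocal_symmetry(self):
        r_neg = ratio_from_intercept(-3.3219, 2.0)
        r_pos = ratio_from_intercept(+3.3219, 2.0)
        assert r_pos == pytest.approx(1.0 / r_neg, rel=1e-12)

    def test_efficiency_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            ratio_from_intercept(1.0, 1.0)


class TestConditionFoldChange:
    @staticmethod
    def _fit(yint, t=3.0, cond="x"):
        return CtCtFit(cond, t, 1.0, yint, 1.0, 5)

    def test_identical_fits_give_unity(self):
        f = self._fit(-2.0)
        assert condition_fold_change(f, f, 2.0) == pytest.approx(1.0)

    def test_one_cycle_shift_at_perfect_doubling_doubles(self):
        assert condition_fold_change(self._fit(-1.0), self._fit(0.0), 2.0) == pytest.approx(2.0)

    def test_monotone_decreasing_in_crush_intercept(self):
        sham = self._fit(0.0)
        folds = [condition_fold_change(self._fit(y), sham, 1.9) for y in (-2, -1, 0, 1, 2)]
        assert all(a > b for a, b in zip(folds, folds[1:]))

    def test_swapping_conditions_inverts(self):
        a, b = self._fit(-1.3), self._fit(0.4)
        assert condition_fold_change(a, b, 1.9) == pytest.approx(
            1.0 / condition_fold_change(b, a, 1.9), rel=1e-12
        )

    def test_mismatched_time_points_rejected(self):
        with pytest.raises(ValueError, match="time"):
            condition_fold_change(self._fit(0.0, t=1.0), self._fit(0.0, t=3.0), 2.0)


class TestRoundTrip:
    @pytest.mark.parametrize("true_r", [0.1, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("e_target", [1.8, 1.9, 2.0])
    @pytest.mark.parametrize("e_control", [1.8, 2.0])
    def test_noise_free_pipeline_recovers_ratio_exactly(self, true_r, e_target, e_control):
        p = QpcrSimParams(
            R_by_condition={"sham": 1.0, "crush": true_r},
            E_target=e_target, E_control=e_control,
            ct_noise_sd=0.0, n_samples_per_condition=5, seed=17,
        )
        table, _ = gen_qpcr_dataset(p)
        fits = {}
        for cond in ("sham", "crush"):
            wide = table[table["condition"] == cond].pivot(
                index="sample_id", columns="gene_name", values="ct"
            )
            fits[cond] = fit_ctct(wide[["GAPDH", "CEBP"]].to_numpy(), cond)
        fold = condition_fold_change(fits["crush"], fits["sham"], e_target)
        assert fold == pytest.approx(true_r, rel=1e-9)
        # intercept itself inverts the generator: R = E^-Yint for each condition
        assert ratio_from_intercept(fits["crush"].y_intercept, e_target) == pytest.approx(true_r, rel=1e-9)

    def test_equal_efficiency_limit_matches_ddct(self):
        # at E_g = E_c = 2 the Ct-Ct estimate equals 2**(-ddCt) with mean
        # dCt per condition, on noise-free data
        p = QpcrSimParams(R_by_condition={"sham": 1.0, "crush": 3.7}, E_target=2.0,
                          E_control=2.0, ct_noise_sd=0.0, seed=23)
        table, _ = gen_qpcr_dataset(p)
        wides = {
            cond: table[table["condition"] == cond].pivot(
                index="sample_id", columns="gene_name", values="ct"
            )
            for cond in ("sham", "crush")
        }
        dct = {c: (w["CEBP"] - w["GAPDH"]).mean() for c, w in wides.items()}
        ddct_estimate = 2.0 ** (-(dct["crush"] - dct["sham"]))
        fits = {c: fit_ctct(w[["GAPDH", "CEBP"]].to_numpy(), c) for c, w in wides.items()}
        ctct_estimate = condition_fold_change(fits["crush"], fits["sham"], 2.0)
        assert ctct_estimate == pytest.approx(ddct_estimate, rel=1e-9)

    def test_equal_efficiency_quantification_equals_ddct_under_noise(self):
        # with both efficiencies known and equal to 2, the quantification
        # intercept (slope fixed at 1) reproduces the classic 2**(-ddCt)
        # estimate exactly, sample by sample, noisy data included
        master = np.random.default_rng(77)
        for _ in range(50):
            p = QpcrSimParams(R_by_condition={"sham": 1.0, "crush": 2.0}, E_target=2.0,
                              E_control=2.0, ct_noise_sd=0.3, sample_spread_sd=0.6,
                              n_samples_per_condition=8, seed=int(master.integers(2**31)))
            table, _ = gen_qpcr_dataset(p)
            wides = {
                c: table[table["condition"] == c].pivot(
                    index="sample_id", columns="gene_name", values="ct"
                )
                for c in ("sham", "crush")
            }
            dct = {c: (w["CEBP"] - w["GAPDH"]).mean() for c, w in wides.items()}
            ddct_estimate = 2.0 ** (-(dct["crush"] - dct["sham"]))
            fits = {
                c: fit_ctct(w[["GAPDH", "CEBP"]].to_numpy(), c, fixed_slope=1.0)
                for c, w in wides.items()
            }
            ctct_estimate = condition_fold_change(fits["crush"], fits["sham"], 2.0)
            assert ctct_estimate == pytest.approx(ddct_estimate, rel=1e-10)


class TestTimecourse:
    def test_noise_free_recovery_of_configured_ratios(self):
        base = QpcrSimParams(R_by_condition={"sham": 1.0}, ct_noise_sd=0.0, seed=31)
        truth_ratios = {1.0: 7.36, 3.0: 2.35, 5.0: 1.98}
        table, _ = gen_qpcr_timecourse(base, truth_ratios, n_groups=5)
        results, qc = quantify_timecourse(table, 2.0, efficiency_control=2.0)
        assert [r.time_hr for r in results] == [1.0, 3.0, 5.0]
        for r in results:
            assert r.fold_change == pytest.approx(truth_ratios[r.time_hr], rel=1e-9)
            assert r.sem == pytest.approx(0.0, abs=1e-9)
            assert r.n == 5
        assert not qc["slope_flag"].any()

    def test_single_group_has_no_sem(self):
        base = QpcrSimParams(R_by_condition={"sham": 1.0}, ct_noise_sd=0.0, seed=32)
        table, _ = gen_qpcr_timecourse(base, {3.0: 2.0}, n_groups=1)
        results, _ = quantify_timecourse(table, 2.0)
        assert results[0].n == 1
        assert results[0].sem is None

    def test_missing_condition_reported(self):
        base = QpcrSimParams(R_by_condition={"sham": 1.0}, ct_noise_sd=0.0, seed=33)
        table, _ = gen_qpcr_timecourse(base, {3.0: 2.0}, n_groups=2)
        broken = table[table["condition"] != "sham"]
        with pytest.raises(ValueError, match="sham"):
            quantify_timecourse(broken, 2.0)

    def test_stochastic_recovery_close_to_truth(self):
        # noisy replicate-group design: mean recovered ratio within 10% of 2.35
        recovered = []
        master = np.random.default_rng(55)
        for _ in range(200):
            base = QpcrSimParams(R_by_condition={"sham": 1.0}, ct_noise_sd=0.3,
                                 sample_spread_sd=0.5, n_samples_per_condition=5,
                                 seed=int(master.integers(2**31)))
            table, _ = gen_qpcr_timecourse(base, {3.0: 2.35}, n_groups=5)
            results, _ = quantify_timecourse(table, 2.0, efficiency_control=2.0)
            recovered.append(results[0].fold_change)
        assert np.mean(recovered) == pytest.approx(2.35, rel=0.10)

    def test_model_estimates_efficiency_from_standard_rows(self):
        base = QpcrSimParams(R_by_condition={"sham": 1.0}, E_target=1.9, E_control=2.0,
                             ct_noise_sd=0.0, seed=37)
        table, _ = gen_qpcr_timecourse(base, {3.0: 4.0}, n_groups=3)
        std_t = gen_standard_curve_series(1.9, (1, 10, 100), gene_name="CEBP")
        std_c = gen_standard_curve_series(2.0, (1, 10, 100), gene_name="GAPDH", gene_role="control")
        full = pd.concat([table, std_t, std_c], ignore_index=True)
        res = CtCtQuantModel(full).fit()
        assert res.efficiency_target == pytest.approx(1.9, rel=1e-6)
        assert res.efficiency_control == pytest.approx(2.0, rel=1e-6)
        assert res.fold_changes[0].fold_change == pytest.approx(4.0, rel=1e-6)
        assert not res.qc["slope_flag"].any()
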