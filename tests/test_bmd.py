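"""Dose-response model fitting, BMC derivation, profile bounds and filters."""

import numpy as np
import pandas as pd
import pytest

import hepapod as hp
from hepapod import bmd
from conftest import make_linear_data


class TestFitModel:
    def test_noiseless_linear_identifiability(self):
        d = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0], 3)
        y = 1.0 + 2.0 * d
        fit = bmd.fit_model("linear", d, y)
        a = fit.params[0]
        b = fit.params[1] / fit.dose_scale  # slope on the raw dose axis
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(2.0, abs=1e-6)

    def test_hill_k_recovery_within_20pct(self):
        rng = np.random.default_rng(42)
        d = np.repeat(hp.make_design(1, 100.0, 9).levels + (0.0,), 4)
        k_true, n_true = 10.0, 2.0
        y = 5.0 + 2.0 * d**n_true / (k_true**n_true + d**n_true)
        y = y + rng.normal(0, 0.1, d.size)
        fit = bmd.fit_model("hill", d, y)
        k_hat = fit.params[2] * fit.dose_scale
        assert abs(k_hat - k_true) / k_true < 0.2

    def test_constant_responses_yield_no_bmc(self):
        d = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
        fit = bmd.fit_model("linear", d, np.full(d.size, 2.0))
        assert bmd.compute_bmc(fit) is None

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            bmd.fit_model("linear", np.repeat([0.0, 1.0, 2.0], 3), np.zeros(9))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            bmd.fit_model("probit", np.arange(8.0), np.arange(8.0))

    @pytest.mark.parametrize("model", bmd.MODELS)
    def test_all_models_fit_monotone_data(self, model, run1_profile):
        doses, y, _ = run1_profile
        fit = bmd.fit_model(model, doses, y)
        assert fit.converged
        assert np.isfinite(fit.aic)
        assert fit.sigma2 > 0


class TestComputeBmc:
    def test_linear_closed_form(self):
        d, y = make_linear_data(b=2.0, sigma=0.5, seed=1)
        fit = bmd.fit_model("linear", d, y)
        slope = fit.params[1] / fit.dose_scale
        closed = 1.0 * np.sqrt(fit.sigma2) / abs(slope)
        assert bmd.compute_bmc(fit, bmr_sd=1.0) == pytest.approx(closed, rel=1e-8)

    def test_bmr_scaling(self):
        d, y = make_linear_data(seed=2)
        fit = bmd.fit_model("linear", d, y)
        assert bmd.compute_bmc(fit, 2.0) == pytest.approx(
            2.0 * bmd.compute_bmc(fit, 1.0), rel=1e-6
        )

    def test_invariant_to_response_shift(self, run1_profile):
        doses, y, _ = run1_profile
        b1 = bmd.compute_bmc(bmd.fit_model("hill", doses, y))
        b2 = bmd.compute_bmc(bmd.fit_model("hill", doses, y + 4.0))
        assert b1 == pytest.approx(b2, rel=1e-4)

    def test_scales_with_dose_axis(self, run1_profile):
        doses, y, _ = run1_profile
        b1 = bmd.compute_bmc(bmd.fit_model("hill", doses, y))
        b2 = bmd.compute_bmc(bmd.fit_model("hill", doses * 10.0, y))
        assert b2 == pytest.approx(10.0 * b1, rel=1e-4)


class TestProfileCi:
    def test_near_noiseless_bounds_collapse(self):
        d = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 4)
        rng = np.random.default_rng(3)
        y = 1.0 + 2.0 * d + rng.normal(0, 1e-5, d.size)
        fit = bmd.fit_model("linear", d, y)
        bmc = bmd.compute_bmc(fit)
        lo, hi, _ = bmd.profile_ci(fit, bmc)
        assert hi / lo < 3.0  # tight interval for near-deterministic data
        assert lo <= bmc <= hi

    @pytest.mark.parametrize("model", ["linear", "hill", "power", "exp4"])
    def test_ordering_bmcl_bmc_bmcu(self, model, run1_profile):
        doses, y, _ = run1_profile
        fit = bmd.fit_model(model, doses, y)
        bmc = bmd.compute_bmc(fit)
        assert bmc is not None
        lo, hi, _ = bmd.profile_ci(fit, bmc)
        assert lo <= bmc <= hi

    def test_linear_coverage_two_sided_90pct(self):
        """[BMCL, BMCU] from two one-sided 95% bounds covers ~90%."""
        n_rep, hits, evaluable = 120, 0, 0
        b_true, sigma_true = 2.0, 0.5
        bmc_true = sigma_true / b_true
        for s in range(n_rep):
            d, y = make_linear_data(b=b_true, sigma=sigma_true, seed=1000 + s)
            fit = bmd.fit_model("linear", d, y)
            bmc = bmd.compute_bmc(fit)
            if bmc is None:
                continue
            lo, hi, flag = bmd.profile_ci(fit, bmc)
            evaluable += 1
            hits += lo <= bmc_true <= hi
        assert evaluable > 100
        coverage = hits / evaluable
        assert abs(coverage - 0.90) <= 3 * np.sqrt(0.9 * 0.1 / evaluable) + 0.01


class TestSelectBest:
    def test_single_eligible_fit_returned(self, run1_profile):
        doses, y, _ = run1_profile
        fit = bmd.fit_model("hill", doses, y)
        best, bmc = bmd.select_best([fit])
        assert best.model == "hill"
        assert bmc is not None

    def test_aic_tie_goes_to_fewer_parameters(self, run1_profile):
        doses, y, _ = run1_profile
        f_hill = bmd.fit_model("hill", doses, y)
        f_lin = bmd.fit_model("linear", doses, y)
        f_lin.aic = f_hill.aic  # force the tie
        best, _ = bmd.select_best([f_hill, f_lin])
        assert best.model == "linear"

    def test_no_eligible_raises(self):
        d = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
        fit = bmd.fit_model("linear", d, np.full(d.size, 1.0))
        with pytest.raises(ValueError, match="no converged fit"):
            bmd.select_best([fit])


class TestFilters:
    def test_toy_table_reasons(self, toy_results):
        out = bmd.apply_bmdexpress_filters(toy_results, lowest_positive_dose=0.05)
        assert sorted(out["probe_id"]) == ["ok1", "ok2"]
        removed = out.attrs["removed"].set_index("probe_id")["filter_reason"]
        assert removed["bad_p"] == "fit_p_below_0.001"
        assert removed["bad_ratio"] == "bmcu_bmcl_ratio_above_40"
        assert removed["bad_low"] == "bmc_below_tenth_lowest_dose"
        assert removed["bad_fc"] == "fold_change_below_2"

    def test_boundary_values_retained(self, toy_results):
        # ok2 sits exactly at ratio 40 and fold-change 2.0: both strict rules
        out = bmd.apply_bmdexpress_filters(toy_results, lowest_positive_dose=0.05)
        assert "ok2" in set(out["probe_id"])

    def test_row_order_independent(self, toy_results):
        shuffled = toy_results.sample(frac=1.0, random_state=4)
        a = bmd.apply_bmdexpress_filters(toy_results, 0.05)
        b = bmd.apply_bmdexpress_filters(shuffled, 0.05)
        assert set(a["probe_id"]) == set(b["probe_id"])

    def test_missing_fields_rejected(self, toy_results):
        with pytest.raises(ValueError, match="missing fields"):
            bmd.apply_bmdexpress_filters(
                toy_results.drop(columns=["bmcl"]), 0.05
            )

    def test_clustering_filter_rules(self, toy_results):
        tbl = toy_results.copy()
        out = bmd.clustering_filter(tbl, top_dose=10.0)
        kept = set(out["probe_id"])
        assert "bad_ratio" not in kept  # ratio 41 > 20
        assert "ok1" in kept  # bmc exactly at the top dose is retained
        assert "ok2" not in kept  # bmc 20 above top dose 10


class TestFitProbe:
    def test_planted_hill_recovered_within_two_fold(self, run1_profile):
        doses, y, _ = run1_profile
        res = bmd.fit_probe("HILL_A", doses, y, substance="S01", run="R1")
        assert res is not None
        assert 5.0 <= res.bmc <= 20.0  # planted at 10
        assert res.bmcl <= res.bmc <= res.bmcu
        assert res.direction == "up"
        assert res.max_fold_change > 2.0

    def test_results_frame_schema(self, run1_profile):
        doses, y, _ = run1_profile
        res = bmd.fit_probe("HILL_A", doses, y, with_ci=False)
        frame = bmd.results_frame([res])
        assert list(frame.columns)[:4] == ["probe_id", "substance", "run", "model"]
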