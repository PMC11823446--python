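"""PAVA, the Williams-type trend test, and both prefilter modes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import hepapod as hp
from hepapod.trend import prefilter_mode_b, williams_batch


def sqp_isotonic(y, w, increasing=True):
    """Independent monotone-LS oracle via constrained quadratic optimization."""
    sign = 1.0 if increasing else -1.0
    cons = [
        {"type": "ineq", "fun": (lambda x, i=i: sign * (x[i + 1] - x[i]))}
        for i in range(len(y) - 1)
    ]
    res = optimize.minimize(
        lambda x: np.sum(w * (x - y) ** 2), x0=np.full(len(y), np.mean(y)),
        constraints=cons, method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x


class TestPava:
    def test_already_monotone_unchanged(self):
        assert np.allclose(hp.pava([1, 2, 3]), [1, 2, 3])

    def test_violator_pooling(self):
        # brute-force minimum over monotone vectors for (3,1,2) is (2,2,2)
        assert np.allclose(hp.pava([3, 1, 2]), [2, 2, 2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hp.pava([])

    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        st.lists(st.floats(0.1, 5), min_size=6, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_constrained_ls_oracle(self, y, w):
        y = np.asarray(y)
        w = np.asarray(w[: len(y)])
        fit = hp.pava(y, w)
        oracle = sqp_isotonic(y, w)
        assert np.sum(w * (fit - y) ** 2) <= np.sum(w * (oracle - y) ** 2) + 1e-6
        assert np.all(np.diff(fit) >= -1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_weighted_mean_conserved(self, y):
        y = np.asarray(y)
        w = np.linspace(1, 2, y.size)
        fit = hp.pava(y, w)
        assert np.sum(w * fit) == pytest.approx(np.sum(w * y), abs=1e-9)

    def test_agrees_with_sklearn(self):
        from sklearn.isotonic import isotonic_regression

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=8)
            w = rng.uniform(0.5, 2.0, size=8)
            assert np.allclose(
                hp.pava(y, w), isotonic_regression(y, sample_weight=w), atol=1e-10
            )

    def test_down_direction_antitone(self):
        fit = hp.pava([1, 3, 2], direction="down")
        assert np.all(np.diff(fit) <= 1e-12)


def noiseless_profile():
    doses = np.repeat([0.0, 1.0, 3.0, 10.0], 3)
    y = np.repeat([0.0, 1.0, 2.0, 3.0], 3) + np.tile([-0.01, 0.0, 0.01], 4)
    return doses, y


class TestWilliamsTest:
    def test_strong_trend_minimal_p(self):
        doses, y = noiseless_profile()
        res = hp.williams_test(doses, y, n_perm=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501, rel=1e-9)
        assert res.direction == "up"

    def test_flat_profile_fails_fc_threshold(self):
        rng = np.random.default_rng(2)
        doses = np.repeat([0.0, 1.0, 3.0, 10.0], 4)
        y = rng.normal(0, 0.05, doses.size)
        res = hp.williams_test(doses, y, n_perm=200, seed=0)
        assert res.max_abs_fold_change < 2.0
        assert not res.passes

    def test_too_few_permutations_rejected(self):
        doses, y = noiseless_profile()
        with pytest.raises(ValueError, match="n_perm"):
            hp.williams_test(doses, y, n_perm=50)

    def test_statistic_shift_and_scale_invariant(self):
        doses, y = noiseless_profile()
        a = hp.williams_test(doses, y, n_perm=200, seed=3)
        b = hp.williams_test(doses, y + 7.5, n_perm=200, seed=3)
        c = hp.williams_test(doses, y * 3.0, n_perm=200, seed=3)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
        assert a.statistic == pytest.approx(c.statistic, rel=1e-9)
        assert a.p_value == b.p_value == c.p_value

    def test_down_trend_detected(self):
        doses, y = noiseless_profile()
        res = hp.williams_test(doses, -y, n_perm=200, seed=4)
        assert res.direction == "down"
        assert res.p_value == pytest.approx(1 / 201, rel=1e-9)

    def test_requires_control_group(self):
        with pytest.raises(ValueError, match="control"):
            hp.williams_test(np.repeat([1.0, 3.0, 10.0], 3), np.zeros(9),
                             n_perm=200)


class TestPrefilterModeA:
    def test_planted_responders_pass(self, planted_expr):
        table = hp.prefilter_mode_a(planted_expr, n_perm=300, seed=5)
        hits = table[(table["probe_id"] == "HILL_A") & table["passes"]]
        assert len(hits) == 2  # both runs
        assert (table[table["probe_id"] == "HILL_A"]["p_value"] < 0.05).all()

    def test_seeded_reproducibility(self, planted_expr):
        a = hp.prefilter_mode_a(planted_expr, n_perm=200, seed=6)
        b = hp.prefilter_mode_a(planted_expr, n_perm=200, seed=6)
        assert a.equals(b)

    def test_null_calibration_quick(self, design):
        """Rejection rate at alpha=0.05 near nominal on 400 null probes."""
        cm = hp.simulate_counts(design, [], n_null_probes=400,
                                mean_depth=3e5, seed=21)
        expr = hp.normalize(cm)
        meta = expr.sample_meta
        sel = meta[meta["run"] == "R1"]
        res = williams_batch(
            expr.values[sel.index].to_numpy(),
            sel["concentration"].to_numpy(),
            n_perm=400,
            seed=22,
        )
        rate = (res["p_value"] < 0.05).mean()
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 400) + 0.01


class TestPrefilterModeB:
    def test_steep_planted_responder_passes(self, design):
        # a steep responder whose first significant dose already exceeds
        # 2-fold: the LOTEL fold-change rule requires an abrupt onset
        resp = [hp.ResponderSpec("STEEP", "hill", true_bmc=30.0,
                                 max_fold_change=32.0, noise_sd=0.2)]
        cm = hp.simulate_counts(design, resp, n_null_probes=30,
                                mean_depth=3e5, seed=13, hill_h=6.0)
        expr = hp.normalize(cm)
        table = prefilter_mode_b(expr)
        by_probe = table.groupby("probe_id")["passes"].any()
        assert by_probe["STEEP"]
        # null probes pass at most sporadically; the planted one dominates
        assert by_probe.drop("STEEP").mean() < 0.5

    def test_flat_constant_profile_never_passes(self, design):
        cm = hp.simulate_counts(design, [], n_null_probes=20,
                                mean_depth=2e5, seed=9)
        expr = hp.normalize(cm)
        table = prefilter_mode_b(expr)
        # constant-ish null probes lack a 2-fold LOTEL
        assert table["passes"].mean() < 0.2
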