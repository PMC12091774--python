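import numpy as np
import pandas as pd
import pytest

from tvmi import clogit
from tvmi.clogit import NonIdentifiableError

from conftest import make_pair_table, naive_conditional_loglik, random_sets


class TestLikelihood:
    def test_null_loglik_is_minus_log_set_size(self):
        rng = np.random.default_rng(0)
        table = random_sets(rng, n_sets=1, n_cols=1, set_size=4)
        ll, _, _ = clogit.conditional_loglik([0.0], table, ["x0"])
        assert ll == pytest.approx(-np.log(4), abs=1e-12)

    def test_gradient_at_null_is_case_minus_set_mean(self):
        rng = np.random.default_rng(1)
        table = random_sets(rng, n_sets=12, n_cols=3, set_size=5)
        xcols = ["x0", "x1", "x2"]
        _, grad, _ = clogit.conditional_loglik(np.zeros(3), table, xcols)
        expected = np.zeros(3)
        for _, g in table.groupby("set_id"):
            X = g[xcols].to_numpy()
            expected += X[g["case"].to_numpy() == 1][0] - X.mean(axis=0)
        np.testing.assert_allclose(grad, expected, atol=1e-10)

    def test_analytic_derivatives_match_finite_differences(self):
        rng = np.random.default_rng(2)
        table = random_sets(rng, n_sets=15, n_cols=3, set_size=4)
        xcols = ["x0", "x1", "x2"]
        beta = rng.normal(0, 0.4, size=3)
        ll, grad, hess = clogit.conditional_loglik(beta, table, xcols)
        assert ll == pytest.approx(naive_conditional_loglik(beta, table, xcols))
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd = (
                naive_conditional_loglik(beta + e, table, xcols)
                - naive_conditional_loglik(beta - e, table, xcols)
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, abs=1e-6)
            _, gp, _ = clogit.conditional_loglik(beta + e, table, xcols)
            _, gm, _ = clogit.conditional_loglik(beta - e, table, xcols)
            np.testing.assert_allclose(hess[:, k], (gp - gm) / (2 * h), atol=1e-5)

    def test_likelihood_invariant_to_set_level_offsets(self):
        # adding any per-set constant to all linear predictors in a set
        # cancels in the conditional likelihood
        rng = np.random.default_rng(3)
        table = random_sets(rng, n_sets=10, n_cols=2, set_size=4)
        xcols = ["x0", "x1"]
        beta = np.array([0.5, -0.3])
        shifted = table.copy()
        offsets = dict(zip(shifted["set_id"].unique(), rng.normal(0, 5, 10)))
        # realise the offset through the design: shift x0 by c/beta0 per set
        shifted["x0"] = shifted["x0"] + shifted["set_id"].map(offsets) / beta[0]
        ll0, _, _ = clogit.conditional_loglik(beta, table, xcols)
        ll1, _, _ = clogit.conditional_loglik(beta, shifted, xcols)
        assert ll1 == pytest.approx(ll0, abs=1e-9)


class TestFit:
    def test_discordant_pairs_closed_form(self):
        table = make_pair_table(10, 5)
        res = clogit.fit(table, ["x"])
        assert res.converged
        assert res.params["x"] == pytest.approx(np.log(2), abs=1e-8)

    def test_uninformative_sets_dropped_and_counted(self):
        table = pd.concat(
            [
                make_pair_table(10, 5),
                pd.DataFrame(
                    {"set_id": [100, 100, 101, 101], "case": [1, 0, 1, 0],
                     "x": [1.0, 1.0, 0.0, 0.0]}
                ),
            ]
        )
        res = clogit.fit(table, ["x"])
        assert res.n_dropped == 2 and res.n_sets == 15
        assert res.params["x"] == pytest.approx(np.log(2), abs=1e-8)

    def test_all_sets_identical_rows_is_an_error(self):
        table = pd.DataFrame(
            {"set_id": [0, 0, 1, 1], "case": [1, 0, 1, 0], "x": [2.0, 2.0, 5.0, 5.0]}
        )
        with pytest.raises(NonIdentifiableError, match="no informative strata"):
            clogit.fit(table, ["x"])

    def test_set_constant_column_rejected_by_name(self):
        rng = np.random.default_rng(4)
        table = random_sets(rng, n_sets=10, n_cols=1, set_size=4)
        table["held"] = table["set_id"].astype(float)  # varies only between sets
        with pytest.raises(NonIdentifiableError, match="held"):
            clogit.fit(table, ["x0", "held"])

    def test_separation_flagged_not_silent(self):
        table = make_pair_table(12, 0)  # all discordant pairs favour the case
        res = clogit.fit(table, ["x"])
        assert not res.converged

    def test_weighted_fit_equals_duplicated_sets(self):
        rng = np.random.default_rng(5)
        base = random_sets(rng, n_sets=15, n_cols=2, set_size=4)
        dup = base[base["set_id"] < 5].copy()
        dup["set_id"] += 1000
        unweighted = clogit.fit(pd.concat([base, dup]), ["x0", "x1"])
        weighted = base.copy()
        weighted["weight"] = np.where(weighted["set_id"] < 5, 2.0, 1.0)
        res = clogit.fit(weighted, ["x0", "x1"])
        np.testing.assert_allclose(
            res.params, unweighted.params, rtol=0, atol=1e-8
        )
        np.testing.assert_allclose(res.cov, unweighted.cov, atol=1e-8)

    def test_covariance_symmetric_positive_definite(self):
        rng = np.random.default_rng(6)
        table = random_sets(rng, n_sets=40, n_cols=3, set_size=4)
        res = clogit.fit(table, ["x0", "x1", "x2"])
        C = res.cov.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(C) > 0)
        assert res.grad_norm < 1e-8

    def test_estimates_concentrate_around_truth_as_n_grows(self):
        """Correctly specified design: the focal-lag estimate stays within
        Wald error of truth at both cohort sizes and its SE shrinks."""
        import tvmi
        from tvmi.synth import smooth_lag_curve

        spec = tvmi.CrossbasisSpec()
        truth = tvmi.TrueEffect(upward_logor_by_lag=smooth_lag_curve(0, 0.009))
        results = {}
        for n in (5_000, 50_000):
            coh = tvmi.generate_cohort(truth=truth, n_events=n, seed=314)
            expo = tvmi.exposure_table_all(coh.temperature)
            ev = (
                coh.events.groupby(["area_id", "date"])
                .size()
                .rename("weight")
                .reset_index()
            )
            ev["event_id"] = np.arange(len(ev))
            table, _ = tvmi.build_matched_sets(ev, expo)
            table = tvmi.add_crossbasis(table, spec)
            fit = clogit.fit(table, spec.column_names())
            results[n] = tvmi.lag_effect(fit, spec, "up", 0)
        for n, eff in results.items():
            assert abs(eff.logor - 0.009) <= 4 * eff.se, n
        assert results[50_000].se < results[5_000].se

    def test_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(7)
        table = random_sets(rng, n_sets=100, n_cols=4, set_size=4)
        xcols = [f"x{k}" for k in range(4)]
        ours = clogit.fit(table, xcols)
        ref = ConditionalLogit(
            table["case"], table[xcols], groups=table["set_id"]
        ).fit(disp=False, method="newton", tol=1e-10)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-6)
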