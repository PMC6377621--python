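import numpy as np
import pandas as pd
import pytest

from polarscape.sem import (
    builtin_model,
    fit_ml,
    implied_covariance,
    net_effects,
    parse_model,
    predict_richness,
    residual_covariance,
    simulate,
    total_effects,
)
from polarscape.sem.effects import collapsed_paths
from polarscape.sem.model import ModelSyntaxError

from oracles import (
    closed_form_recursive_ml,
    path_enumeration_total_effects,
    random_recursive_model,
)


class TestParse:
    def test_single_path_counts(self):
        m = parse_model("y <- x")
        assert m.df == 0
        assert {q.name for q in m.parameters} == {"y~x", "psi(y)", "var(x)"}

    def test_cycle_rejected(self):
        with pytest.raises(ModelSyntaxError, match="cycle"):
            parse_model("y <- x\nx <- y")

    def test_self_loop_rejected(self):
        with pytest.raises(ModelSyntaxError, match="cycle"):
            parse_model("y <- y")

    def test_duplicate_path_rejected(self):
        with pytest.raises(ModelSyntaxError, match="duplicate"):
            parse_model("y <- x\ny <- x")

    def test_unknown_variables_in_covariance(self):
        with pytest.raises(ModelSyntaxError, match="unknown variable"):
            parse_model("y <- x\np ~~ q")

    def test_fixed_coefficient(self):
        m = parse_model("y <- 0.5*x")
        assert all(q.name != "y~x" for q in m.parameters)

    def test_final_2019_df_35(self):
        m = builtin_model("final_2019")
        assert m.df == 35
        assert m.n_observed == 14
        assert set(m.composites) == {"space_cyano", "space_fungal", "space_multi"}

    def test_composite_cannot_receive_paths(self):
        with pytest.raises(ModelSyntaxError, match="composite"):
            parse_model("composite c <= 1*a + b\nc <- d")

    def test_exogenous_covariances_free_by_default(self):
        m = parse_model("y <- a + b")
        assert any(q.name == "a~~b" for q in m.parameters)


class TestFitML:
    def test_saturated_model_zero_chi2(self, rng):
        data = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        m = parse_model("a ~~ b\na ~~ c\nb ~~ c")
        fit = fit_ml(m, data)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        np.testing.assert_allclose(fit.sigma, fit.S, atol=1e-8)

    def test_single_path_equals_ols_and_r(self, rng):
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_ml(parse_model("y <- x"), data)
        ols = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.param("y~x") == pytest.approx(ols, abs=1e-8)
        assert fit.param("y~x", standardized=True) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-8
        )

    def test_standardized_equals_raw_on_standardized_data(self, rng):
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        data = pd.DataFrame({"x": x / x.std(ddof=1), "y": y / y.std(ddof=1)})
        fit = fit_ml(parse_model("y <- x"), data)
        # same up to the implied-variance scaling (exactly equal at the optimum)
        assert fit.param("y~x") == pytest.approx(fit.param("y~x", standardized=True), abs=1e-6)

    def test_missing_columns_rejected(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=50)})
        with pytest.raises(ValueError, match="lacks"):
            fit_ml(parse_model("y <- x"), data)

    def test_listwise_deletion(self, rng):
        data = pd.DataFrame(rng.normal(size=(80, 2)), columns=["x", "y"])
        data.loc[3, "x"] = np.nan
        fit = fit_ml(parse_model("y <- x"), data)
        assert fit.n == 79

    def test_oracle_equivalence_small_models(self, rng):
        # iterative fitter vs closed-form recursive-OLS route, 15 random models
        for k in range(15):
            nv = int(rng.integers(3, 7))
            text, _ = random_recursive_model(rng, nv)
            model = parse_model(text)
            data = pd.DataFrame(
                rng.normal(size=(150, nv)) @ rng.normal(size=(nv, nv)) * 0.4
                + rng.normal(size=(150, nv)),
                columns=[f"v{i}" for i in range(nv)],
            )
            fit = fit_ml(model, data[model.observed], compute_se=False)
            f_ref, sigma_ref = closed_form_recursive_ml(model, fit.S)
            assert fit.F_ML == pytest.approx(f_ref, abs=1e-8)
            np.testing.assert_allclose(fit.sigma, sigma_ref, atol=2e-5)

    def test_chi2_distribution_under_truth(self, truth):
        # parametric simulation: mean of chi2 ~ df for data from the true model
        chis = []
        values = truth.param_values()
        rng = np.random.default_rng(11)
        for _ in range(40):
            data = simulate(truth.model, values, 490, rng)
            fit = fit_ml(truth.model, data, compute_se=False)
            chis.append(fit.chi2)
        mean = np.mean(chis)
        assert abs(mean - 35) < 3 * np.sqrt(2 * 35 / len(chis))

    def test_cfi_bounds(self, rng):
        x = rng.normal(size=300)
        y = 0.8 * x + 0.3 * rng.normal(size=300)
        fit = fit_ml(parse_model("y <- x"), pd.DataFrame({"x": x, "y": y}))
        assert 0.0 <= fit.cfi <= 1.0
        assert fit.cfi == pytest.approx(1.0, abs=1e-6)  # df = 0 -> CFI ~ 1

    def test_standard_errors_reasonable(self, rng):
        x = rng.normal(size=400)
        y = 0.5 * x + rng.normal(size=400)
        fit = fit_ml(parse_model("y <- x"), pd.DataFrame({"x": x, "y": y}))
        # OLS slope SE ~ sd(resid)/ (sd(x) sqrt(n))
        expected = 1.0 / np.sqrt(400)
        assert fit.se["y~x"] == pytest.approx(expected, rel=0.25)


class TestEffects:
    def _chain_fit(self, rng, a=0.5, b=0.4, c=0.3):
        n = 4000
        x = rng.normal(size=n)
        m = a * x + rng.normal(size=n) * 0.7
        y = b * m + c * x + rng.normal(size=n) * 0.7
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        return fit_ml(parse_model("m <- x\ny <- m + x"), data)

    def test_two_path_sum_of_products(self, rng):
        fit = self._chain_fit(rng)
        eff = total_effects(fit, standardized=False)
        row = eff[(eff.source == "x") & (eff.outcome == "y")].iloc[0]
        a = fit.param("m~x")
        b = fit.param("y~m")
        c = fit.param("y~x")
        assert row.total == pytest.approx(c + a * b, abs=1e-10)
        assert row.direct == pytest.approx(c)
        assert row.indirect == pytest.approx(a * b, abs=1e-10)

    def test_total_equals_direct_plus_indirect_everywhere(self, rng):
        fit = self._chain_fit(rng)
        eff = total_effects(fit)
        np.testing.assert_allclose(eff.total, eff.direct + eff.indirect, atol=1e-12)

    def test_path_enumeration_oracle_random_dags(self, rng):
        for _ in range(25):
            nv = int(rng.integers(3, 7))
            p = nv
            b = np.zeros((p, p))
            for j in range(1, p):
                for i in range(j):
                    if rng.random() < 0.5:
                        b[j, i] = rng.normal()
            total = np.linalg.inv(np.eye(p) - b) - np.eye(p)
            ref = path_enumeration_total_effects(b)
            np.testing.assert_allclose(total, ref, atol=1e-10)

    def test_no_self_effect(self, rng):
        fit = self._chain_fit(rng)
        eff = total_effects(fit)
        assert not ((eff.source == eff.outcome).any())

    def test_collapsed_composite_paths(self, truth):
        rng = np.random.default_rng(5)
        data = simulate(truth.model, truth.param_values(), 3000, rng)
        fit = fit_ml(truth.model, data, compute_se=False)
        B = collapsed_paths(fit, standardized=True)
        # composite route: s1 -> cyano_s collapsed coefficient near truth
        assert B.loc["cyano_s", "s1"] == pytest.approx(
            truth.path_coefficients[("s1", "cyano_s")], abs=0.08
        )


class TestNetEffects:
    def test_structural_zero_for_cyano_biotic(self, truth):
        rng = np.random.default_rng(6)
        data = simulate(truth.model, truth.param_values(), 1000, rng)
        fit = fit_ml(truth.model, data, compute_se=False)
        net = net_effects(fit)
        assert net.loc["cyano_s", "biotic"] == 0.0
        assert ((net >= 0) & (net <= 1)).all().all()

    def test_single_cause_composite_equals_std_path(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_ml(parse_model("y <- x"), data)
        net = net_effects(fit, groups={"y": {"abiotic": ["x"]}})
        assert net.loc["y", "abiotic"] == pytest.approx(
            abs(fit.param("y~x", standardized=True)), abs=1e-9
        )

    def test_recovers_truth(self, truth):
        rng = np.random.default_rng(7)
        nets = []
        for _ in range(10):
            data = simulate(truth.model, truth.param_values(), 490, rng)
            fit = fit_ml(truth.model, data, compute_se=False)
            nets.append(net_effects(fit).to_numpy())
        mean_net = np.mean(nets, axis=0)
        np.testing.assert_allclose(mean_net, truth.net_effects().to_numpy(), atol=0.05)


class TestResidualCovariance:
    def test_saturated_zero(self, rng):
        data = pd.DataFrame(rng.normal(size=(150, 2)), columns=["a", "b"])
        fit = fit_ml(parse_model("a ~~ b"), data)
        res = residual_covariance(fit)
        np.testing.assert_allclose(res["residual"].to_numpy(), 0.0, atol=1e-7)

    def test_symmetric(self, truth):
        rng = np.random.default_rng(8)
        data = simulate(truth.model, truth.param_values(), 300, rng)
        fit = fit_ml(truth.model, data, compute_se=False)
        r = residual_covariance(fit)["residual"].to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)

    def test_missing_path_flagged(self, rng):
        # true model has y <- x + z; fitted model omits the strong z path
        n = 1500
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            x = r.normal(size=n)
            z = r.normal(size=n)
            y = 0.3 * x + 0.6 * z + r.normal(size=n) * 0.6
            data = pd.DataFrame({"x": x, "z": z, "y": y})
            fit = fit_ml(parse_model("y <- x\nz ~~ x"), data, compute_se=False)
            top = residual_covariance(fit)["largest"][0]
            if {top[0], top[1]} == {"z", "y"}:
                hits += 1
        assert hits >= 18

    def test_simulate_matches_implied(self, truth):
        rng = np.random.default_rng(9)
        data = simulate(truth.model, truth.param_values(), 20000, rng)
        S = np.cov(data.to_numpy(), rowvar=False)
        theta = np.array([truth.param_values()[q.name] for q in truth.model.parameters])
        sigma = implied_covariance(truth.model, theta)
        obs = truth.model.observed_index
        np.testing.assert_allclose(S, sigma[np.ix_(obs, obs)], atol=0.06)


class TestPredict:
    def test_in_sample_identity(self, rng):
        n = 400
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n) * 0.8
        y = 0.4 * m + rng.normal(size=n) * 0.8
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = fit_ml(parse_model("m <- x\ny <- m"), data)
        pred = predict_richness(fit, data)
        beta_mx = fit.param("m~x")
        expected_m = fit.means["m"] + beta_mx * (x - fit.means["x"])
        np.testing.assert_allclose(pred["m"], expected_m, atol=1e-8)
        # mediator propagated, not observed m
        np.testing.assert_allclose(
            pred["y"], fit.means["y"] + fit.param("y~m") * (expected_m - fit.means["m"]),
            atol=1e-8,
        )

    def test_missing_predictor_named(self, rng):
        data = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        fit = fit_ml(parse_model("y <- x"), data)
        with pytest.raises(ValueError, match="x"):
            predict_richness(fit, pd.DataFrame({"z": [1.0]}))

    def test_r2_matches_squared_correlation(self, rng):
        n = 600
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n) * 0.5
        data = pd.DataFrame({"x": x, "y": y})
        fit = fit_ml(parse_model("y <- x"), data)
        pred = predict_richness(fit, data)
        r2_pred = np.corrcoef(pred["y"], y)[0, 1] ** 2
        assert r2_pred == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)


class TestConsistency:
    @pytest.mark.parametrize("n", [100, 400, 1600])
    def test_bias_shrinks_with_n(self, truth, n):
        rng = np.random.default_rng(100 + n)
        values = truth.param_values()
        errs = []
        for _ in range(8):
            data = simulate(truth.model, values, n, rng)
            fit = fit_ml(truth.model, data, compute_se=False)
            errs.append(abs(fit.param("fungal_s~cyano_s") - values["fungal_s~cyano_s"]))
        assert np.mean(errs) < 1.5 / np.sqrt(n) + 0.05
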