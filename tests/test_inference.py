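"""Hierarchical fit: likelihood, recovery, Wald screening, AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ttemeta.families import survival_natural
from ttemeta.inference import (
    FitOptions,
    PopulationModel,
    aic,
    fit,
    marginal_loglik,
    observations_from_curve,
    predict_survival,
    se_weights,
    select_model,
    wald_test,
)
from ttemeta.synthetic import generate_observations


class TestSEWeights:
    def test_closed_forms(self):
        assert se_weights(0.5, 100) == pytest.approx(0.05)
        assert se_weights(0.9, 279) == pytest.approx(math.sqrt(0.09 / 279), rel=1e-9)

    def test_floor_rule(self):
        # 0.999 is clamped to 0.995 before weighting
        assert se_weights(0.999, 100) == pytest.approx(
            math.sqrt(0.995 * 0.005 / 100), rel=1e-12
        )
        assert se_weights(0.0, 50) == pytest.approx(math.sqrt(0.005 * 0.995 / 50))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            se_weights(0.5, 0)


class TestPredictSurvival:
    MODEL = PopulationModel("weibull", 41.69, 2.25, {"race_nonasian": 0.19}, 0.44, 0.54)

    def test_identity_chain(self):
        s = predict_survival(self.MODEL, None, {"race_nonasian": 0}, 41.69)
        assert float(s) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_covariate_scales_te(self):
        te, _ = self.MODEL.study_params({"race_nonasian": 1})
        assert te == pytest.approx(41.69 * math.exp(0.19), rel=1e-12)
        s = predict_survival(self.MODEL, None, {"race_nonasian": 1}, te)
        assert float(s) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_random_effect_scales_te(self):
        te, _ = self.MODEL.study_params(None, eta_te=0.44)
        assert te / 41.69 == pytest.approx(math.exp(0.44), rel=1e-12)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            predict_survival(self.MODEL, None, {"ecog": 1}, 10.0)


class TestMarginalLoglik:
    def test_zero_omega_single_perfect_obs(self):
        m = PopulationModel("weibull", 40.0, 2.0, {}, 0.0, 0.0, 1.0)
        t = 20.0
        pred = float(survival_natural("weibull", t, 40.0, 2.0))
        n = 150
        data = pd.DataFrame(
            [{"study_id": "a", "time": t, "obs": pred, "n_at_risk": n}]
        )
        se = float(se_weights(pred, n))
        expected = -math.log(se * math.sqrt(2 * math.pi))
        assert marginal_loglik(m, data) == pytest.approx(expected, rel=1e-10)

    def test_sigma_doubling_closed_form(self):
        m1 = PopulationModel("weibull", 40.0, 2.0, {}, 0.0, 0.0, 1.0)
        m2 = PopulationModel("weibull", 40.0, 2.0, {}, 0.0, 0.0, 2.0)
        data, _ = generate_observations(m1, n_studies=3, seed=5)
        ll1 = marginal_loglik(m1, data)
        ll2 = marginal_loglik(m2, data)
        # residual sum of squares in SE units
        pred = survival_natural("weibull", data["time"], 40.0, 2.0)
        se = se_weights(data["obs"], data["n_at_risk"])
        rss = float((((data["obs"] - pred) / se) ** 2).sum())
        n = len(data)
        expected_delta = -n * math.log(2.0) + 0.5 * rss * (1 - 1 / 4)
        assert ll2 - ll1 == pytest.approx(expected_delta, rel=1e-9)

    def test_quadrature_matches_brute_force_trapezoid(self):
        """AGQ vs dense 2-D trapezoid integration on a 2-study toy set."""
        m = PopulationModel("loglogistic", 25.0, 3.0, {}, 0.4, 0.3, 1.2)
        data, _ = generate_observations(
            m, n_studies=2, times=np.array([6.0, 12.0, 18.0, 24.0, 30.0]),
            arm_size=120, seed=9,
        )
        ll_agq = marginal_loglik(m, data, n_nodes=15)

        # brute force per study
        se = se_weights(data["obs"], data["n_at_risk"])
        total = 0.0
        grid = np.linspace(-2.0, 2.0, 401)
        for sid in data["study_id"].unique():
            sub = data[data["study_id"] == sid]
            s_se = se[sub.index.to_numpy()]
            E1, E2 = np.meshgrid(grid, grid, indexing="ij")
            te = 25.0 * np.exp(E1)[..., None]
            p = 3.0 * np.exp(E2)[..., None]
            pred = survival_natural("loglogistic", sub["time"].to_numpy(), te, p)
            r = sub["obs"].to_numpy() - pred
            var = (1.2 * s_se) ** 2
            loglik = (-0.5 * (r**2 / var + np.log(2 * np.pi * var))).sum(axis=-1)
            prior = norm.logpdf(E1, scale=0.4) + norm.logpdf(E2, scale=0.3)
            integrand = np.exp(loglik + prior)
            val = np.trapezoid(np.trapezoid(integrand, grid, axis=1), grid)
            total += math.log(val)
        assert ll_agq == pytest.approx(total, abs=1e-4)

    def test_nonpositive_sigma_flagged(self):
        m = PopulationModel("weibull", 40.0, 2.0, {}, 0.0, 0.0, 1.0)
        m.sigma = 0.0
        data, _ = generate_observations(m, n_studies=2, seed=1)
        with pytest.raises(ValueError):
            marginal_loglik(m, data)


class TestFit:
    def test_recovery_20_studies(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.3, 0.3, 1.0)
        data, _ = generate_observations(truth, n_studies=20, seed=11)
        f = fit("weibull", data)
        assert f.converged
        assert f.estimates["te_pop"] == pytest.approx(40.0, rel=0.10)
        assert f.estimates["p_pop"] == pytest.approx(2.2, rel=0.15)

    def test_omega_boundary_recovery(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.0, 0.0, 1.0)
        data, _ = generate_observations(truth, n_studies=12, seed=13)
        f = fit("weibull", data)
        assert f.estimates["omega_te"] < 0.05

    def test_deterministic_refit(self):
        truth = PopulationModel("loglogistic", 27.0, 3.5, {}, 0.4, 0.4, 1.0)
        data, _ = generate_observations(truth, n_studies=8, seed=3)
        f1 = fit("loglogistic", data)
        f2 = fit("loglogistic", data)
        assert f1.estimates == f2.estimates
        assert f1.minus2ll == f2.minus2ll

    def test_rse_definition(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.3, 0.3, 1.0)
        data, _ = generate_observations(truth, n_studies=10, seed=17)
        f = fit("weibull", data)
        for name, est in f.estimates.items():
            if f.se[name] is not None:
                assert f.rse_percent[name] == pytest.approx(
                    100 * f.se[name] / abs(est)
                )


class TestWald:
    def test_table_value(self):
        # theta=0.19 at 50% RSE: se=0.095, z=2.0
        res = wald_test(0.19, 0.095)
        assert res["z"] == pytest.approx(2.0)
        assert res["p_value"] == pytest.approx(0.0455, abs=2e-4)
        assert res["p_value"] < 0.05

    def test_null_estimate(self):
        assert wald_test(0.0, 1.0)["p_value"] == pytest.approx(1.0)

    def test_borderline(self):
        assert wald_test(1.96, 1.0)["p_value"] == pytest.approx(0.05, abs=1e-3)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestModelSelection:
    @staticmethod
    def _dummy_fit(aic_val, k, data_hash="h"):
        import pandas as pd

        from ttemeta.inference import FitResult

        return FitResult(
            model=PopulationModel("weibull", 40, 2.2),
            estimates={}, se={}, rse_percent={},
            minus2ll=aic_val - 2 * k, aic=aic_val, n_params=k,
            study_effects=pd.DataFrame(), converged=True, n_iter=1,
            final_grad_norm=0.0, data_hash=data_hash, n_obs=10,
        )

    def test_aic_identity(self):
        f = self._dummy_fit(110.0, 5)
        assert aic(f) == pytest.approx(110.0)
        assert f.minus2ll == pytest.approx(100.0)

    def test_tie_prefers_fewer_parameters(self):
        a = self._dummy_fit(100.0, 6)
        b = self._dummy_fit(100.0, 5)
        assert select_model([a, b]) is b

    def test_different_data_rejected(self):
        a = self._dummy_fit(100.0, 5, "h1")
        b = self._dummy_fit(90.0, 5, "h2")
        with pytest.raises(ValueError):
            select_model([a, b])

    def test_k_audit_with_covariates(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {"x": 0.3}, 0.3, 0.3, 1.0)
        rngx = np.random.default_rng(5)
        covv = {"x": rngx.uniform(0, 1, 10)}
        data, cov = generate_observations(truth, n_studies=10, cov_values=covv, seed=19)
        f0 = fit("weibull", data, cov)
        f1 = fit("weibull", data, cov, covariates=["x"])
        assert f1.n_params == f0.n_params + 1
        assert f1.data_hash == f0.data_hash


def test_observations_from_curve_interpolates_risk(bundle):
    arm = bundle["arms"]["flaura_like"]
    obs = observations_from_curve(arm["curve"])
    assert (obs["time"] > 0).all()
    assert obs["obs"].between(0.005, 0.995).all()
    rt = arm["curve"].risk_times
    nr = arm["curve"].n_at_risk
    j = len(rt) // 2
    mid = 0.5 * (rt[j] + rt[j + 1])
    row = obs.iloc[(obs["time"] - mid).abs().argmin()]
    expected = np.interp(row["time"], rt, nr.astype(float))
    assert row["n_at_risk"] == pytest.approx(expected)
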