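"""Scenario Monte Carlo, landmark rates, VPC and GOF diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from ttemeta.inference import PopulationModel, fit
from ttemeta.simulate import (
    SimulationScenario,
    Stratum,
    gof,
    landmark_rate,
    simulate_scenario,
    vpc,
)
from ttemeta.synthetic import generate_observations

ALL = [Stratum("all", 1.0)]


def _scenario(model, **kw):
    defaults = dict(strata=ALL, n_replicates=300, subjects_per_replicate=2000, seed=7)
    defaults.update(kw)
    return SimulationScenario(model=model, **defaults)


class TestSimulateScenario:
    def test_loglogistic_median_matches_analytic(self):
        m = PopulationModel("loglogistic", 27.47, 3.5, {}, 0.0, 0.0)
        s = simulate_scenario(_scenario(m))
        assert s.median == pytest.approx(27.47, rel=0.02)

    def test_weibull_median_matches_analytic(self):
        m = PopulationModel("weibull", 41.69, 2.25, {}, 0.0, 0.0)
        s = simulate_scenario(_scenario(m, subjects_per_replicate=10_000, n_replicates=100))
        assert s.median == pytest.approx(41.69 * math.log(2) ** (1 / 2.25), rel=0.02)

    def test_same_seed_identical_summary(self):
        m = PopulationModel("weibull", 41.69, 2.25, {}, 0.44, 0.54)
        s1 = simulate_scenario(_scenario(m, n_replicates=50, subjects_per_replicate=200))
        s2 = simulate_scenario(_scenario(m, n_replicates=50, subjects_per_replicate=200))
        assert s1.median == s2.median
        assert s1.landmark_rates == s2.landmark_rates
        np.testing.assert_array_equal(s1.band_50, s2.band_50)

    def test_ci_width_shrinks_with_cohort_size(self):
        m = PopulationModel("weibull", 40.0, 2.2, {}, 0.0, 0.0)
        widths = []
        for n in (50, 2000):
            acc = 0.0
            for seed in (1, 2, 3):
                s = simulate_scenario(
                    _scenario(m, n_replicates=150, subjects_per_replicate=n, seed=seed)
                )
                acc += s.median_ci[1] - s.median_ci[0]
            widths.append(acc / 3)
        assert widths[1] < widths[0]

    def test_landmark_rates_nonincreasing_and_bands_ordered(self):
        m = PopulationModel("loglogistic", 18.03, 5.88, {}, 0.8, 0.81)
        s = simulate_scenario(_scenario(m, n_replicates=100, subjects_per_replicate=300))
        vals = [s.landmark_rates[t] for t in sorted(s.landmark_rates)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert np.all(s.band_10 <= s.band_50 + 1e-12)
        assert np.all(s.band_50 <= s.band_90 + 1e-12)

    def test_bad_weights_rejected(self):
        m = PopulationModel("weibull", 40.0, 2.2)
        with pytest.raises(ValueError):
            SimulationScenario(model=m, strata=[Stratum("a", 0.7)])


class TestLandmarkRate:
    MIX = [
        Stratum("asian", 0.62, {"race_nonasian": 0.0}),
        Stratum("nonasian", 0.38, {"race_nonasian": 1.0}),
    ]
    MODEL = PopulationModel("weibull", 41.69, 2.25, {"race_nonasian": 0.19}, 0.44, 0.54)

    def test_t_zero_is_one(self):
        assert landmark_rate(self.MODEL, self.MIX, 0.0) == pytest.approx(1.0)

    def test_closed_form_without_variability(self):
        m = PopulationModel("weibull", 41.69, 2.25, {}, 0.0, 0.0)
        r = landmark_rate(m, ALL, 36.0, with_random_effects=False)
        assert r == pytest.approx(math.exp(-((36.0 / 41.69) ** 2.25)), rel=1e-12)
        assert r == pytest.approx(0.487, abs=0.001)

    def test_mixture_is_weighted_average_when_omega_zero(self):
        m = PopulationModel("weibull", 41.69, 2.25, {"race_nonasian": 0.19}, 0.0, 0.0)
        r_mix = landmark_rate(m, self.MIX, 36.0)
        r_a = landmark_rate(m, [Stratum("a", 1.0, {"race_nonasian": 0.0})], 36.0)
        r_n = landmark_rate(m, [Stratum("n", 1.0, {"race_nonasian": 1.0})], 36.0)
        assert r_mix == pytest.approx(0.62 * r_a + 0.38 * r_n, rel=1e-12)

    def test_variability_lifts_the_tail(self):
        # averaging survival over lognormal study effects raises the far tail
        r_no = landmark_rate(self.MODEL, self.MIX, 60.0, with_random_effects=False)
        r_yes = landmark_rate(self.MODEL, self.MIX, 60.0, n_draws=50_000, seed=4)
        assert r_yes > r_no


class TestVPC:
    def test_self_simulated_calibration(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.3, 0.3, 1.0)
        data, _ = generate_observations(truth, n_studies=15, seed=23)
        f = fit("weibull", data)
        rep = vpc(f, data, n_sim=300, seed=1)
        assert rep.fraction_in_band >= 0.70

    def test_misspecified_model_fits_worse(self):
        truth = PopulationModel("weibull", 40.0, 1.0, {}, 0.05, 0.05, 1.0)
        data, _ = generate_observations(
            truth, n_studies=10, times=np.linspace(2, 80, 16), seed=29
        )
        good = vpc(truth, data, n_sim=200, seed=2)
        wrong = PopulationModel("loglogistic", 30.0, 4.5, {}, 0.05, 0.05, 1.0)
        bad = vpc(wrong, data, n_sim=200, seed=2)
        assert bad.fraction_in_band < good.fraction_in_band

    def test_single_replicate_degenerate_bands(self):
        m = PopulationModel("weibull", 40.0, 2.2, {}, 0.2, 0.2, 1.0)
        data, _ = generate_observations(m, n_studies=3, seed=31)
        rep = vpc(m, data, n_sim=1, seed=3)
        np.testing.assert_array_equal(rep.table["sim_p10"], rep.table["sim_p90"])


class TestGOF:
    def test_near_noiseless_data_r2(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.0, 0.0, 1e-4)
        data, _ = generate_observations(truth, n_studies=5, seed=37)
        table, summary = gof(truth, data)
        assert summary["r2"] >= 0.999

    def test_model_vs_own_predictions_zero_residuals(self):
        m = PopulationModel("weibull", 41.69, 2.25, {}, 0.0, 0.0, 1.0)
        data, _ = generate_observations(
            PopulationModel("weibull", 41.69, 2.25, {}, 0.0, 0.0, 1e-9),
            n_studies=2, times=np.linspace(9.0, 39.0, 11), seed=41,
        )
        table, summary = gof(m, data)
        assert summary["max_abs_residual"] < 1e-6

    def test_weighted_residuals_are_gaussian(self):
        truth = PopulationModel("weibull", 40.0, 2.2, {}, 0.0, 0.0, 1.0)
        data, _ = generate_observations(truth, n_studies=20, seed=43)
        table, _ = gof(truth, data)
        # under the true model, (obs-pred)/SE ~ N(0, sigma=1)
        res = kstest(table["weighted_residual"], "norm").pvalue
        assert res > 0.01
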