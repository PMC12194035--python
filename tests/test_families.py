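"""Closed-form hazard/survival math and the Te/p parameterization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ttemeta.families import (
    HazardParameters,
    NaturalParameters,
    cumulative_hazard,
    from_natural,
    hazard,
    quantile,
    quantile_natural,
    sample_event_times,
    survival,
    survival_natural,
    to_natural,
)

FAMILIES = ["weibull", "gompertz", "loglogistic"]

# (family, lam, gam) grid spanning increasing, flat-ish and decreasing hazards
PARAM_GRID = [
    ("weibull", 0.01, 2.5),
    ("weibull", 0.05, 1.0),
    ("weibull", 0.2, 0.7),
    ("gompertz", 0.01, 0.08),
    ("gompertz", 0.05, 0.01),
    ("loglogistic", 1 / 27.47, 3.5),
    ("loglogistic", 0.1, 0.9),
]


@pytest.mark.parametrize(
    "family, lam, gam, t, expected",
    [
        ("weibull", 1.0, 1.0, 5.0, 1.0),  # exponential limit
        ("gompertz", 0.1, 1e-13, 7.3, 0.1),  # gam -> 0 constant hazard
        ("loglogistic", 0.5, 2.0, 2.0, 0.5),  # 0.5*2*1/(1+1)
    ],
)
def test_hazard_closed_forms(family, lam, gam, t, expected):
    hp = HazardParameters(family, lam, gam)
    assert hazard(hp, t) == pytest.approx(expected, rel=1e-9)


def test_hazard_rejects_bad_times():
    hp = HazardParameters("weibull", 0.01, 2.0)
    with pytest.raises(ValueError):
        hazard(hp, -1.0)
    with pytest.raises(ValueError):
        hazard(hp, float("nan"))


@pytest.mark.parametrize("family, lam, gam", PARAM_GRID)
def test_survival_matches_integrated_hazard(family, lam, gam):
    """exp(-integral of h) equals the closed form to 1e-6 relative."""
    hp = HazardParameters(family, lam, gam)
    for t in (0.5, 5.0, 20.0, 45.0):
        H_num, _ = quad(lambda u: hazard(hp, u), 0, t, limit=200)
        assert survival(hp, t) == pytest.approx(math.exp(-H_num), rel=1e-6)


@pytest.mark.parametrize("family, lam, gam", PARAM_GRID)
def test_survival_basic_shape(family, lam, gam):
    hp = HazardParameters(family, lam, gam)
    t = np.linspace(0, 120, 200)
    S = survival(hp, t)
    assert S[0] == 1.0
    assert np.all(np.diff(S) <= 1e-15)
    assert S[-1] < 0.5  # decays over a long enough horizon
    assert np.all(hazard(hp, t[1:]) >= 0)


def test_characteristic_time_level():
    """S(Te) = exp(-1) for Weibull/Gompertz; = 0.5 for log-logistic."""
    w = NaturalParameters("weibull", 41.69, 2.25)
    assert survival(w, 41.69) == pytest.approx(math.exp(-1), rel=1e-12)
    g = NaturalParameters("gompertz", 30.0, 0.05)
    assert survival(g, 30.0) == pytest.approx(math.exp(-1), rel=1e-9)
    ll = NaturalParameters("loglogistic", 27.47, 3.5)
    assert survival(ll, 27.47) == pytest.approx(0.5, rel=1e-12)


def test_exponential_limits():
    """Weibull gam=1 and Gompertz gam->0+ reduce to S = exp(-lam t)."""
    t = np.linspace(0.1, 50, 40)
    lam = 0.03
    S_w = survival(HazardParameters("weibull", lam, 1.0), t)
    S_g = survival(HazardParameters("gompertz", lam, 1e-8), t)
    S_exp = np.exp(-lam * t)
    np.testing.assert_allclose(S_w, S_exp, rtol=1e-12)
    np.testing.assert_allclose(S_g, S_exp, rtol=1e-6)


@pytest.mark.parametrize(
    "family, Te, p, q, expected",
    [
        ("loglogistic", 10.31, 5.92, 0.5, 10.31),  # median equals Te
        ("weibull", 41.69, 2.25, 0.5, 41.69 * math.log(2) ** (1 / 2.25)),
    ],
)
def test_quantile_medians(family, Te, p, q, expected):
    npar = NaturalParameters(family, Te, p)
    assert quantile(npar, q) == pytest.approx(expected, rel=1e-9)


def test_quantile_at_exp_minus_one_returns_te():
    for family, Te, p in [("weibull", 41.69, 2.25), ("gompertz", 25.0, 0.06)]:
        npar = NaturalParameters(family, Te, p)
        assert quantile(npar, math.exp(-1)) == pytest.approx(Te, rel=1e-8)


@pytest.mark.parametrize("family, lam, gam", PARAM_GRID)
def test_quantile_survival_mutual_inverses(family, lam, gam):
    hp = HazardParameters(family, lam, gam)
    q = np.array([0.01, 0.1, 0.3679, 0.5, 0.9, 0.99])
    t = quantile(hp, q)
    np.testing.assert_allclose(survival(hp, t), q, rtol=1e-8)


def test_quantile_rejects_out_of_range():
    hp = HazardParameters("weibull", 0.01, 2.0)
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            quantile(hp, bad)


class TestSampling:
    def test_empirical_median(self):
        npar = NaturalParameters("weibull", 40.0, 2.0)
        t = sample_event_times(npar, 10_000, rng=7)
        expected = 40.0 * math.log(2) ** 0.5
        assert np.median(t) == pytest.approx(expected, rel=0.02)

    def test_empirical_survival_at_te(self):
        npar = NaturalParameters("weibull", 40.0, 2.0)
        n = 10_000
        t = sample_event_times(npar, n, rng=7)
        frac = (t > 40.0).mean()
        e1 = math.exp(-1)
        assert abs(frac - e1) < 3 * math.sqrt(e1 * (1 - e1) / n)

    def test_single_draw_and_determinism(self):
        npar = NaturalParameters("loglogistic", 27.47, 3.5)
        one = sample_event_times(npar, 1, rng=0)
        assert one.shape == (1,) and one[0] > 0 and np.isfinite(one[0])
        a = sample_event_times(npar, 500, rng=42)
        b = sample_event_times(npar, 500, rng=42)
        np.testing.assert_array_equal(a, b)


class TestParameterizationRoundTrip:
    def test_weibull_known_values(self):
        hp = HazardParameters("weibull", 41.69 ** (-2.25), 2.25)
        npar = to_natural(hp)
        assert npar.Te == pytest.approx(41.69, rel=1e-10)
        assert npar.p == pytest.approx(2.25)

    def test_loglogistic_te_is_reciprocal_lam(self):
        npar = to_natural(HazardParameters("loglogistic", 1 / 27.47, 3.5))
        assert npar.Te == pytest.approx(27.47, rel=1e-12)

    def test_gompertz_te_solves_unit_cumhaz(self):
        npar = to_natural(HazardParameters("gompertz", 0.02, 0.07))
        assert cumulative_hazard(NaturalParameters("gompertz", npar.Te, npar.p), npar.Te) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_random_round_trips(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            family = FAMILIES[rng.integers(3)]
            lam = float(10 ** rng.uniform(-3, -0.5))
            gam = float(10 ** rng.uniform(-1.2, 0.6))
            hp = HazardParameters(family, lam, gam)
            back = from_natural(to_natural(hp))
            worst = max(
                worst,
                abs(back.lam - hp.lam) / hp.lam,
                abs(back.gam - hp.gam) / hp.gam,
            )
        assert worst < 1e-10


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(FAMILIES),
    Te=st.floats(5.0, 80.0),
    p=st.floats(0.5, 6.0),
    t=st.floats(0.0, 120.0),
)
def test_vectorized_kernels_agree_with_scalar_path(family, Te, p, t):
    npar = NaturalParameters(family, Te, p)
    s_vec = float(survival_natural(family, t, Te, p))
    assert s_vec == pytest.approx(float(survival(npar, t)), rel=1e-10, abs=1e-12)
    if 0.01 < s_vec < 0.99:
        assert float(quantile_natural(family, s_vec, Te, p)) == pytest.approx(
            t, rel=1e-6, abs=1e-6
        )
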