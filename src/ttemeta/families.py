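"""Parametric hazard families for time-to-event meta-analysis.

Three families are supported — Weibull, Gompertz and log-logistic — in two
equivalent parameterizations:

* the *hazard* form ``(lam, gam)``: ``lam`` is the risk scale at time 0 and
  ``gam`` the shape (Weibull power, Gompertz exponential rate, log-logistic
  power);
* the *natural* form ``(Te, p)`` used for population modeling: ``p = gam``
  and ``Te`` is a characteristic event time in months.

The natural form follows the convention of mixed-effects time-to-event
software: for Weibull and Gompertz, ``Te`` is the time at which the
cumulative hazard reaches 1, so ``S(Te) = exp(-1)``; for the log-logistic,
``Te = 1/lam``, so ``S(Te) = 0.5`` and the median equals ``Te`` exactly.

Closed forms (hazard h, cumulative hazard H), with time t in months::

    weibull      h = lam*gam*t**(gam-1)                 H = lam*t**gam
    gompertz     h = lam*exp(gam*t)                     H = (lam/gam)*(exp(gam*t)-1)
    loglogistic  h = lam*gam*(lam*t)**(gam-1)/(1+(lam*t)**gam)
                                                        H = log(1+(lam*t)**gam)

All functions are vectorized over ``t``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParametricFamily",
    "HazardParameters",
    "NaturalParameters",
    "hazard",
    "cumulative_hazard",
    "survival",
    "quantile",
    "sample_event_times",
    "to_natural",
    "from_natural",
    "survival_natural",
    "survival_natural_grad",
    "quantile_natural",
]

# Gompertz gam below this is treated as the exponential limit to avoid 0/0.
_GOMPERTZ_EXP_LIMIT = 1e-12


class ParametricFamily(str, enum.Enum):
    """The three candidate hazard families."""

    WEIBULL = "weibull"
    GOMPERTZ = "gompertz"
    LOGLOGISTIC = "loglogistic"


def _as_family(family: "ParametricFamily | str") -> ParametricFamily:
    return ParametricFamily(family)


@dataclass(frozen=True)
class HazardParameters:
    """Hazard-form parameters (lam, gam), both strictly positive.

    ``lam`` has units months**(-gam) for Weibull and months**(-1) for
    Gompertz and log-logistic; ``gam`` is dimensionless except for the
    Gompertz rate (months**(-1)).
    """

    family: ParametricFamily
    lam: float
    gam: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", _as_family(self.family))
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be positive and finite, got {self.lam}")
        if not (self.gam > 0 and math.isfinite(self.gam)):
            raise ValueError(f"gam must be positive and finite, got {self.gam}")


@dataclass(frozen=True)
class NaturalParameters:
    """Natural-form parameters: characteristic time Te (months) and shape p."""

    family: ParametricFamily
    Te: float
    p: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", _as_family(self.family))
        if not (self.Te > 0 and math.isfinite(self.Te)):
            raise ValueError(f"Te must be positive and finite, got {self.Te}")
        if not (self.p > 0 and math.isfinite(self.p)):
            raise ValueError(f"p must be positive and finite, got {self.p}")


def _coerce_hazard(params: "HazardParameters | NaturalParameters") -> HazardParameters:
    if isinstance(params, NaturalParameters):
        return from_natural(params)
    return params


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return t


def hazard(params: "HazardParameters | NaturalParameters", t) -> np.ndarray:
    """Instantaneous hazard h(t).

    For Weibull and log-logistic with ``gam < 1`` the hazard diverges at
    t = 0; the value ``inf`` is returned there (never evaluate the hazard at
    0 inside a likelihood — use the cumulative hazard).
    """
    hp = _coerce_hazard(params)
    t = _check_times(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    lam, gam = hp.lam, hp.gam
    with np.errstate(divide="ignore"):
        if hp.family is ParametricFamily.WEIBULL:
            out = lam * gam * t ** (gam - 1.0)
        elif hp.family is ParametricFamily.GOMPERTZ:
            out = lam * np.exp(gam * t)
        else:
            u = (lam * t) ** gam
            out = lam * gam * (lam * t) ** (gam - 1.0) / (1.0 + u)
    return float(out[0]) if scalar else out


def cumulative_hazard(params: "HazardParameters | NaturalParameters", t) -> np.ndarray:
    """Cumulative hazard H(t) = integral of h from 0 to t, closed form."""
    hp = _coerce_hazard(params)
    t = _check_times(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    lam, gam = hp.lam, hp.gam
    if hp.family is ParametricFamily.WEIBULL:
        out = lam * t**gam
    elif hp.family is ParametricFamily.GOMPERTZ:
        if gam < _GOMPERTZ_EXP_LIMIT:
            out = lam * t
        else:
            out = (lam / gam) * np.expm1(gam * t)
    else:
        out = np.log1p((lam * t) ** gam)
    return float(out[0]) if scalar else out


def survival(params: "HazardParameters | NaturalParameters", t) -> np.ndarray:
    """Survival function S(t) = exp(-H(t)); S(0) = 1 exactly."""
    H = cumulative_hazard(params, t)
    return np.exp(-H) if isinstance(H, np.ndarray) else math.exp(-H)


def quantile(params: "HazardParameters | NaturalParameters", q) -> np.ndarray:
    """Time t at which S(t) = q, for survival level q in (0, 1).

    The median is ``quantile(params, 0.5)``.
    """
    hp = _coerce_hazard(params)
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if np.any((q <= 0) | (q >= 1)) or not np.all(np.isfinite(q)):
        raise ValueError("survival level q must lie strictly in (0, 1)")
    lam, gam = hp.lam, hp.gam
    H = -np.log(q)  # target cumulative hazard
    if hp.family is ParametricFamily.WEIBULL:
        out = (H / lam) ** (1.0 / gam)
    elif hp.family is ParametricFamily.GOMPERTZ:
        if gam < _GOMPERTZ_EXP_LIMIT:
            out = H / lam
        else:
            out = np.log1p(gam * H / lam) / gam
    else:
        # H = log(1 + (lam t)^gam)  =>  (lam t)^gam = e^H - 1
        out = np.expm1(H) ** (1.0 / gam) / lam
    return float(out[0]) if scalar else out


def sample_event_times(
    params: "HazardParameters | NaturalParameters",
    n: int,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. event times by inverse-CDF sampling.

    ``rng`` may be a Generator, an integer seed, or None (fresh entropy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # S(T) ~ U(0,1) => T = quantile(U)
    u = rng.uniform(size=n)
    return quantile(params, u)


def to_natural(hp: HazardParameters) -> NaturalParameters:
    """Convert hazard-form (lam, gam) to natural-form (Te, p).

    Weibull: Te = lam**(-1/gam).  Log-logistic: Te = 1/lam.  Gompertz: Te
    solves H(Te) = 1, which inverts exactly to log1p(gam/lam)/gam.
    """
    lam, gam = hp.lam, hp.gam
    if hp.family is ParametricFamily.WEIBULL:
        Te = lam ** (-1.0 / gam)
    elif hp.family is ParametricFamily.LOGLOGISTIC:
        Te = 1.0 / lam
    else:
        if gam < _GOMPERTZ_EXP_LIMIT:
            Te = 1.0 / lam
        else:
            Te = math.log1p(gam / lam) / gam
    return NaturalParameters(hp.family, float(Te), float(gam))


def from_natural(npar: NaturalParameters) -> HazardParameters:
    """Convert natural-form (Te, p) back to hazard-form (lam, gam)."""
    Te, p = npar.Te, npar.p
    if npar.family is ParametricFamily.WEIBULL:
        lam = Te ** (-p)
    elif npar.family is ParametricFamily.LOGLOGISTIC:
        lam = 1.0 / Te
    else:
        # (lam/p)(e^{p Te} - 1) = 1  =>  lam = p / expm1(p*Te)
        if p * Te > 700.0:
            raise ValueError("Gompertz p*Te too large to represent lam")
        lam = p / math.expm1(p * Te)
    return HazardParameters(npar.family, float(lam), float(p))


# ---------------------------------------------------------------------------
# Vectorized natural-form kernels.
#
# The hierarchical model and the simulator evaluate S(t; Te, p) with Te and p
# varying per study, quadrature node or subject, so these accept arbitrary
# broadcastable arrays. They are the hot path of the likelihood.
# ---------------------------------------------------------------------------


def survival_natural(family: "ParametricFamily | str", t, Te, p) -> np.ndarray:
    """S(t; Te, p), broadcasting over all arguments."""
    family = _as_family(family)
    t = np.asarray(t, dtype=float)
    Te = np.asarray(Te, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(over="ignore"):
        if family is ParametricFamily.WEIBULL:
            return np.exp(-((t / Te) ** p))
        if family is ParametricFamily.LOGLOGISTIC:
            return 1.0 / (1.0 + (t / Te) ** p)
        # Gompertz: H = expm1(p t) / expm1(p Te)
        return np.exp(-np.expm1(p * t) / np.expm1(p * Te))


def survival_natural_grad(family: "ParametricFamily | str", t, Te, p):
    """Return (S, dS/dTe, dS/dp), broadcasting over all arguments.

    Used by the Gauss-Newton inner step of the marginal likelihood. The
    t = 0 limit is handled exactly (S = 1, gradients 0).
    """
    family = _as_family(family)
    t, Te, p = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(Te, float), np.asarray(p, float)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.where(t > 0, np.log(t / Te), 0.0)
    if family is ParametricFamily.GOMPERTZ:
        with np.errstate(over="ignore", invalid="ignore"):
            A = np.expm1(p * t)
            B = np.expm1(p * Te)
            H = A / B
            S = np.exp(-H)
            dH_dTe = -A * p * np.exp(p * Te) / B**2
            dH_dp = (t * np.exp(p * t) * B - A * Te * np.exp(p * Te)) / B**2
            dS_dTe = np.nan_to_num(-S * dH_dTe, nan=0.0, posinf=0.0, neginf=0.0)
            dS_dp = np.nan_to_num(-S * dH_dp, nan=0.0, posinf=0.0, neginf=0.0)
        return S, dS_dTe, dS_dp
    with np.errstate(over="ignore", invalid="ignore"):
        u = np.where(t > 0, (t / Te) ** p, 0.0)
        if family is ParametricFamily.WEIBULL:
            S = np.exp(-u)
            dS_dTe = S * u * p / Te
            dS_dp = -S * u * logr
        else:  # log-logistic
            S = 1.0 / (1.0 + u)
            dS_dTe = S**2 * u * p / Te
            dS_dp = -(S**2) * u * logr
    # overflowing u means S has underflowed to 0 and so have the gradients
    dS_dTe = np.where(np.isfinite(u), dS_dTe, 0.0)
    dS_dp = np.where(np.isfinite(u), dS_dp, 0.0)
    return S, dS_dTe, dS_dp


def quantile_natural(family: "ParametricFamily | str", q, Te, p) -> np.ndarray:
    """Inverse survival t with S(t) = q, broadcasting over all arguments."""
    family = _as_family(family)
    q = np.asarray(q, dtype=float)
    Te = np.asarray(Te, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("survival level q must lie strictly in (0, 1)")
    if family is ParametricFamily.WEIBULL:
        return Te * (-np.log(q)) ** (1.0 / p)
    if family is ParametricFamily.LOGLOGISTIC:
        return Te * ((1.0 - q) / q) ** (1.0 / p)
    # Gompertz: expm1(p t) = -log(q) * expm1(p Te)
    return np.log1p(-np.log(q) * np.expm1(p * Te)) / p
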