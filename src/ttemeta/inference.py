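"""Hierarchical parametric modeling of multi-study survival fractions.

The observation unit is a digitized survival probability ``Obs_{ij}`` at
time ``t_{ij}`` in study ``i``.  The model is

    Obs_{ij} = S(t_{ij}; Te_i, p_i) + eps_{ij} * SE_{ij},   eps ~ N(0, sigma^2)
    Te_i = Te_pop * exp(sum_c theta_c * COV_{ic}) * exp(eta_Te,i)
    p_i  = p_pop * exp(eta_p,i)
    (eta_Te, eta_p) ~ N(0, diag(omega_Te^2, omega_p^2))   (study level)

with ``SE_{ij} = sqrt(Obs(1-Obs)/N)`` the binomial standard error of the
observed fraction (``N`` = number at risk at that time).  The marginal
likelihood integrates the Gaussian observation density over the study-level
random effects by adaptive Gauss-Hermite quadrature (nodes centered and
scaled at each study's conditional mode, Gauss-Newton curvature), and is
maximized directly by quasi-Newton iteration on log-transformed positive
parameters.  Standard errors come from a finite-difference Hessian of the
negative marginal log-likelihood at the optimum.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import ParametricFamily, survival_natural, survival_natural_grad

__all__ = [
    "PopulationModel",
    "FitOptions",
    "FitResult",
    "se_weights",
    "observations_from_curve",
    "predict_survival",
    "marginal_loglik",
    "fit",
    "wald_test",
    "aic",
    "select_model",
    "screen_covariates",
]

_OBS_FLOOR = 0.005
_OBS_CEIL = 0.995
_OMEGA_ZERO = 1e-6  # below this an omega is treated as exactly 0
_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class PopulationModel:
    """Population parameters of the hierarchical time-to-event model."""

    family: ParametricFamily
    te_pop: float
    p_pop: float
    theta_cov: dict[str, float] = field(default_factory=dict)
    omega_te: float = 0.0
    omega_p: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.family = ParametricFamily(self.family)
        if self.te_pop <= 0 or self.p_pop <= 0:
            raise ValueError("te_pop and p_pop must be positive")
        if min(self.omega_te, self.omega_p, self.sigma) < 0:
            raise ValueError("omega and sigma must be nonnegative")

    def study_params(self, cov: dict | None = None, eta_te: float = 0.0, eta_p: float = 0.0):
        """Study-level (Te_i, p_i) after covariate shift and random effect."""
        shift = 0.0
        cov = cov or {}
        for name, val in cov.items():
            if name in self.theta_cov:
                shift += self.theta_cov[name] * float(val)
        te = self.te_pop * math.exp(shift) * math.exp(eta_te)
        p = self.p_pop * math.exp(eta_p)
        return te, p


def se_weights(obs, n_at_risk) -> np.ndarray:
    """Binomial standard error sqrt(Obs(1-Obs)/N) of an observed fraction.

    Observations are clamped to [0.005, 0.995] first so that curve values at
    the extremes never receive a zero weight.
    """
    obs = np.clip(np.asarray(obs, dtype=float), _OBS_FLOOR, _OBS_CEIL)
    n = np.asarray(n_at_risk, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_at_risk must be >= 1")
    return np.sqrt(obs * (1.0 - obs) / n)


def observations_from_curve(curve, drop_origin: bool = True) -> pd.DataFrame:
    """Turn a DigitizedCurve into weighted observation records.

    The number at risk at each coordinate is linearly interpolated from the
    risk table (held constant beyond its last entry). The ``t = 0`` point is
    dropped by default: S(0) = 1 identically and carries no information.
    """
    t = curve.times
    obs = curve.surv
    if curve.risk_times.size:
        n = np.interp(t, curve.risk_times, curve.n_at_risk.astype(float))
    else:
        n = np.full_like(t, float(curve.total_n))
    n = np.maximum(n, 1.0)
    df = pd.DataFrame(
        {
            "study_id": curve.study_id or "study",
            "time": t,
            "obs": np.clip(obs, _OBS_FLOOR, _OBS_CEIL),
            "n_at_risk": n,
        }
    )
    if drop_origin:
        df = df[df["time"] > 0].reset_index(drop=True)
    df["se_weight"] = se_weights(df["obs"], df["n_at_risk"])
    return df


def predict_survival(model: PopulationModel, effects=None, cov: dict | None = None, t=0.0):
    """Model-predicted survival for one study at time(s) ``t``.

    ``effects`` may be None (typical study), a ``(eta_te, eta_p)`` pair, or
    an object with ``eta_te``/``eta_p`` attributes.
    """
    if effects is None:
        eta_te = eta_p = 0.0
    elif hasattr(effects, "eta_te"):
        eta_te, eta_p = float(effects.eta_te), float(effects.eta_p)
    else:
        eta_te, eta_p = map(float, effects)
    if cov:
        bad = sorted(set(cov) - set(model.theta_cov))
        if bad:
            raise KeyError(f"covariate(s) {bad} have no coefficient in the model")
    te, p = model.study_params(cov, eta_te, eta_p)
    return survival_natural(model.family, t, te, p)


# ---------------------------------------------------------------------------
# Packed data + marginal likelihood
# ---------------------------------------------------------------------------


class _Packed:
    """Observations padded to (n_studies, max_points) arrays."""

    def __init__(self, data: pd.DataFrame, cov: pd.DataFrame | None, cov_names: list[str]):
        req = {"study_id", "time", "obs", "n_at_risk"}
        missing = req - set(data.columns)
        if missing:
            raise ValueError(f"observation table missing columns {sorted(missing)}")
        self.studies = list(dict.fromkeys(data["study_id"]))
        S = len(self.studies)
        J = int(data.groupby("study_id").size().max())
        self.t = np.zeros((S, J))
        self.obs = np.zeros((S, J))
        self.se = np.ones((S, J))
        self.mask = np.zeros((S, J), dtype=bool)
        for s, sid in enumerate(self.studies):
            sub = data[data["study_id"] == sid]
            j = len(sub)
            self.t[s, :j] = sub["time"].to_numpy()
            o = np.clip(sub["obs"].to_numpy(dtype=float), _OBS_FLOOR, _OBS_CEIL)
            self.obs[s, :j] = o
            self.se[s, :j] = se_weights(o, sub["n_at_risk"].to_numpy(dtype=float))
            self.mask[s, :j] = True
        self.n_obs = int(self.mask.sum())
        self.cov = np.zeros((S, len(cov_names)))
        for c, name in enumerate(cov_names):
            if cov is None or name not in cov.columns:
                raise ValueError(f"covariate {name!r} not provided")
            self.cov[:, c] = cov.loc[self.studies, name].to_numpy(dtype=float)
        self.cov_names = cov_names
        h = hashlib.sha256()
        h.update(self.t.tobytes() + self.obs.tobytes() + self.se.tobytes())
        self.data_hash = h.hexdigest()[:16]


def _hermgauss(n: int):
    z, w = np.polynomial.hermite.hermgauss(n)
    return z, w


def _study_loglik_grid(packed: _Packed, family, te_base, p_pop, sigma, eta1, eta2):
    """Conditional log-likelihood per study for eta arrays of shape (S, Q)."""
    te = te_base[:, None] * np.exp(eta1)  # (S, Q)
    p = p_pop * np.exp(eta2)
    S_pred = survival_natural(
        family, packed.t[:, None, :], te[:, :, None], p[:, :, None]
    )  # (S, Q, J)
    r = packed.obs[:, None, :] - S_pred
    var = (sigma * packed.se[:, None, :]) ** 2
    ll = -0.5 * (r**2 / var + np.log(var) + _LOG2PI)
    return np.where(packed.mask[:, None, :], ll, 0.0).sum(axis=2)  # (S, Q)


def _find_modes(packed, family, te_base, p_pop, sigma, om1, om2, active, eta0=None):
    """Batched Gauss-Newton search for the per-study joint modes.

    Returns (eta, H) with eta (S, 2) the conditional modes and H (S, 2, 2)
    the Gauss-Newton curvature of the negative joint log-density there.
    Inactive dimensions (omega = 0) stay pinned at 0.
    """
    S = len(packed.studies)
    eta = np.zeros((S, 2)) if eta0 is None else eta0.copy()
    prec = np.array(
        [1.0 / om1**2 if active[0] else 0.0, 1.0 / om2**2 if active[1] else 0.0]
    )
    ivar = np.where(packed.mask, 1.0 / (sigma * packed.se) ** 2, 0.0)

    def fval(e):
        with np.errstate(over="ignore"):
            te = te_base * np.exp(np.clip(e[:, 0], -30, 30))
            p = p_pop * np.exp(np.clip(e[:, 1], -30, 30))
        Sp = survival_natural(family, packed.t, te[:, None], p[:, None])
        r = np.where(packed.mask, packed.obs - Sp, 0.0)
        return 0.5 * (r**2 * ivar).sum(axis=1) + 0.5 * (prec * e**2).sum(axis=1)

    f = fval(eta)
    H = np.zeros((S, 2, 2))
    # the marginal is stationary at the mode, so a 1e-7 gradient suffices
    for _ in range(18):
        eta = np.clip(eta, -30.0, 30.0)
        te = te_base * np.exp(eta[:, 0])
        p = p_pop * np.exp(eta[:, 1])
        Sp, dTe, dp = survival_natural_grad(family, packed.t, te[:, None], p[:, None])
        r = np.where(packed.mask, packed.obs - Sp, 0.0)
        # dS/deta with Te_i = te_base*e^eta1, p_i = p_pop*e^eta2
        J1 = dTe * te[:, None]
        J2 = dp * p[:, None]
        g1 = -(r * J1 * ivar).sum(axis=1) + prec[0] * eta[:, 0]
        g2 = -(r * J2 * ivar).sum(axis=1) + prec[1] * eta[:, 1]
        H11 = (J1 * J1 * ivar).sum(axis=1) + prec[0]
        H22 = (J2 * J2 * ivar).sum(axis=1) + prec[1]
        H12 = (J1 * J2 * ivar).sum(axis=1)
        # pin inactive dimensions
        if not active[0]:
            g1 = np.zeros_like(g1); H12 = np.zeros_like(H12); H11 = np.ones_like(H11)
        if not active[1]:
            g2 = np.zeros_like(g2); H12 = np.zeros_like(H12); H22 = np.ones_like(H22)
        H = np.stack(
            [np.stack([H11, H12], axis=1), np.stack([H12, H22], axis=1)], axis=1
        )
        det = H11 * H22 - H12**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s1 = (H22 * g1 - H12 * g2) / det
        s2 = (H11 * g2 - H12 * g1) / det
        step = np.stack([s1, s2], axis=1)
        gnorm = np.abs(g1) + np.abs(g2)
        if np.all(gnorm < 1e-7):
            break
        # backtracking line search, batched
        scale = np.ones(S)
        for _ls in range(12):
            trial = eta - scale[:, None] * step
            f_new = fval(trial)
            worse = f_new > f + 1e-12
            if not np.any(worse):
                break
            scale = np.where(worse, scale * 0.5, scale)
        improved = f_new <= f
        eta = np.where(improved[:, None], eta - scale[:, None] * step, eta)
        f = np.where(improved, f_new, f)
        if np.max(gnorm) < 1e-7:
            break
    return eta, H


def marginal_loglik(
    model: PopulationModel,
    data: "pd.DataFrame | _Packed",
    cov: pd.DataFrame | None = None,
    n_nodes: int = 9,
    return_modes: bool = False,
    _mode_cache: dict | None = None,
):
    """Marginal log-likelihood of the observation table under ``model``.

    Study-level random effects are integrated out by adaptive Gauss-Hermite
    quadrature with ``n_nodes`` per active dimension; with both omegas 0 the
    closed-form weighted Gaussian log-likelihood is returned.  Raises if the
    result is not finite.
    """
    cov_names = list(model.theta_cov)
    packed = data if isinstance(data, _Packed) else _Packed(data, cov, cov_names)
    theta = np.array([model.theta_cov[c] for c in packed.cov_names])
    te_base = model.te_pop * np.exp(packed.cov @ theta) if len(theta) else np.full(
        len(packed.studies), model.te_pop
    )
    om1, om2, sigma = model.omega_te, model.omega_p, model.sigma
    if sigma <= 0:
        raise ValueError("sigma must be positive for a Gaussian likelihood")
    active = (om1 > _OMEGA_ZERO, om2 > _OMEGA_ZERO)

    if not any(active):
        ll = _study_loglik_grid(
            packed, model.family, te_base, model.p_pop, sigma,
            np.zeros((len(packed.studies), 1)), np.zeros((len(packed.studies), 1)),
        )[:, 0]
        total = float(ll.sum())
        modes = np.zeros((len(packed.studies), 2))
    else:
        eta0 = None if _mode_cache is None else _mode_cache.get("eta")
        modes, H = _find_modes(
            packed, model.family, te_base, model.p_pop, sigma, om1, om2, active, eta0
        )
        if _mode_cache is not None:
            _mode_cache["eta"] = modes
        z, w = _hermgauss(n_nodes)
        logw = np.log(w)
        Sn = len(packed.studies)
        if all(active):
            # 2-D tensor nodes, curvature-scaled (lower Cholesky of H^-1)
            H11, H12, H22 = H[:, 0, 0], H[:, 0, 1], H[:, 1, 1]
            det = np.maximum(H11 * H22 - H12**2, 1e-300)
            # chol of inverse: Sigma = H^-1
            s11 = H22 / det; s12 = -H12 / det; s22 = H11 / det
            l11 = np.sqrt(np.maximum(s11, 1e-300))
            l21 = s12 / l11
            l22 = np.sqrt(np.maximum(s22 - l21**2, 1e-300))
            Z1, Z2 = np.meshgrid(z, z, indexing="ij")
            z1 = Z1.ravel(); z2 = Z2.ravel()
            lw = (logw[:, None] + logw[None, :]).ravel() + z1**2 + z2**2
            e1 = modes[:, 0:1] + math.sqrt(2.0) * l11[:, None] * z1[None, :]
            e2 = (
                modes[:, 1:2]
                + math.sqrt(2.0) * (l21[:, None] * z1[None, :] + l22[:, None] * z2[None, :])
            )
            ll_cond = _study_loglik_grid(
                packed, model.family, te_base, model.p_pop, sigma, e1, e2
            )
            lprior = (
                -0.5 * (e1 / om1) ** 2 - 0.5 * (e2 / om2) ** 2
                - np.log(om1) - np.log(om2) - _LOG2PI
            )
            logdet_fac = np.log(2.0) + np.log(l11 * l22)
            integrand = lw[None, :] + ll_cond + lprior
            m = integrand.max(axis=1)
            total_s = m + np.log(np.exp(integrand - m[:, None]).sum(axis=1)) + logdet_fac
        else:
            d = 0 if active[0] else 1
            om = om1 if d == 0 else om2
            Hd = H[:, d, d]
            sd = np.sqrt(1.0 / np.maximum(Hd, 1e-300))
            lw = logw + z**2
            e_act = modes[:, d : d + 1] + math.sqrt(2.0) * sd[:, None] * z[None, :]
            zeros = np.zeros_like(e_act)
            e1, e2 = (e_act, zeros) if d == 0 else (zeros, e_act)
            ll_cond = _study_loglik_grid(
                packed, model.family, te_base, model.p_pop, sigma, e1, e2
            )
            lprior = -0.5 * (e_act / om) ** 2 - np.log(om) - 0.5 * _LOG2PI
            logdet_fac = 0.5 * np.log(2.0) + np.log(sd)
            integrand = lw[None, :] + ll_cond + lprior
            m = integrand.max(axis=1)
            total_s = m + np.log(np.exp(integrand - m[:, None]).sum(axis=1)) + logdet_fac
        total = float(total_s.sum())

    if not np.isfinite(total):
        raise FloatingPointError("non-finite marginal log-likelihood")
    if return_modes:
        return total, modes
    return total


# ---------------------------------------------------------------------------
# Maximum likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Estimation settings for :func:`fit`."""

    n_nodes: int = 9
    fix_sigma: float | None = None
    estimate_omega: bool = True
    maxiter: int = 300
    gtol: float = 1e-6
    omega_bounds: tuple[float, float] = (1e-3, 5.0)
    hessian_rel_step: float = 1e-3


@dataclass
class FitResult:
    """Maximum-likelihood fit of a :class:`PopulationModel`."""

    model: PopulationModel
    estimates: dict[str, float]
    se: dict[str, float | None]
    rse_percent: dict[str, float | None]
    minus2ll: float
    aic: float
    n_params: int
    study_effects: pd.DataFrame
    converged: bool
    n_iter: int
    final_grad_norm: float
    data_hash: str
    n_obs: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": self.se.get(name),
                    "rse_percent": self.rse_percent.get(name),
                }
            )
        return pd.DataFrame(rows)


def _unpack(x, cov_names, est_omega, fix_sigma):
    i = 0
    te = math.exp(x[i]); i += 1
    p = math.exp(x[i]); i += 1
    theta = {}
    for c in cov_names:
        theta[c] = x[i]; i += 1
    if est_omega:
        om1 = math.exp(x[i]); i += 1
        om2 = math.exp(x[i]); i += 1
    else:
        om1 = om2 = 0.0
    sigma = fix_sigma if fix_sigma is not None else math.exp(x[i])
    return te, p, theta, om1, om2, sigma


def _start_values(packed: _Packed, family: ParametricFamily):
    """Crude per-study Te guesses from the curve level S(Te) (e^-1 or 0.5)."""
    ref = 0.5 if family is ParametricFamily.LOGLOGISTIC else math.exp(-1.0)
    te_guesses = []
    for s in range(len(packed.studies)):
        t = packed.t[s][packed.mask[s]]
        o = packed.obs[s][packed.mask[s]]
        j = int(np.argmin(np.abs(o - ref)))
        lo = o[j]
        # extrapolate if the curve never reaches the reference level
        te_guesses.append(t[j] * (math.log(ref) / math.log(max(min(lo, 0.99), 0.01))))
    te0 = float(np.exp(np.mean(np.log(np.clip(te_guesses, 1e-2, 1e4)))))
    return te0, 2.0


def fit(
    family: "ParametricFamily | str",
    data: pd.DataFrame,
    cov: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the AGQ-marginalized likelihood for one hazard family.

    ``data`` is the observation table (study_id, time, obs, n_at_risk);
    ``cov`` an optional study-indexed covariate table; ``covariates`` the
    names whose coefficients (on Te) are estimated.  Deterministic: the same
    data and options always give the identical result.
    """
    family = ParametricFamily(family)
    covariates = covariates or []
    options = options or FitOptions()
    packed = _Packed(data, cov, covariates)
    S = len(packed.studies)
    est_omega = options.estimate_omega and S >= 2

    te0, p0 = _start_values(packed, family)
    x0 = [math.log(te0), math.log(p0)] + [0.0] * len(covariates)
    if est_omega:
        x0 += [math.log(0.3), math.log(0.3)]
    if options.fix_sigma is None:
        x0 += [0.0]
    x0 = np.array(x0)

    lob, upb = options.omega_bounds
    bounds = [(math.log(1e-2), math.log(1e4)), (math.log(0.05), math.log(50.0))]
    bounds += [(-5.0, 5.0)] * len(covariates)
    if est_omega:
        bounds += [(math.log(lob), math.log(upb))] * 2
    if options.fix_sigma is None:
        bounds += [(math.log(1e-3), math.log(1e3))]

    def negll(x):
        te, p, theta, om1, om2, sigma = _unpack(
            x, covariates, est_omega, options.fix_sigma
        )
        model = PopulationModel(
            family, te, p, theta, om1, om2, sigma if sigma else 1.0
        )
        try:
            return -marginal_loglik(model, packed, n_nodes=options.n_nodes)
        except FloatingPointError:
            return 1e10

    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": options.maxiter,
            "gtol": options.gtol,
            "ftol": 1e-11,
            "eps": 1e-5,
        },
    )
    te, p, theta, om1, om2, sigma = _unpack(
        res.x, covariates, est_omega, options.fix_sigma
    )
    model = PopulationModel(family, te, p, theta, om1, om2, sigma)
    ll, modes = marginal_loglik(
        model, packed, n_nodes=options.n_nodes, return_modes=True
    )

    names = ["te_pop", "p_pop"] + [f"theta_{c}" for c in covariates]
    values = [te, p] + [theta[c] for c in covariates]
    if est_omega:
        names += ["omega_te", "omega_p"]
        values += [om1, om2]
    if options.fix_sigma is None:
        names += ["sigma"]
        values += [sigma]
    k = len(names)

    se = _wald_se(
        values, names, covariates, est_omega, options, family, packed
    )
    rse = {
        n: (100.0 * s / abs(v) if (s is not None and v != 0) else None)
        for n, v, s in zip(names, values, se.values())
    }
    eff = pd.DataFrame(
        {"study_id": packed.studies, "eta_te": modes[:, 0], "eta_p": modes[:, 1]}
    )
    return FitResult(
        model=model,
        estimates=dict(zip(names, values)),
        se=se,
        rse_percent=rse,
        minus2ll=-2.0 * ll,
        aic=-2.0 * ll + 2.0 * k,
        n_params=k,
        study_effects=eff,
        converged=bool(res.success),
        n_iter=int(res.nit),
        final_grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else math.nan,
        data_hash=packed.data_hash,
        n_obs=packed.n_obs,
    )


def _wald_se(values, names, covariates, est_omega, options, family, packed):
    """SEs from a central finite-difference Hessian on the natural scale."""

    def negll_nat(v):
        i = 0
        te = v[i]; i += 1
        p = v[i]; i += 1
        theta = {}
        for c in covariates:
            theta[c] = v[i]; i += 1
        if est_omega:
            om1 = v[i]; om2 = v[i + 1]; i += 2
        else:
            om1 = om2 = 0.0
        sigma = v[i] if options.fix_sigma is None else options.fix_sigma
        if te <= 0 or p <= 0 or sigma <= 0 or min(om1, om2) < 0:
            return 1e10
        model = PopulationModel(family, te, p, theta, om1, om2, sigma)
        try:
            return -marginal_loglik(model, packed, n_nodes=options.n_nodes)
        except FloatingPointError:
            return 1e10

    v0 = np.array(values, dtype=float)
    n = len(v0)
    h = options.hessian_rel_step * np.maximum(np.abs(v0), 1e-3)
    H = np.zeros((n, n))
    f0 = negll_nat(v0)
    for a in range(n):
        for b in range(a, n):
            if a == b:
                vp = v0.copy(); vp[a] += h[a]
                vm = v0.copy(); vm[a] -= h[a]
                H[a, a] = (negll_nat(vp) - 2 * f0 + negll_nat(vm)) / h[a] ** 2
            else:
                vpp = v0.copy(); vpp[[a, b]] += [h[a], h[b]]
                vpm = v0.copy(); vpm[a] += h[a]; vpm[b] -= h[b]
                vmp = v0.copy(); vmp[a] -= h[a]; vmp[b] += h[b]
                vmm = v0.copy(); vmm[[a, b]] -= [h[a], h[b]]
                H[a, b] = H[b, a] = (
                    negll_nat(vpp) - negll_nat(vpm) - negll_nat(vmp) + negll_nat(vmm)
                ) / (4 * h[a] * h[b])
    se: dict[str, float | None] = {}
    try:
        covm = np.linalg.inv(H)
        d = np.diag(covm)
        for name, da in zip(names, d):
            se[name] = float(math.sqrt(da)) if da > 0 else None
    except np.linalg.LinAlgError:
        se = {name: None for name in names}
    return se


def wald_test(estimate: float, se: float) -> dict[str, float]:
    """Two-sided Wald z-test of ``estimate`` against a standard normal."""
    if not (se > 0):
        raise ValueError("se must be positive")
    z = estimate / se
    return {"z": z, "p_value": float(2.0 * stats.norm.sf(abs(z)))}


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion, -2LL + 2k."""
    return fit_result.minus2ll + 2.0 * fit_result.n_params


def select_model(fits: list[FitResult]) -> FitResult:
    """Pick the minimum-AIC fit; ties go to the fewer-parameter model.

    All candidates must have been fitted to the same observations.
    """
    if not fits:
        raise ValueError("no candidate fits")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("candidate fits are not on identical data")
    return min(fits, key=lambda f: (round(f.aic, 9), f.n_params))


def screen_covariates(
    family: "ParametricFamily | str",
    data: pd.DataFrame,
    cov: pd.DataFrame,
    candidates: list[str],
    options: FitOptions | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-at-a-time Wald screening of covariates on Te (forward inclusion).

    Each candidate is added alone to the base model; its coefficient is
    tested against 0 at level ``alpha``.  Returns one row per candidate with
    the estimate, SE, z, p-value and inclusion flag.
    """
    rows = []
    for name in candidates:
        f = fit(family, data, cov, covariates=[name], options=options)
        est = f.estimates[f"theta_{name}"]
        s = f.se.get(f"theta_{name}")
        if s is None or s <= 0:
            rows.append(
                {"covariate": name, "theta": est, "se": s, "z": None,
                 "p_value": None, "significant": False}
            )
            continue
        wt = wald_test(est, s)
        rows.append(
            {"covariate": name, "theta": est, "se": s, "z": wt["z"],
             "p_value": wt["p_value"], "significant": wt["p_value"] < alpha}
        )
    return pd.DataFrame(rows)


def observations_from_ipd(ipd: pd.DataFrame, times) -> pd.DataFrame:
    """KM survival fractions of an IPD table evaluated on a time grid.

    The at-risk count at each grid time comes straight from the records.
    Used to close the loop digitize -> reconstruct -> re-estimate -> fit.
    """
    from .reconstruct import km_survival_at

    times = np.asarray(times, dtype=float)
    times = times[times > 0]
    surv = km_survival_at(ipd, times)
    tarr = ipd["time"].to_numpy()
    n = np.array([(tarr >= g).sum() for g in times], dtype=float)
    keep = n >= 1
    sid = str(ipd["study_id"].iloc[0]) if "study_id" in ipd else "study"
    df = pd.DataFrame(
        {
            "study_id": sid,
            "time": times[keep],
            "obs": np.clip(surv[keep], _OBS_FLOOR, _OBS_CEIL),
            "n_at_risk": n[keep],
        }
    )
    df["se_weight"] = se_weights(df["obs"], df["n_at_risk"])
    return df
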