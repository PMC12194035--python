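"""Synthetic multi-study trial data with the structure the pipeline assumes.

Published KM figures cannot be redistributed, so tests and examples run on
generated data that emulates them: several trial arms whose true parameters
scatter lognormally around a population model, subjects censored by an
administrative cutoff plus random (exponential) dropout, and curves
"digitized" onto a coarse sampling grid with a numbers-at-risk table —
exactly the inputs the reconstruction and fitting stages expect.

Default condition choices: dropout rate 0.008/month with a 38-month cutoff
censors roughly half of the overall-survival records of a 40-month-median
arm, matching the maturity of the trials this pipeline targets; digitization
uses 40 points per curve, a 6-month risk-table interval and uniform +/-0.005
jitter on the survival axis (small enough to be repaired by monotone
cleaning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import quantile_natural
from .inference import PopulationModel
from .reconstruct import DigitizedCurve, clean_curve, km_estimate

__all__ = ["TrialSpec", "generate_trial", "digitize", "make_benchmark_suite"]


@dataclass
class TrialSpec:
    """Design of a synthetic multi-study dataset."""

    model: PopulationModel
    n_studies: int = 20
    subjects_per_study: int = 300
    covariate_dists: dict[str, float] = field(default_factory=dict)  # P(cov=1) per name
    admin_cutoff: float = 38.0  # months of follow-up
    dropout_rate: float = 0.008  # exponential censoring, events per month
    points_per_curve: int = 40
    risk_interval: float = 6.0  # months between risk-table entries
    jitter: float = 0.005  # uniform digitization error on survival
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.subjects_per_study < 1:
            raise ValueError("counts must be positive")
        if self.admin_cutoff <= 0:
            raise ValueError("admin cutoff must be positive")


def generate_trial(spec: TrialSpec) -> pd.DataFrame:
    """Simulate true per-subject records for every study in ``spec``.

    Returns an IPD DataFrame (time, event, study_id, arm, covariate columns)
    plus per-study truth in ``df.attrs['truth']`` (eta values and effective
    parameters) for recovery assertions.  Deterministic in ``spec.seed``.
    """
    m = spec.model
    rng = np.random.default_rng(spec.seed)
    frames = []
    truth = []
    for s in range(spec.n_studies):
        eta_te = rng.normal(0.0, m.omega_te) if m.omega_te > 0 else 0.0
        eta_p = rng.normal(0.0, m.omega_p) if m.omega_p > 0 else 0.0
        n = spec.subjects_per_study
        covs = {
            name: (rng.uniform(size=n) < prob).astype(float)
            for name, prob in spec.covariate_dists.items()
        }
        shift = np.zeros(n)
        for name, vals in covs.items():
            shift += m.theta_cov.get(name, 0.0) * vals
        te = m.te_pop * np.exp(shift) * math.exp(eta_te)
        p = m.p_pop * math.exp(eta_p)
        u = rng.uniform(size=n)
        t_event = quantile_natural(m.family, u, te, p)
        t_cens = np.full(n, spec.admin_cutoff)
        if spec.dropout_rate > 0:
            t_cens = np.minimum(t_cens, rng.exponential(1.0 / spec.dropout_rate, n))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        df = pd.DataFrame({"time": time, "event": event})
        df["study_id"] = f"study_{s:02d}"
        df["arm"] = "active"
        for name, vals in covs.items():
            df[name] = vals
        frames.append(df)
        truth.append(
            {"study_id": f"study_{s:02d}", "eta_te": eta_te, "eta_p": eta_p,
             "te_study": m.te_pop * math.exp(eta_te), "p_study": p}
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["truth"] = pd.DataFrame(truth)
    return out


def digitize(
    ipd: pd.DataFrame,
    points_per_curve: int = 40,
    risk_interval: float = 6.0,
    jitter: float = 0.0,
    seed: int = 0,
    **labels,
) -> DigitizedCurve:
    """Emulate figure extraction: KM curve sampled on a coarse grid.

    With ``jitter == 0`` and a grid equal to the step times the result is
    the exact KM output; positive jitter adds uniform +/-jitter noise on the
    survival axis (subsequently repaired by :func:`clean_curve`).
    """
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    times, surv, _ = km_estimate(ipd)
    t_max = float(ipd["time"].max())
    if points_per_curve >= len(times) and jitter == 0:
        grid_t, grid_s = times, surv
    else:
        grid_t = np.linspace(0.0, t_max, points_per_curve)
        idx = np.searchsorted(times, grid_t, side="right") - 1
        grid_s = surv[np.clip(idx, 0, len(surv) - 1)]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        grid_s = grid_s + rng.uniform(-jitter, jitter, size=len(grid_s))
    risk_times = np.arange(0.0, t_max + 1e-9, risk_interval)
    tarr = ipd["time"].to_numpy()
    n_at_risk = np.array([(tarr >= g).sum() for g in risk_times])
    keep = n_at_risk > 0
    labels.setdefault("study_id", str(ipd["study_id"].iloc[0]) if "study_id" in ipd else "")
    labels.setdefault("arm_label", str(ipd["arm"].iloc[0]) if "arm" in ipd else "")
    return clean_curve(
        grid_t,
        grid_s,
        risk_times=risk_times[keep],
        n_at_risk=n_at_risk[keep],
        total_n=len(ipd),
        total_events=int(ipd["event"].sum()),
        **labels,
    )


# Published-model parameters used for the benchmark bundle: the final
# first-line OS Weibull (race coefficient on Te) and the second-line OS
# log-logistic base model, with the corresponding trial-arm sizes and race
# mixes of the source trials.
FIRSTLINE_OS = PopulationModel(
    "weibull", 41.69, 2.25, {"race_nonasian": 0.19}, 0.44, 0.54, 1.0
)
SECONDLINE_OS = PopulationModel("loglogistic", 27.47, 3.5, {}, 0.6, 0.75, 1.0)
FIRSTLINE_PFS = PopulationModel("loglogistic", 18.03, 5.88, {}, 0.8, 0.81, 1.0)
SECONDLINE_PFS = PopulationModel("loglogistic", 10.31, 5.92, {}, 0.93, 0.74, 1.0)

#: (arm name, line, n, proportion non-Asian)
_BENCHMARK_ARMS = [
    ("flaura_like", "first", 279, 0.38),
    ("flaura_asia_like", "first", 71, 0.0),
    ("aura_ext_like", "second", 129, 0.35),
    ("aura3_like", "second", 279, 0.35),
]


def make_benchmark_suite(seed: int = 0) -> dict:
    """Deterministic fixture bundle for tests and worked examples.

    Contains (a) four trial arms mirroring the first/second-line design
    (sizes 279/71/129/279, race mixes 62%/100% Asian in first line)
    generated from the published final-model parameters, (b) a 20-study
    recovery dataset from a known Weibull population model, and (c) a tiny
    hand-checkable 10-subject arm.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    arms = {}
    for i, (name, line, n, p_nonasian) in enumerate(_BENCHMARK_ARMS):
        model = FIRSTLINE_OS if line == "first" else SECONDLINE_OS
        spec = TrialSpec(
            model=model,
            n_studies=1,
            subjects_per_study=n,
            covariate_dists={"race_nonasian": p_nonasian},
            admin_cutoff=38.0 if line == "first" else 30.0,
            seed=seeds[i],
        )
        ipd = generate_trial(spec)
        ipd["study_id"] = name
        curve = digitize(
            ipd, jitter=0.005, seed=seeds[i], endpoint="OS", line=line
        )
        arms[name] = {"ipd": ipd, "curve": curve, "line": line, "n": n}

    recovery_model = PopulationModel("weibull", 40.0, 2.2, {}, 0.3, 0.3, 1.0)
    recovery = generate_trial(
        TrialSpec(model=recovery_model, n_studies=20, subjects_per_study=300,
                  seed=seeds[4])
    )

    tiny = pd.DataFrame(
        {
            "time": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
            "event": [1, 0, 1, 1, 0, 1, 0, 1, 1, 0],
            "study_id": "tiny",
            "arm": "active",
        }
    )
    return {
        "arms": arms,
        "recovery_ipd": recovery,
        "recovery_model": recovery_model,
        "tiny_ipd": tiny,
        "seed": seed,
    }


def generate_observations(
    model: PopulationModel,
    n_studies: int = 20,
    times=None,
    arm_size: int = 300,
    cov_values: dict[str, np.ndarray] | None = None,
    seed: int = 0,
):
    """Simulate survival-fraction observations directly from the model.

    This is the observation-level data-generating process the hierarchical
    fit assumes: per study, lognormal study effects perturb (Te, p), the
    predicted curve is evaluated on ``times``, the number at risk decays
    with the curve from ``arm_size``, and Gaussian residuals scaled by the
    binomial SE (times sigma) are added.  Returns ``(data, cov)`` ready for
    :func:`ttemeta.inference.fit`.
    """
    from .families import survival_natural
    from .inference import se_weights

    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(3.0, 39.0, 13)
    times = np.asarray(times, dtype=float)
    rows = []
    cov_rows = {}
    for s in range(n_studies):
        sid = f"study_{s:02d}"
        covs = {k: float(v[s]) for k, v in (cov_values or {}).items()}
        eta1 = rng.normal(0.0, model.omega_te) if model.omega_te > 0 else 0.0
        eta2 = rng.normal(0.0, model.omega_p) if model.omega_p > 0 else 0.0
        te, p = model.study_params(covs, eta1, eta2)
        pred = survival_natural(model.family, times, te, p)
        n_at_risk = np.maximum(arm_size * pred, 5.0)
        se = se_weights(pred, n_at_risk)
        obs = np.clip(pred + rng.normal(size=len(times)) * model.sigma * se, 0.005, 0.995)
        for t, o, n in zip(times, obs, n_at_risk):
            rows.append({"study_id": sid, "time": t, "obs": o, "n_at_risk": n})
        cov_rows[sid] = covs
    data = pd.DataFrame(rows)
    cov = pd.DataFrame.from_dict(cov_rows, orient="index") if cov_values else None
    return data, cov
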