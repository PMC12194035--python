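"""File formats: curve/risk-table/IPD CSV dialects, fit JSON, scenario YAML.

All tabular files are comma-separated UTF-8 with '.' decimal and a header
row.  Curve CSV: ``time,survival``; risk-table CSV: ``time,n_at_risk``; IPD
CSV: ``time,event,study_id,arm`` plus covariate columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .families import ParametricFamily
from .inference import FitResult, PopulationModel
from .reconstruct import DigitizedCurve, clean_curve

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_ipd_csv",
    "write_ipd_csv",
    "fit_result_to_dict",
    "save_fit_result",
    "load_population_model",
    "load_config",
]


def read_curve_csv(
    curve_path, risk_path=None, total_n: int = 0, **labels
) -> DigitizedCurve:
    """Load one arm's digitized curve (+ optional risk table) and clean it."""
    cdf = pd.read_csv(curve_path)
    for col in ("time", "survival"):
        if col not in cdf.columns:
            raise ValueError(f"{curve_path}: missing column {col!r}")
    risk_times: np.ndarray | tuple = ()
    n_at_risk: np.ndarray | tuple = ()
    if risk_path is not None:
        rdf = pd.read_csv(risk_path)
        for col in ("time", "n_at_risk"):
            if col not in rdf.columns:
                raise ValueError(f"{risk_path}: missing column {col!r}")
        risk_times = rdf["time"].to_numpy(dtype=float)
        n_at_risk = rdf["n_at_risk"].to_numpy(dtype=int)
    return clean_curve(
        cdf["time"].to_numpy(dtype=float),
        cdf["survival"].to_numpy(dtype=float),
        risk_times=risk_times,
        n_at_risk=n_at_risk,
        total_n=total_n,
        **labels,
    )


def write_curve_csv(curve: DigitizedCurve, curve_path, risk_path=None) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.surv}).to_csv(
        curve_path, index=False
    )
    if risk_path is not None:
        pd.DataFrame(
            {"time": curve.risk_times, "n_at_risk": curve.n_at_risk}
        ).to_csv(risk_path, index=False)


def read_ipd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False)


def fit_result_to_dict(fr: FitResult) -> dict:
    return {
        "family": fr.model.family.value,
        "estimates": fr.estimates,
        "se": fr.se,
        "rse_percent": fr.rse_percent,
        "theta_cov": fr.model.theta_cov,
        "minus2ll": fr.minus2ll,
        "aic": fr.aic,
        "n_params": fr.n_params,
        "n_obs": fr.n_obs,
        "converged": fr.converged,
        "n_iter": fr.n_iter,
        "study_effects": fr.study_effects.to_dict(orient="records"),
        "data_hash": fr.data_hash,
    }


def save_fit_result(fr: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fr), indent=1, default=float))


def load_population_model(source) -> PopulationModel:
    """Build a PopulationModel from a dict or a saved fit JSON path."""
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    if "estimates" in source:  # saved fit
        est = source["estimates"]
        theta = {
            k.removeprefix("theta_"): v
            for k, v in est.items()
            if k.startswith("theta_")
        }
        return PopulationModel(
            ParametricFamily(source["family"]),
            est["te_pop"],
            est["p_pop"],
            theta,
            est.get("omega_te", 0.0),
            est.get("omega_p", 0.0),
            est.get("sigma", 1.0),
        )
    return PopulationModel(
        ParametricFamily(source["family"]),
        source["te_pop"],
        source["p_pop"],
        dict(source.get("theta_cov", {})),
        source.get("omega_te", 0.0),
        source.get("omega_p", 0.0),
        source.get("sigma", 1.0),
    )


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
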