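# ttemeta

Model-based meta-analysis of published survival curves: reconstruct
pseudo-patient data from digitized Kaplan–Meier figures, fit hierarchical
parametric time-to-event models across trials, and simulate long-term
medians and landmark survival rates.

## The problem

Pivotal oncology trials report overall survival (OS) and progression-free
survival (PFS) as Kaplan–Meier figures that are still immature at
publication — for osimertinib in EGFR-mutant NSCLC, the first-line OS data
were only ~58% mature.  A parametric time-to-event model fitted *across*
the published trial arms can extrapolate beyond the observed follow-up,
quantify between-trial heterogeneity, and test trial-level covariates such
as the Asian/non-Asian race mix.  This package implements that workflow for
anyone doing survival meta-analysis from published figures: curve cleaning,
Guyot-type individual-patient-data (IPD) reconstruction from curve
coordinates plus numbers-at-risk tables, hierarchical model fitting on
survival fractions, and Monte Carlo extrapolation.

## The model

Three hazard families are candidates, written here in a natural
`(Te, p)` parameterization (`Te` in months):

| family       | S(t)                          | `Te` means            |
|--------------|-------------------------------|-----------------------|
| Weibull      | exp(−(t/Te)^p)                | S(Te) = e⁻¹           |
| Gompertz     | exp(−expm1(p·t)/expm1(p·Te))  | S(Te) = e⁻¹           |
| log-logistic | 1 / (1 + (t/Te)^p)            | S(Te) = ½ (median)    |

Observed survival fractions Obs_ij (study *i*, time *j*) follow

    Obs_ij = S(t_ij; Te_i, p_i) + ε_ij · SE_ij,      ε ~ N(0, σ²)
    Te_i   = Te_pop · exp(θ_cov · COV_i) · exp(η_Te,i)
    p_i    = p_pop · exp(η_p,i),   η ~ N(0, diag(ω_Te², ω_p²))

with SE_ij = √(Obs(1−Obs)/N_ij) the binomial standard error at the
interpolated number at risk N_ij.  The study-level random effects are
integrated out by adaptive Gauss–Hermite quadrature and the marginal
likelihood is maximized directly; families are ranked by AIC and trial-level
covariates are screened one at a time with a Wald test (p < 0.05).

## Worked example

Simulate the final first-line OS model (Weibull, Te_pop = 41.69 months,
p_pop = 2.25, race coefficient θ = 0.19 on Te, ω_Te = 0.44, ω_p = 0.54)
with the pooled 62% Asian / 38% non-Asian mix:

```python
from ttemeta import PopulationModel, SimulationScenario, Stratum
from ttemeta.simulate import landmark_rate, simulate_scenario

model = PopulationModel("weibull", 41.69, 2.25,
                        {"race_nonasian": 0.19}, 0.44, 0.54)
mix = [Stratum("asian", 0.62, {"race_nonasian": 0.0}),
       Stratum("nonasian", 0.38, {"race_nonasian": 1.0})]
scn = SimulationScenario(model=model, strata=mix, n_replicates=1000,
                         subjects_per_replicate=350, seed=1)
s = simulate_scenario(scn)
print(f"median OS {s.median:.2f} months")
print(f"5-year OS {100 * landmark_rate(model, mix, 60.0, seed=1):.1f}%")
```

prints

```
median OS 37.01 months
5-year OS 23.2%
```

the simulated median OS of a 350-subject first-line cohort (median of 1000
replicate KM medians) and the 5-year survival rate averaged over the
study-level variability.  The numbered scripts under `analysis/` run the
full narrative — synthetic fixture arms (the original digitized figures are
not redistributable), IPD reconstruction with validation, model fitting and
covariate screening, prediction scenarios, and VPC/GOF diagnostics — each
writing its tables under `results/`.  A `ttemeta` command-line interface
(`reconstruct`, `fit`, `simulate`, `vpc`, `make-fixtures`) exposes the same
stages for YAML-configured runs.

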