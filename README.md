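# psmiss

Propensity-score weighting with missing confounders: a simulation
laboratory comparing strategies for handling covariate missingness when
estimating the causal effect of a binary exposure on a continuous
outcome by stabilized inverse-probability weighting (IPW).

Observational studies routinely estimate exposure effects by weighting
on the propensity score e(x) = P(T=1 | x), but the confounders entering
e(x) are rarely complete.  `psmiss` implements, end to end, the
competing ways an analyst can proceed — impute and fit a logistic PS
model, or hand the incomplete data directly to gradient-boosted trees
that tolerate missing values via surrogate splits — and measures what
each choice does to the bias, SD, SE and RMSE of the weighted estimate
over many simulated replications.  It is aimed at methods researchers
and at analysts who want to stress-test a missing-confounder workflow
under known truth.

## What is inside

| module | contents |
| --- | --- |
| `psmiss.synthetic_data` | 10 covariates (6 binary, 4 normal) with latent-scale correlations; exposure scenarios A (main effects) and G (quadratics + interactions); outcome with true effect −0.4 |
| `psmiss.missingness` | MCAR, MAR-1 (auxiliary-driven), MAR-2 (auxiliary × outcome groups), MAR-sinister (group-level correlation driven), at 25%/50% on the four confounders |
| `psmiss.imputation` | treatment-mean imputation; single imputation ± parameter uncertainty; chained-equations MI (m = 20, predictive mean matching or Bayesian normal); MIMP (MI + pooled missingness-pattern indicator) |
| `psmiss.ps_logistic` | IRLS logistic PS under four covariate-inclusion strategies plus the correct scenario-G specification |
| `psmiss.ps_boosting` | gradient-boosted regression trees (shrinkage 0.05, interaction depth 4, Newton leaves) with surrogate-split handling of missing cells and AASM-minimizing iteration selection |
| `psmiss.effect_estimation` | stabilized weights, 1st/99th-percentile winsorization, weighted regression of Y on T, Rubin's rules |
| `psmiss.sim_driver` + `psmiss` CLI | factorial Monte-Carlo driver with counter-based seeding, YAML configs, delimited result tables |

The model core: the exposure follows
`logit P(T=1|x) = 0.8x₁ − 0.25x₂ + 0.6x₃ − 0.4x₄ − 0.8x₅ − 0.5x₆ + 0.7x₇`
(scenario G adds 3 quadratic and 10 interaction terms), the outcome is
`Y = −3.85 + 0.3x₁ − 0.36x₂ − 0.73x₃ − 0.2x₄ + 0.71x₈ − 0.19x₉ + 0.26x₁₀ − 0.4T + ε`,
and the estimand is the coefficient −0.4 recovered by weighted least
squares with weights p̄/pᵢ (exposed) and (1−p̄)/(1−pᵢ) (unexposed).
See `docs/methods.md` for the full account, including the deliberate
departures from the reference implementation and their rationale.

## Worked example

```python
import numpy as np
from psmiss import (
    GeneratorConfig, generate_complete_sample, impose_mcar,
    chained_equations_impute, build_design, fit_logistic_ps,
    estimate_effect, rubin_combine,
)

rng = np.random.default_rng(7)
sample = generate_complete_sample(GeneratorConfig(n=500, scenario="A", seed=7))
inc = impose_mcar(sample, 0.25, rng)
print("missing fraction:", round(inc.mask.mean(), 3))

out = chained_equations_impute(inc, m=20, rng=rng)   # MI via PMM
ests, vars_ = [], []
for Xc in out.completed:
    fit = fit_logistic_ps(build_design(Xc, "true_confounders"), sample.T)
    e = estimate_effect(sample.Y, sample.T, fit.ps)
    ests.append(e.estimate); vars_.append(e.variance)
combined = rubin_combine(ests, vars_)
print(f"MI estimate: {combined.estimate:.3f} (SE {combined.se:.3f}); truth -0.4")
```

prints

```
missing fraction: 0.243
MI estimate: -0.204 (SE 0.116); truth -0.4
```

One replication at n = 500 is noisy (the SE is ~0.12); the simulation
driver averages hundreds of them:

```python
from psmiss.sim_driver import CellSpec, run_cell
res = run_cell(CellSpec(method="TMI", mechanism="MCAR",
                        replications=200, master_seed=7))
print(f"bias={res.bias:+.3f} sd={res.sd:.3f} se={res.mean_se:.3f} rmse={res.rmse:.3f}")
```

```
bias=+0.002 sd=0.103 se=0.109 rmse=0.103
```

i.e. under MCAR at 25% missingness, treatment-mean imputation followed
by a true-confounder logistic PS leaves essentially no bias in this
implementation, with between-replication SD ≈ 0.10 at n = 500.

Full factorial studies run from a YAML config:

```sh
psmiss run study.yaml --out results.tsv --reps 1000 --seed 42
psmiss report results.tsv --out table.tsv
```

where `study.yaml` lists cells (scenario, n, mechanism, rate, method,
inclusion strategy; lists expand as a product), and `report` pivots the
per-cell rows into the published table layout.

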