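# ruraldce

A discrete choice experiment (DCE) toolkit for stated-preference studies of
rural health-workforce job postings, built around a study of final-year
Ethiopian medical students choosing between hypothetical rural jobs
described by six attributes: monthly salary (9,056 ETB base plus rural
allowances of 25/50/75%), housing quality, drug and medical-equipment
availability, mandatory service years before study leave, management
support and workload.

The package covers the whole analysis chain for anyone designing or
re-analysing such an experiment:

* **design** — blocked orthogonal main-effects paired-choice designs
  (24 tasks = 48 profiles in 3 blocks of 8; each respondent answers two
  blocks), built by a seeded search over the classical criteria: level
  balance, orthogonality, minimum overlap and utility balance;
* **simulation** — synthetic respondents under random utility theory
  (utility `x'β` plus i.i.d. Gumbel noise), with homogeneous, mixed-logit
  and three-class latent-class preference presets matching the published
  estimates, plus age/sex covariates and an age × service-year interaction;
* **estimation** — conditional logit (analytic Newton), latent-class logit
  (EM with seeded restarts and AIC selection of the class count), and
  panel mixed logit by simulated maximum likelihood with Halton draws;
* **post-estimation** — willingness to accept, per-class and pooled
  relative importance, and marginal uptake-rate change, each with
  delta-method or Krinsky–Robb intervals.

## The models

Choices between paired jobs A and B follow the logit kernel
`P(A) = 1 / (1 + exp(−(x_A − x_B)'β))` with

```
U = β_salary·Salary + β_house·HouseSuperior + β_drug·DrugAdequate
  + β_serve·ServeOneYear + β_mgmt·ManagementSupportive + β_work·WorkloadNormal + ε
```

where salary is linear in ETB/month and the binary attributes are dummy
coded against the less attractive level. The mixed logit gives every
non-salary coefficient an independent normal distribution across
respondents, `β_k ~ N(μ_k, σ_k²)`, and integrates each respondent's
16-task likelihood over it by quasi-random (Halton) simulation; the
latent-class model instead assumes C discrete preference classes with
shares π_c. Post-estimation statistics:

* WTA for attribute k: `β_k / β_salary` (ETB/month);
* relative importance: each attribute's within-class utility range
  (`|β_salary|·6792` for salary, `|β_k|` for binaries), normalised so the
  largest per class is 1; pooled scores weight classes by π_c;
* uptake-rate change for one attribute move:
  `Δ% = 100·(logistic(β'Δx) − 0.5)/0.5` percentage points.

## Worked example

```python
import ruraldce as r

schema = r.default_schema()
design, diag = r.build_paired_design(schema, n_tasks=24, n_blocks=3, seed=1)
dataset, _, _ = r.simulate_study(r.reference_mixl_dgp(), design, schema,
                                 n_respondents=352, seed=7)
fit = r.fit_mixl(dataset, schema, R=200, seed=3)
print(fit.summary().round(4))
print(r.wta(fit, "drug_supply_adequate").point)
```

prints

```
                         coef      se      sd   se_sd
salary                 0.0002  0.0000     NaN     NaN
housing_superior       0.2035  0.0543  0.7382  0.0633
drug_supply_adequate   0.9399  0.0762  1.1610  0.0728
service_oneyear        0.4539  0.0672  1.0686  0.0675
management_supportive  0.4800  0.0545  0.6682  0.0615
workload_normal        0.5642  0.0436  0.0457  0.1215
```

and a WTA of about 4114 ETB/month: with 352 simulated respondents whose
true preferences are the reference means/SDs (drug supply mean 1.01,
SD 1.13; salary 0.0002371 per ETB, fixed), the refit recovers every mean
and SD within sampling error, and the implied compensation for inadequate
drug supply is around four thousand ETB per month. Evaluating the uptake
formula at the reference coefficients themselves gives
`r.uptake_change(r.reference_mixl_result(), schema, "base", "base+25%")`
→ 26.21 percentage points.

A `dce` command exposes the same steps from the shell
(`dce design build`, `dce simulate`, `dce fit mixl`, `dce postest wta`,
`dce run --config run.yaml`); see `dce --help`.

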