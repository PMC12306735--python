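# immucast

Bayesian spatio-temporal estimation and projection of childhood
immunization coverage from household-survey data, with socioeconomic
inequality indices.

`immucast` is aimed at epidemiologists and health-policy analysts who
track routine childhood vaccination (BCG, Polio3, DPT3, MCV1 and full
immunization) at the sub-national (Admin-1) level from DHS-style
surveys, and who need (a) design-adjusted coverage estimates, (b)
smoothed small-area trends with honest uncertainty, (c) projections
against the 80% universal-health-coverage (UHC) and 90% IA2030 targets,
and (d) absolute and relative socioeconomic inequality summaries.
Because survey microdata are access-restricted, the package ships a
first-class synthetic-survey generator that reproduces the statistical
structure of the real data (stratified two-stage cluster sampling with
weights, logit-linear region trends, spatially correlated region
effects, wealth and education gradients), so the entire pipeline is
testable end-to-end offline.

## The model

Design-weighted coverage in region *i* (country *c*), year *t* and
subgroup *s* enters a binomial likelihood on Kish effective counts with
a logit-linear predictor

```
logit p_its = mu + a_c + b_i + gamma_s + (beta + e_c + g_i + delta_s + h_is) * t
```

where `b_i` is a spatial random effect on the region adjacency graph.
Six variants are supported: Besag (intrinsic CAR), BYM
(structured + unstructured) and BYM2 (total scale sigma, mixing
proportion phi on a variance-scaled structured component), each with or
without the hierarchical country level (`besag_1` ... `bym2_2`).
Penalized-complexity priors calibrate every scale
(`P(sigma > U) = alpha`) and the BYM2 mixing proportion.  Inference is
a nested Laplace approximation for latent Gaussian models (Newton
solves of the log-concave field conditional on hyperparameters,
Gaussian propagation of hyperparameter uncertainty), with an ensemble
MCMC backend as a cross-check.

Downstream, every quantity is computed per posterior draw: logit-linear
projection to 2030, exceedance probabilities `P(p_i,2030 >= c)` for
`c = 0.8, 0.9`, the average annual rate of change
`AARC = 100[(Pn/P0)^(1/N) - 1]`, required additional AARC to reach a
target, the slope and relative indices of inequality (SII, RII) from
weighted regression on ridit midpoints, their time changes (AAC for
SII, AARC for RII), and the four-quadrant classification of joint
inequality change.

## Worked example

```python
from immucast import (CoverageTrendModel, ModelSpec, SurveyDesign,
                      generate_region_graph, simulate_surveys, simulate_truth)
from immucast.survey import derive_full_immunization, estimate_coverage
from immucast.trajectory import national_aggregate, project, exceedance_probability

graph = generate_region_graph(n_countries=2, regions_per_country=6, seed=1)
truth = simulate_truth(graph, range(2000, 2020), seed=2)
design = SurveyDesign(survey_years={c: (2000, 2007, 2013, 2019)
                                    for c in graph.country_ids})
children, assets = simulate_surveys(truth, design, seed=3)

cells = estimate_coverage(derive_full_immunization(children), "dpt3",
                          age_window=(12, 23))
res = CoverageTrendModel(cells, graph, ModelSpec("bym2_2")).fit(seed=4)

nat = national_aggregate(project(res.surface, 2030))
p2030 = float(nat.sel_year(2030).mean("draw").mean())
exc = exceedance_probability(nat, 0.8, 2030)
print(f"national DPT3 2030: {p2030:.3f}")
print(exc[["region", "prob"]].to_string(index=False))
```

prints (seed-exact):

```
national DPT3 2030: 0.785
region  prob
   C00 0.859
   C01 0.027
```

i.e. projected national DPT3 coverage averages 78.5% in 2030; country
C00 exceeds the 80% UHC threshold with posterior probability 0.86,
while C01 — this draw of the generator gave it a lower, flatter
trajectory — almost certainly does not (probability 0.03).

A thin CLI wraps the pipeline:

```bash
immucast run --outdir out --seed 1          # simulate -> fit -> project -> inequality
immucast validate --cells out/cells_dpt3.tsv --graph out/graph.txt \
    --variant besag_1 --variant bym2_2 --out out/validation.tsv
```

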