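# musenet

Dual network analysis of **music use, emotion-regulation self-efficacy,
alexithymia, anxiety and depression** in questionnaire cohorts — for
researchers in psychometrics and mental-health epidemiology who want the
two standard network views of such data as one tested, reproducible
pipeline:

1. an undirected **regularized partial-correlation network** (RPCN /
   Gaussian graphical model): nonparanormal Gaussianization, graphical
   lasso over a penalty path, EBIC (γ = 0.5) model selection; node
   centralities (strength, closeness, betweenness, one-step expected
   influence), the four bridge-centrality indices over instrument
   communities, bootstrap edge-weight confidence intervals, and case-drop
   correlation-stability (CS) coefficients;
2. a directed **Gaussian Bayesian network**: hill-climbing structure
   search under the Gaussian BIC (default 50 restarts, 100 perturbations),
   bootstrap arc strength/direction frequencies, the averaged network at
   the 85%/50% thresholds, and an OLS linear model per child node (β, SE,
   p per parent; R², residual standard error and F-test per model).

Edges of the RPCN are partial correlations ρᵢⱼ = −ωᵢⱼ/√(ωᵢᵢωⱼⱼ) from the
estimated precision matrix Ω̂; model selection minimizes
EBIC = −2·loglik + E·log n + 4γE·log p over the path.

Because respondent-level data of this kind are rarely deposited, the
package ships a first-class synthetic-cohort generator with *known ground
truth* — a sparse precision matrix for GGM recovery, a linear-Gaussian SEM
for Bayesian-network recovery, and a one-factor Likert item generator for
scoring and reliability — calibrated by default to the dimension means/SDs
of a cohort of 16,588 college students.  Scoring of the four instruments
(K10, TAS-20, RESE, HUMS) with their clinical cutoffs, plus Cronbach's
alpha, is included.

## Worked example

Run the full healthy-music-use pipeline on a synthetic cohort of 2,000
respondents (reduced bootstrap sizes; a few minutes on one CPU):

```python
from musenet import pipeline

cfg = pipeline.PipelineConfig(variant="healthy", n=2000, seed=5,
                              edge_bootstrap_R=200, casedrop_R=100,
                              bn_bootstrap_R=200, hc_restarts=10,
                              hc_perturbations=20)
res = pipeline.run_pipeline(cfg)
print(res["network"].edge_list().round(3).head(6))
```

The selected RPCN has 12 edges at λ = 0.0217; the first rows of the edge
list:

```
node_a node_b  weight
   HMU    POS   0.182
   HMU    EOT  -0.136
   POS    DES   0.296
   POS    ANG   0.170
   DES    ANG   0.363
   DES    Dep  -0.251
```

Healthy music use is positively tied to expressing positive affect and
negatively to externally oriented thinking; the self-efficacy dimensions
form a positive clique and managing despondency-distress is negatively
tied to depression — the structure planted by the generator's ground
truth.  Centrality (first rows) and stability:

```
     strength  closeness  betweenness  expected_influence_1
HMU     0.318      0.011          3.0                 0.046
POS     0.647      0.013          6.0                 0.647
DES     0.909      0.015         10.0                 0.408
ANG     0.612      0.011          0.0                 0.453

CS: {'strength': 0.75, 'closeness': 0.75, 'betweenness': 0.75,
     'expected_influence_1': 0.75}
```

A CS coefficient of 0.75 (the grid ceiling) means the centrality order
still correlates ≥ 0.7 with the full sample in ≥ 95% of subsamples after
dropping 75% of respondents — a very stable network.  The averaged
Bayesian network (first arcs, strength = bootstrap adjacency frequency,
direction = orientation frequency) and child-node models:

```
parent child  strength  direction
   Anx   DIF       1.0      0.640
   Anx   Dep       1.0      0.560
   DES   ANG       1.0      0.895
   DES   Dep       1.0      0.845
   DIF   DDF       1.0      0.945

child parent  estimate    se  p_value  r_squared   rse
  POS    HMU     0.226 0.022      0.0      0.051 0.974
  DES    POS     0.454 0.020      0.0      0.206 0.891
  ANG    DES     0.435 0.021      0.0      0.288 0.844
```

`pipeline.write_outputs(res, "out/")` writes the report bundle: CSV
tables, a TSV edge list, a DOT export of the averaged DAG and a JSON
manifest with every seed and parameter (sufficient to reproduce the run
bit-identically).

The same stages are available from the shell:

```sh
musenet simulate -n 2000 --seed 5 --out out/
musenet run --variant healthy --seed 5 --out out/
```

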