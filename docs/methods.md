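# Methods

`musenet` implements a dual network analysis of questionnaire data on music
use, emotion-regulation self-efficacy, alexithymia, anxiety and depression:
an undirected regularized partial-correlation network (RPCN) with centrality
and bootstrap-stability analysis, and a directed Gaussian Bayesian network
with bootstrap arc averaging and per-child linear models.  This note
documents the models, the defaults and the design decisions; nothing here
reports a number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Instruments and scoring

Four self-report instruments, all 5-point Likert (1..5):

| Instrument | Items | Dimensions (range) |
|---|---|---|
| K10 | 10 | anxiety (4–20), depression (6–30), total (10–50) |
| TAS-20 | 20 | DIF (7–35), DDF (5–25), EOT (8–40), total (20–100) |
| RESE | 12 | POS, DES, ANG (each 4–20) |
| HUMS | 13 | HMU (5–25), UHMU (8–40) |

K10 risk levels are the step function 10–19 / 20–24 / 25–29 / 30–50
(levels 1–4).  TAS-20 categories are ≤51 none, 52–60 possible, ≥61
alexithymia present; the dominant facet is the argmax of per-item facet
means, with exact ties reported jointly in the fixed order DIF < DDF < EOT.

Assumptions made where the instruments' short descriptions are silent, all
configurable keyword arguments:

* **K10 anxiety/depression split** — not printed anywhere; we ship the
  widely used assignment (anxiety items 2, 3, 5, 6; depression items 1, 4,
  7, 8, 9, 10).
* **TAS-20 keying** — standard facet membership and reverse-keyed items
  {4, 5, 10, 18, 19}, recoded 6 − x before summation.
* **RESE and HUMS item blocks** — contiguous blocks in instrument order
  (RESE: POS 1–4, DES 5–8, ANG 9–12; HUMS: HMU 1–5, UHMU 6–13).  Override
  these to match a particular questionnaire export.
* **RESE range** — four items per dimension arithmetically give 4–20; the
  occasionally quoted "5 to 20" is inconsistent with four items and is not
  used.
* **Missing data** — listwise deletion by default; optional per-item
  rounded-mean imputation behind a flag.

Cronbach's alpha is the classical `k/(k−1) · (1 − Σ var(item)/var(sum))`
with sample variances; a zero-variance total raises an error rather than
returning a value.

## Synthetic cohorts

Raw respondent-level data for this kind of study are typically not
deposited, so the generator is a first-class module: it defines the study
conditions under which every recovery claim is tested.

* **Dimension mode** (`generate_dimension_scores`) draws rows from
  N(0, Ω⁻¹) for a user-specified sparse, positive-definite precision matrix
  Ω, then maps each column affinely to a target mean and SD.  Per-column
  affine maps leave partial correlations invariant, so Ω's zero pattern and
  the partial correlations ρᵢⱼ = −ωᵢⱼ/√(ωᵢᵢωⱼⱼ) are exact ground truth.
  Default calibration targets are the whole-sample dimension means and SDs
  of the motivating cohort of 16,588 college students (anxiety 7.68 ± 2.90,
  UHMU 16.54 ± 5.94, and so on); at that n the sample means land well
  within 1% of target.
* **SEM mode** (`sample_from_sem`) simulates a linear-Gaussian structural
  equation model over a DAG in topological order (child = intercept +
  Σ coef·parent + Gaussian noise), the generating process assumed by
  Gaussian Bayesian-network learning.  `implied_covariance()` gives the
  closed-form (I−B)⁻¹D(I−B)⁻ᵀ covariance for consistency checks.
* **Item mode** (`generate_item_responses`) produces integer Likert items
  from a per-dimension one-factor model.  Equal loadings are solved from a
  per-instrument Cronbach's-alpha target via r = α/(k − α(k−1)); latents
  are discretized through standard-normal quintile thresholds shifted (by
  Brent root-finding) so the expected scale-sum mean matches the
  calibration target.  Scale-sum SDs are approximate only: with item
  variance fixed at 1 the sum SD is determined by k and the inter-item
  correlation, so it cannot be matched independently of alpha.  The
  discretization also attenuates alpha slightly relative to its latent
  target.

The shipped 9-node precision matrix and DAG (one per analysis variant —
"healthy" includes HMU and excludes UHMU, "unhealthy" the reverse) are
illustrative round-number structures qualitatively echoing the reported
networks (a positive self-efficacy clique, the alexithymia triangle with a
negative DIF–EOT partial, anxiety–depression comorbidity, self-efficacy
protective against depression, music use attached to POS/EOT or to the
symptom cluster).  They are **not** estimates of any empirical network;
recovery tests demonstrate that the estimators work under such conditions,
not that real data would yield these graphs.  Real questionnaire data
differ in ways the generator deliberately ignores: discreteness and skew of
sum scores (dimension mode is Gaussian), item-level multidimensionality,
and respondent heterogeneity.

## Regularized partial-correlation network

1. **Transform.**  Default is the nonparanormal "shrunken ECDF" transform:
   per column, ranks → ECDF winsorized to [δₙ, 1−δₙ] with
   δₙ = 1/(4 n^{1/4} √(π log n)) → standard-normal quantiles → rescaled to
   unit sample variance.  It is rank-based, hence invariant under monotone
   column transformations.  Plain z-scoring and the z-score-then-npn
   composition are also available (`transform=` argument); since the npn
   transform is rank-based, applying it after z-scoring gives the same
   result as applying it directly, so the default `"npn"` covers both
   orderings of the standardize-then-Gaussianize recipe.
2. **Graphical lasso path.**  100 penalties, log-spaced from
   λ_max = max |off-diagonal sample covariance| (the smallest penalty giving
   an empty graph) down to λ_max/100.  The inner solver is scikit-learn's
   graphical lasso; `tol`, `enet_tol` and `max_iter` are exposed because
   the inner-lasso default tolerance (1e−4) leaves the solution ~1e−3 from
   the optimum, which matters when validating against an independent
   solver.  Non-converged penalties are dropped with a warning.
3. **EBIC selection.**  EBIC(λ) = −2·loglik(Ω̂) + E log n + 4γE log p with
   E the edge count and γ = 0.5 by default.
4. **Edge thresholding (default on).**  At large n the EBIC-selected
   graphical lasso retains many tiny spurious edges (in our n = 5,000
   recovery setting, about eight edges with |ρ| ≤ 0.023).  We therefore
   zero, after selection, edges below the detection bound
   √(log(p(p−1)/2)/n) — the thresholded-glasso rule familiar from the
   psychometric-network estimation literature, which restores sparsistency.
   Pass `threshold=False` for the plain EBIC-glasso solution.

A caution on the path itself: edge counts along the λ grid are *usually*
monotone but not guaranteed to be — with suppression structure (e.g. a
chain, where a marginal correlation vanishes conditionally) a small edge
can enter the path and leave it again.  The monotonicity test therefore
uses data without suppression effects.

## Centrality

Conventions standard in this literature: strength = Σ|w|, one-step expected
influence = Σw (signed), shortest paths on distances 1/|w| (Dijkstra),
closeness = 1/Σ distances to reachable nodes (isolated or unreachable
pairs contribute nothing; a node reaching nobody gets closeness 0),
betweenness by Brandes accounting with fractional credit among equal-length
paths, path-length ties compared at 1e−10.  Bridge variants restrict to
cross-community edges/pairs; bridge closeness is the inverse *mean*
distance to out-community nodes.  The default community partition is
instrument membership ({music use}, {POS, DES, ANG}, {DIF, DDF, EOT},
{Anx, Dep}); it is configurable because empirical workflows rarely state
theirs.  Tables are emitted raw and z-standardized (profiles are usually
plotted as z-scores).

## Stability

* **Edge bootstrap**: R row-resamples with replacement, percentile 2.5/97.5
  intervals per edge; failed replicates are dropped and counted.  Percentile
  (not BCa) intervals: simplest to verify and the convention of the
  workflow.  Being percentile-based, an interval need not cover the point
  estimate in pathological cases, but lower ≤ upper always holds.
* **Case-drop CS coefficient**: for drop proportions q in
  {0.05, 0.15, …, 0.75}, R subsamples of ⌈(1−q)n⌉ rows without
  replacement; Pearson correlation of subsample centralities with the
  full-sample ones; CS(cor = 0.7) is the largest q such that ≥95% of
  correlations are ≥0.7 at every grid proportion up to q (so a failure at
  the smallest proportion gives CS = 0, and 0.75 is the attainable
  ceiling).  Undefined correlations (constant centrality vectors, e.g.
  all-zero betweenness) count as failures — a conservative convention.

## Gaussian Bayesian network

* **Score**: decomposable Gaussian BIC, per node the OLS/MLE log-likelihood
  minus (k+2)/2 · log n, counting parent coefficients, intercept and
  residual variance.  Local scores come from the Gram matrix of [1, X], so
  one evaluation is O(k³) independent of n, and are cached per
  (child, parent-set) — this is what makes bootstrap × restarts tractable.
  Singular parent designs (and exact collinearity, which drives σ̂² to 0)
  score −∞.  The score is score-equivalent: Markov-equivalent DAGs tie
  exactly, so learned orientations within an equivalence class are
  tie-break artifacts; only the bootstrap direction frequencies carry
  orientation evidence.
* **Hill climbing**: steepest-ascent over add/delete/reverse arc moves
  (acyclicity checked on every candidate), from the empty graph to a local
  optimum; each of the default 50 restarts perturbs the incumbent best DAG
  by 100 random legal moves and climbs again.  Move ties are broken by
  (operation, parent, child) order and improvements must exceed 1e−9, so
  the search is deterministic given the seed.
* **Bootstrap averaging**: R = 1,000 (default) row-resamples of size n,
  hill climbing per resample with 3 restarts / 15 perturbations — a small
  amount of per-replicate restarting escapes orientation-artifact local
  optima that otherwise inflate spurious adjacency frequencies, at ~3× the
  single-climb cost.  Arc strength is the adjacency frequency; direction is
  the orientation frequency among adjacency-containing replicates.
* **Averaged network**: keep pairs with strength ≥ 0.85, orient by
  direction > 0.5 (strict, so exact 50/50 pairs are excluded with a
  warning); any residual directed cycle is resolved by dropping its
  weakest arc; arcs are reported in descending strength order.
* **Child models**: per child with ≥1 parent, OLS with intercept; per
  parent β, SE and two-sided t-test p; per model R², RSE =
  √(RSS/(n−k−1)) and the overall F-test p.  No multiple-testing
  correction is applied.

## Pipeline

`run_pipeline` ties the stages together for one variant: input (CSV of
dimension scores, CSV of raw items auto-scored, or the synthetic
generator), descriptive summary, RPCN + centralities, stability, Bayesian
network + regressions, and a JSON manifest recording every parameter and
per-stage seed (derived deterministically from the master seed), which
suffices to reproduce a run bit-identically.  The two variants run on the
same respondents and differ only in which music-use column enters.

## Problem sizes used in the checks

Recovery and calibration checks run at the sizes they state: generator
calibration at the full cohort size n = 16,588; sparse-precision recovery
at n = 5,000 (≥90% of true-zero edges excluded, mean absolute error ≤0.05
on true edges); DAG-adjacency recovery at n = 5,000 with R = 200 bootstrap
replicates (≥70% of true adjacencies, nothing outside the true moral
graph); stability behavior at n = 3,000 with R = 100 and a 20-penalty
grid.  Bootstrap replicate counts below the full-scale defaults are used
where the check is about ordering or thresholds rather than about
precision of the frequencies themselves.

## Known limitations

* The Likert generator matches sum means, not sum SDs, and its one-factor
  structure is per dimension with a shared per-instrument alpha target.
* Closeness in disconnected graphs depends on the reachable-only
  convention; other packages return other conventions (e.g. harmonic
  closeness), so cross-package comparisons need care.
* The hill climber explores the DAG space, not the equivalence-class
  space; bootstrap direction frequencies near 0.5 should be read as
  "undetermined", and the strict >0.5 rule will drop such pairs entirely.
* Cycle resolution in the averaged network is a repair heuristic; it
  fires rarely (high-strength cycles are unusual) but is not an estimator
  of the best acyclic subgraph.
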