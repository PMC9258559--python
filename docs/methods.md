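# Methods

## Model

`prevtrend` fits a Gaussian linear mixed model to logit-transformed survey
prevalence estimates. Writing t for calendar time rescaled to [0, 1] over
the study window (default 1990–2020), the marginal covariance of the
outcome vector is

    V = σ²_a Z_a Z_aᵀ + Σ_i Z_i G Z_iᵀ + diag(σ²_e + κ s²),

where Z_a is the random part of the population P-spline, Z_i stacks a
country's random intercept and spline columns, and s is each record's
known logit-scale sampling SE. Fixed effects are profiled out by
generalized least squares; the variance components are estimated by
maximizing the ML or REML likelihood (REML for reported fits, ML when
comparing candidate structures by AICc, since REML likelihoods are not
comparable across fixed-effect sets). The likelihood is evaluated through
the Woodbury identity in the total random-effect dimension m (spline
columns + countries × (q+1)), so the per-evaluation cost is O(n·m²)
rather than O(n³); on region-scale data (≈1 800 records, m ≈ 120) a full
REML fit takes about one second.

### P-spline as random effects

The population trend uses cubic B-splines on equally spaced knots
(candidates: 2- and 4-year spacing) with a second-order difference
penalty ‖Dθ‖². Any coefficient vector decomposes as θ = Nδ + Tα with
N a basis of null(D) (constant + linear) and T = Dᵀ(DDᵀ)⁻¹, so the
penalized fit equals a mixed model in which α ~ N(0, σ²_e/λ · I): the
smoothing parameter becomes a variance ratio estimated by REML instead of
a tuning constant. In the full model the null-space part is represented
by the intercept and linear-time fixed effects; the basis is clamped
(full boundary-knot replication) and evaluation outside the knot domain
raises rather than extrapolating.

### Covariate encoding

* **Age.** Records carry arbitrary sub-intervals of [0, 60) months. Each
  record receives six weights — its fractional month overlap with the
  standard partitions 0–5, 6–11, 12–23, 24–35, 36–47, 48–59 — and the
  last five enter as fixed effects (0–5 months is the reference; the six
  weights sum to one, so one column is redundant). A complete-interval
  record thus has weights (0.1, 0.1, 0.2, 0.2, 0.2, 0.2).
* **Sex.** Effect-coded: male +0.5, female −0.5, both-sex strata 0, which
  places a combined-sex record exactly at the mean of the two sexes
  without row duplication.
* **Income.** A low/middle-income (LMIC) indicator; an optional
  income × time interaction is off by default.

### Measurement layer

* **Limit of detection.** A recorded prevalence of exactly 0 cannot be
  logit-transformed; it is replaced by 1/(2n) with n the unweighted
  sample size. Prevalence exactly 1 is treated symmetrically (1 − 1/(2n))
  behind a flag defaulting on.
* **SSE transfer.** Sampling SEs are reported on the proportion scale and
  enter the model on the logit scale via the first-order delta method,
  s = sse/(p(1−p)).
* **SSE imputation.** Records with a sample size but no SSE get
  sqrt(deff · p(1−p)/n) with design effect deff = 2 by default (a
  conventional cluster-survey inflation; configurable). Records missing
  *both* SSE and sample size are excluded — they carry no usable
  uncertainty and no way to reconstruct one.
* **Residual model.** Var(ε) = σ²_e + κ·s² with κ fixed at 1: the known
  sampling variance is an additive offset, which nests homoscedasticity
  (s = 0) and lets σ²_e absorb genuine model residual.

### Country covariance structures

G over the (q+1) country effects may be compound-symmetric
(σ²[(1−ρ)I + ρJ], ρ ∈ (−1/q, 1)), diagonal, or unstructured
(log-Cholesky, limited to dimension ≤ 6 to keep the parameter count
sane). The country spline basis has exactly q columns: cubic with q − 4
interior knots for q ≥ 4, degree q − 1 with no interior knots for
q ∈ {1, 2, 3}.

### Optimization

Variance components are optimized on unconstrained transforms (log
variances, a scaled-logistic map for the CS correlation onto its
positive-definiteness interval, log-Cholesky for unstructured G) with
L-BFGS-B from documented starting values (OLS residual variance split
across components). If the first search fails, up to three restarts are
taken from deterministically jittered starts (fixed generator), so
fitting is bit-reproducible. Individual components can be frozen at given
values (`fit(..., fix=...)`), which is how degenerate limits (all random
effect variances zero) are exercised exactly. AICc counts k = fixed
effects + free variance parameters against n = observation rows; both
conventions are recorded in the selection table.

## Prediction

A prediction for country i at year t combines the fixed profile, the
population-spline BLUP, and (when the country has data) the country BLUP.
The logit-scale variance is the exact BLUP prediction-error variance

    Var(f̂ − f) = u*ᵀΣu* − u*ᵀ ΣUᵀV⁻¹UΣ u* + dᵀ(XᵀV⁻¹X)⁻¹d,
    d = x* − XᵀV⁻¹UΣ u*,

which carries all cross-covariances between fixed effects, population
spline and country effects (verified in tests against a dense inverse of
Henderson's mixed-model equations). For a country with no data the
country BLUP is zero and the full prior variance z_cᵀG z_c is added.
Confidence intervals use est ± 1.959964·se on the logit scale, mapped
endpoint-wise through the inverse logit (bounds stay in [0, 1] and the
ordering PI ⊇ CI ∋ estimate is preserved exactly); prediction intervals
widen the SE by σ²_e — they target a hypothetical perfectly measured
survey — and a per-request flag can add a survey sampling variance s².

## Cross-validation

Folds are formed at the survey level: distinct source ids are shuffled by
a mandatory seed and dealt round-robin, so all records of a survey share
a fold and fold sizes differ by at most one source. Each fold's model is
refit on the remaining folds and each held-out record is predicted under
its own covariate profile, conditioning on the training-data BLUP of its
country (its country usually has *other* surveys; a strict new-country
mode is available). Metrics — coverage of 95% prediction intervals,
average and median bias (predicted − observed), MSE, RMSE, MAD — are
computed per fold on the proportion scale and averaged across folds.
Held-out coverage is scored against prediction intervals that include the
held-out record's own sampling variance, because an observed survey
estimate carries sampling noise on top of model residual; without that
term nominal coverage is unattainable by construction. The age-group
analysis labels each record by the partition holding its largest age
weight (ties, e.g. the complete interval, go to "other"), computes
fold-level RMSE and MAD per group, and compares groups with a one-way
ANOVA using the fold as the replication unit.

## Synthetic data

The generator draws from exactly the model above: country incomes at a
fixed LMIC proportion, country effects from a compound-symmetric G,
population-spline coefficients from N(0, σ²_a) (so recovery and
calibration tests are well-specified; a fixed coefficient vector may be
supplied instead), fixed effects chosen to produce complete-interval
prevalence means near 0.16 (LMIC) and 0.02–0.05 (HIC) with a declining
trend, and a per-record residual N(0, σ²_e). Observations are binomial
draws at effective size n/deff, which yields internally consistent SSEs,
SEs that peak toward prevalence 0.5, legitimate zero-prevalence records
(whose SSE is recorded as missing — a zero count carries no usable SE)
and occasional missing SSEs by masking. Survey layouts mix complete-
interval rows, both-sex and sex-stratified partition rows, and
nonstandard partial intervals, at probabilities set to reproduce a sparse
region's corpus: ≈26 countries, ≈95 sources, ≈1 700–1 800 records, ≈18
records per source. Survey sample-size draws are lognormal with median
8 000 children (cells of a few hundred effective children after sex ×
partition splitting), the scale of national anthropometric surveys.

What the generator does *not* emulate: country-specific historical
trajectories, survey-methodology heterogeneity across sources, non-random
missingness of SSEs, and correlation between a country's income class and
its survey frequency. Passing tests therefore demonstrate correctness of
the estimator and calibration machinery under the stated model, not
robustness to those real-data features.

### A known small-sample property worth stating

Because survey SEs are estimated from the survey's own observed
proportion (in real data as in the generator), the inverse-variance
weights are slightly correlated with the outcome noise: cells whose
observed prevalence fluctuates upward (below 0.5) look more precise and
receive more weight. At realistic cell sizes this pulls low-prevalence
cells up by O(1/n_eff) on the logit scale — about 0.01 here — which
attenuates the age-partition contrasts detectably when averaged over many
replicates, although it is negligible for any practical use (≈0.1–0.2
percentage points of prevalence). This is a property of weighting by
self-estimated precision, not of the fitting algorithm; it would affect
any implementation of the method, and it vanishes as survey cells grow.

## Numerical choices and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| knot spacing | 2 y (candidate 4 y) | population P-spline, cubic, clamped |
| penalty order | 2 | null space = linear trend; configurable |
| q (country splines) | 3 | candidate grid {0, 2, 3, 4, 5} |
| G structure | compound symmetry | candidates: diagonal, unstructured |
| κ | 1 | fixed; s enters as known variance |
| deff (imputation) | 2 | cluster-survey design effect |
| study window | 1990–2020 | spline domain; configurable |
| k (CV folds) | 10 | survey-level split, seed mandatory |
| convergence | ftol 1e-12, gtol 1e-7 | L-BFGS-B, ≤ 3 jittered restarts |

Degenerate inputs: empty record lists are rejected where they are
meaningless (summaries) and pass through as empty designs where they are
not; prevalence exactly 0/1 without a sample size is an unrecoverable
record; a CS correlation outside (−1/q, 1), a non-PSD G or a singular
fixed-effect design raise with named columns. Problem sizes in the test
suite (tiny oracle instances of 12 rows; 12–20 country datasets for
calibration and selection checks; the full ≈26-country scale for recovery)
were chosen so the whole suite documents the method at the scale it is
meant for while individual checks stay sharp.

## Limitations

* The delta-method transfer of SSEs to the logit scale is first-order;
  for very small prevalences with small samples the implied logit-scale
  variance is approximate.
* Income classification is a fixed input; the model does not propagate
  uncertainty in it, and the default specification carries no
  income × time interaction.
* No spatial or between-country correlation beyond the shared population
  curve; no region-level aggregation with population weights.
* Extrapolation beyond the spline domain is refused rather than modelled.
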