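# Methods

## Scope and data model

`polyomic` analyzes a longitudinal multi-omic cohort: per-sample feature
tables for up to four omic layers (MGN species counts, MTS pathway counts,
VRM virus counts, MBL compound intensities) plus per-sample metadata
(participant, three-level diagnosis collapsing to binary IBD status, age,
sex, race, antibiotic use, study site, collection week).  "Sample" means one
specimen; a participant contributes several samples over the study, and the
diagnosis is constant within participant.  All tables are tab-separated
text; the canonical in-memory orientation is rows = samples.

## Preprocessing

Count layers are compositional (library-size constrained), so they are
centered log-ratio (CLR) transformed: each row x is replaced by
ln((x + c) / g(x + c)) with g the row geometric mean.  The pseudocount c
defaults to 0.5 (half-count replacement; configurable) because CLR is
undefined at zero counts.  Intensities are log10(x + c) with default c = 1.

Feature filters run after the transform, per layer:

| layer | transform | presence rule (on raw values) | collinearity | SD filter |
|-------|-----------|-------------------------------|--------------|-----------|
| MGN   | CLR       | —                             | —            | < 1 removed |
| MTS   | CLR       | —                             | r > 0.95     | < 1 removed |
| VRM   | CLR       | removed if in < 5% of samples | —            | < 0.1 removed |
| MBL   | log10     | kept only if in > 99%         | r > 0.95     | < 0.1 removed |

Presence is computed on the raw (pre-transform) nonzero entries — the only
self-consistent reading once a pseudocount has removed all zeros.  The VRM
rule removes features found in strictly fewer than the threshold fraction of
samples (so exactly 5% presence is kept); the MBL rule keeps strictly more
than 99%.  The collinearity filter removes one member of each offending
pair, chosen by a seeded RNG (deterministic per seed; the surviving count is
stable across seeds for duplicate-style blocks).  SD uses the sample (n−1)
denominator.  Filters are fit on training samples only and the surviving
feature list frozen for validation samples (`filter_scope="all"` reproduces
the pooled alternative); the row-wise transforms carry no cross-sample state,
so no leakage enters through them.

## Selection model

Per layer, binary diagnosis is regressed on the transformed features with an
L1 penalty, unpenalized demographic covariates, and crossed random
intercepts for site and participant.  The solver works on the penalized
joint (h-likelihood) objective:

* each IRLS iteration forms the working weighted least-squares problem at
  the current linear predictor, solves the unpenalized block (intercept,
  covariates, and random intercepts, ridged by the prior precisions)
  exactly as one linear system — coordinate-wise updates zigzag badly there
  because the participant indicators are nearly collinear with the
  intercept — and then runs soft-threshold coordinate descent with an
  active-set strategy over the penalized features only;
* each IRLS proposal is backtracked against the true objective, so the
  recorded objective trace is non-increasing; a damped Newton step refreshes
  the intercept modes between variance updates;
* features are standardized internally (training mean/SD) and coefficients
  back-transformed, since the L1 penalty is scale-sensitive.

Convergence: relative objective change below 1e-6 (configurable), iteration
cap 500.  Coefficients below 1e-7 on the standardized scale are clipped to
exactly zero when reporting the selected set.

### Variance components

The diagnosis is constant within participant, which makes the participant
intercept variance degenerate under marginal maximum likelihood: with
repeated samples per participant, intercepts that interpolate the diagnosis
are always preferred (verified here with both Laplace and adaptive
Gauss–Hermite criteria), which would starve the features of signal and is
not the estimand of interest.  The variances are therefore treated as
bounded shrinkage parameters: estimated by the iterated quasi-likelihood
fixed point sigma² ← (||u||² + tr[(Z'WZ + D⁻¹)⁻¹])/q, capped at 1.0 on the
logit scale, floored near zero, and — along the penalty path — estimated
once on the null (covariate-only) model and then held fixed, so the empty
model at lambda_max is a stationary point by construction and per-lambda
differences reflect the penalty alone.  Random factors with fewer than two
levels, or in which every group is observed once, are dropped: they carry no
repeated-measures information.

### Penalty path and elbow

lambda_max is the largest absolute score-equation component for the
penalized block at the null fit; the grid is log-spaced down to
lambda_max × min_ratio (default 15 points, ratio 0.01), fit largest-first
with warm starts.  The elbow maximizes the discrete second difference of the
selected-count curve, ties breaking toward the larger penalty; a flat or
linear curve falls back to the grid point whose count is nearest half the
maximum, with a warning.  The elbow definition is a repository convention
(the underlying idea — the knee of the count-versus-penalty curve — admits
several formalizations).

### Refit and separation

The elbow-selected features are refit unpenalized under the same structure;
the feature weights from this refit (covariates excluded) define the score.
Synthetic cohorts with strong planted effects are often separable at
lambda = 0; descent stops early once any standardized coefficient passes 12
(odds ratios beyond any biological plausibility) and the fit is retried with
a unit-Gaussian ridge on the standardized coefficients, recorded on the
result.  Wald standard errors come from the fixed-effects block of the
Fisher information with the random-intercept block profiled out.

## Scores, split, evaluation

Raw scores are the weighted feature sums; standardization constants (mean,
n−1 SD) come from the training samples (`standardize_scope="pooled"` gives
the joint alternative) and standardized scores are averaged per participant.
The validation set is the `n_validation` participants (default 30) with the
most complete-all-layers samples, ties broken by fewest incomplete samples,
then participant id; all of a participant's samples share its assignment.

Validation evaluation collapses to one averaged row per participant, so the
evaluation models are ordinary logistic regressions: AUC is the
Mann–Whitney probability (ties half) with a DeLong 95% CI; OR per SD comes
from `diagnosis ~ score + age + sex` (a score-only variant is a flag) with
Wald CIs; Nagelkerke R² rescales Cox–Snell by its attainable maximum.  The
combined model regresses diagnosis on the four layer scores plus age and
sex over participants whose validation samples carry all four layers,
reporting per-layer ORs, the full/covariate-only/scores-only R², the score
correlation matrix, and leave-one-omic-out refits.  Evaluation fits that are
(quasi-)separated fall back to a ridge-stabilized IRLS fit and are flagged;
an OR under separation is reported with an unbounded CI.  Perfectly
collinear score columns are dropped with a warning (coefficients reported as
NaN).

## Synthetic cohort generator

The generator emulates the structure the pipeline targets: ~130 participants
across 5 sites with realistic site/race/antibiotic marginals, 2–8
longitudinal samples per participant over 52 weeks, and four layers with
planted case–control effects.  Generation is case-control conditional:
diagnosis is assigned first, and each layer's causal features get a mean
log-abundance shift delta (random sign) in cases, so the planted support is
exactly the discriminative set the selector should recover.  Per-sample
latent log-abundances add a participant intercept, a site intercept, and a
per-sample scalar shift (depth-like), then per-feature noise; count layers
exponentiate, normalize, draw one multinomial per sample at the library
size, and apply a per-feature dropout mask; the intensity layer
exponentiates directly.  Dropout rates are Beta-distributed per feature
around the layer mean (concentration 2) so sparse layers contain both rare
and common features — the regime the presence filters are written for.
Each (sample, layer) pair is dropped independently with the layer's
missingness probability.  Each layer consumes its own RNG stream derived
from the master seed, so adding a layer never perturbs another.

Defaults chosen once (no external source prescribes them): library sizes
1e5 (2e4 for the sparse virus layer), per-feature noise SD 1, base
log-abundance SD 1, samples per participant uniform on 4–8 (2–4 in the
scaled-down test designs), per-layer missingness 10–35%, zero-inflation
means 0.35 / 0.25 / 0.90 / ~0 for MGN / MTS / VRM / MBL, participant and
site intercept SDs 0.5 and 0.25.  The ready-made cohort-scale design plants
effect sizes 0.6 / 0.9 / 1.8 / 1.4 log-units with 14 / 22 / 6 / 14 causal
features per layer — strongest in the metabolomic and viromic layers —
mirroring the predictive ordering the framework is designed to expose.

What the generator does not emulate: phylogenetic correlation among taxa,
within-participant temporal autocorrelation beyond the participant
intercept (samples are i.i.d. around the participant mean), batch effects,
and measurement-platform artifacts.  Passing tests therefore demonstrate
that the pipeline recovers planted, exchangeable, participant-level signals
under compositional noise and missingness — not that it is robust to the
full complexity of real multi-omic data.  Note also that a scalar
participant intercept on log-abundances cancels under closure plus CLR in
the count layers (a genuine property of compositions), so the planted
random-intercept variance mainly stresses the intensity layer and the
mixed-model machinery.

## Numerical conventions and degenerate inputs

Working-weight floor 1e-6 in IRLS, 1e-10 elsewhere; variance floor 1e-8 and
cap 1.0; coefficient zero-clip 1e-7 (standardized scale); collinearity and
co-occurrence treat zero-variance features as correlation 0 (never removed
by that filter) and NaN respectively; a score model with zero selected
features is kept as an affine identity (score ≡ 0, chance AUC by the tie
convention) so a pipeline run stays total; single-class evaluation inputs
raise rather than return vacuous numbers.

## Problem sizes used in the checks

The test suite and the acceptance script run on scaled-down cohorts chosen
as the package's own desk-scale defaults: 50–130 participants, 25–100
features per layer, 8–15 penalty grid points, 10–20 seeds for the
statistical criteria.  The full-shape design (130 participants, 578 / 421 /
239 / 596 features) is generated and sanity-checked in tests but not pushed
through the solver there.
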