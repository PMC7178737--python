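# Methods

## Scope

`twinlat` implements the complete analysis pipeline of a twin/singleton
handedness study: laterality scoring from raw questionnaire and pegboard
data, descriptive and inferential prevalence statistics, and classical
twin-design variance decomposition (univariate ACE family and bivariate
Cholesky models) estimated by maximum likelihood.  Because raw participant
data of such studies are typically not public, a synthetic cohort
generator that inverts the assumed models is a first-class component:
every stage of the pipeline is testable end to end at desk scale.

## Laterality scoring

The preference instrument is a ten-item hand-preference inventory
(a child-adapted Edinburgh Handedness Inventory variant: writing, drawing,
throwing, scissors, toothbrush, chopsticks, spoon, knife, broom, box lid).
Point assignment per item: "always" puts 2 points in the preferred
column, "usually" puts 1, "either" puts 1 in both columns.  The laterality
quotient is EHI = (RH − LH)/(RH + LH) over the column totals, in [−1, +1];
EHI2 binarises at zero with a score of exactly zero assigned to the
non-right-handed (NRH) class.  Writing- and drawing-hand binary measures
code right = 1 and left-or-no-preference = 0.  A switch-inference flag
marks subjects who write with the right hand while the left column total
over the eight non-pen items exceeds the right total.

Design choices where the scoring rules are underdetermined:

* A "usually" response contributes (1, 0) — 1 point in the preferred
  column and none in the other.  This keeps the ±1 endpoints attainable.
* Missing items are excluded from the sums, never imputed; a record with
  no usable items yields a missing score (and an error at the functional
  API, which refuses a silent zero).  The number of items used is
  reported alongside the score.
* Pegboard "best three of five" trials are the three smallest times,
  ties keeping earlier trials, so scoring is deterministic.  PegQ =
  2(L − R)/(L + R) on the best-three means; positive values mean a faster
  right hand; PegQ2 binarises at zero the same way as EHI2.

## Prevalence statistics

Contingency comparisons use the uncorrected Pearson chi-square
(no Yates continuity correction anywhere; the 2×2 statistics in the
published tables this package reproduces only match the uncorrected
form).  Per-item tables are built from valid responses for that item, so
denominators can differ across items.  The Bonferroni level for a family
of m item comparisons is α/m.  Item-total correlations default to the
uncorrected item-vs-total form with an item-rest option; item scores are
the signed point difference (right − left points ∈ {−2..2}).  Cronbach's
alpha uses the standard k/(k−1)(1 − Σ var_i / var_total) formula.  The
sample-by-sex two-way ANOVA defaults to Type III sums of squares with
sum-to-zero contrasts (statsmodels OLS); Types I and II are available
because published F values rarely state the convention.  Correlation
matrices are pairwise-complete Pearson with two-sided p-values; binary
measures enter as 0/1 codes and sex as 0 = male, 1 = female.

## Twin models

Phenotypic variance is decomposed into additive-genetic (A), shared-
environment (C) and non-shared-environment (E) components.  All models
use the path (Cholesky) parameterization, so implied component
covariances are positive semi-definite by construction and negative
variance estimates cannot occur; reported quantities are standardized
squares, which removes the sign indeterminacy of paths.  The expected
pair covariance has within-twin block AA′ + CC′ + EE′ and cross-twin
block k·AA′ + CC′ with k = 1 (MZ) or 0.5 (DZ).  No dominance component
is modelled, and opposite-sex DZ pairs are pooled with same-sex DZ pairs
(the usual practice after homogeneity testing); age and sex are not
regressed out of the means by default — the homogeneity ladder carries
the sex test instead.

**Continuous traits** are fit by full-information maximum likelihood:
each pair contributes the multivariate-normal log-density of its observed
sub-vector, so single-twin pairs are retained.  Internally the FIML
objective is evaluated from sufficient statistics grouped by zygosity ×
missingness pattern × mean label (count, mean, scatter), making each
evaluation independent of sample size; the grouped form is checked in the
tests against a direct per-pair density summation to 1e−8 relative.

**Binary traits** use the liability-threshold model: a standard-normal
liability exceeds threshold τ, total liability variance fixed at 1.
Concordance-cell probabilities are bivariate-normal orthants at liability
correlation a² + c² (MZ) or 0.5a² + c² (DZ), computed from Owen's-T
(absolute accuracy well below 1e−8, validated against 2-D quadrature);
pairs with a missing co-twin contribute univariate tail probabilities.
The unit-variance constraint is enforced exactly by spherical
parameterization of (a, c, e).

**Bookkeeping** follows the convention of standard twin-modelling
software: df = (number of non-missing trait observations) − (free
parameters) and AIC = −2LL − 2·df.  Note this AIC differs from the common
−2LL + 2k form by a data-dependent constant; rankings on the same data
are identical.  Free-parameter counts: continuous univariate ACE/AE/CE/E
= 4/3/3/2 (mean + paths); binary = 3/2/2/1 (threshold + angles);
bivariate = 2 means + the retained Cholesky entries (full ACE: 11).

**Model comparison.**  Likelihood-ratio tests use the naive chi-square
reference, as is conventional in this literature, although variance
components on the boundary make the test conservative (the 50:50 mixture
reference would halve the p-values; the naive convention is retained for
comparability and documented here).  The bivariate ladder fits, in order:
full ACE; AE (both C factors dropped); AE1 (AE with the genetic cross
path a21 = 0 — independent genetic factors); AE2 (AE with a22 = 0 —
a single shared genetic factor); CE; E — and selects by minimum AIC.
A converged bivariate fit can be re-expressed as a correlated-factors
model: per-trait standardized components plus factor correlations
rX = (XX′)₁₂/√((XX′)₁₁(XX′)₂₂), undefined when a trait has no variance
from that component.  The reconstruction is algebraically exact and
tested to 1e−10.

**Homogeneity ladder.**  Before structural modelling, a saturated
Gaussian pair model (means and SDs by zygosity × twin order, pair
correlations by zygosity, a sex term on the mean) is successively
constrained: equal across twin order, then zygosity, then sex, each step
tested by LRT against the previous model.  Groupings with fewer than two
pairs are skipped with a warning.

**Optimization.**  L-BFGS-B with numerical gradients from moment-based
starting values, plus seeded random restarts (default 5) and a bounded
Nelder-Mead polish; binary fits use Nelder-Mead on the concordance
counts.  Non-positive-definite proposals receive a large finite penalty
so optimizers back away rather than abort.  A fit reports a convergence
flag; the nested-model LRT raises if a constrained fit beats its parent
beyond numerical tolerance, which signals an optimizer failure rather
than producing a silently negative test statistic.

## Synthetic cohort generator

Defaults mirror the emulated study: 91 MZ + 114 DZ twin pairs (study
pair-type mix), 426 age/sex-matched singletons, hand-preference liability
a² = .205, pegboard liability a² = .217, no shared environment, and a
cross-trait phenotypic correlation of ≈ .42 carried entirely by the
non-shared environmental factors (r_e = .53 = .42/√(e₁²e₂²)), the
best-supported structure for these measures.  The non-right prevalence is
8% with a male:female NRH odds ratio of 1.27 entering as a liability mean
shift (solved numerically so the overall prevalence is preserved).

Latent structure: per trait, A factors correlate 1 in MZ and 0.5 in DZ
pairs (common + unique construction), C is shared within a pair, E is
independent; cross-trait correlations r_A, r_C, r_E are applied within
each factor block.  Questionnaire items follow a graded-response model —
item liability = loading × trait liability + independent noise, cut at
symmetric thresholds (−t₂, −t₁, t₁, t₂) into the five ordered answers.
The default loadings (pen tasks ≈ .95, broom/box lid = .50) and
thresholds were calibrated once, analytically, to the emulated
instrument's published marginal behaviour: a J-shaped EHI with ≈ 8%
non-right-handers, item no-preference rates from ≈ 1–2% (writing) to
≈ 45% (box lid), and item-total correlations highest for pen items.
Pegboard trials are per-hand means base×(1 ± q/2) with
q = .095 + .097 × liability plus i.i.d. trial noise (sd 0.5 s on a 13 s
base), giving a population PegQ centred at ≈ .095 with sd ≈ .10; a
configuration implying non-positive times raises rather than truncating.

Randomness: one root `SeedSequence` is split per sub-generator (pairs,
singletons, sexes, ages, items, pegboard), and draws within a stream are
vectorized in subject order, so fixed seeds give byte-identical output
files and enlarging a cohort does not perturb earlier subjects.

What the generator does *not* emulate — and therefore what passing tests
cannot certify about real data: age trends in handedness strength,
skewness of real PegQ distributions (the generated index is symmetric
around its mean, so the binarised PegQ2 rate runs ≈ 17% versus ≈ 14% in
real children), cultural pressure producing writing-hand switches (the
≈ 2% switch-flag rate emerges from item noise, not a switching process),
chorionicity, or mirror twinning.  Recovery tests demonstrate that the
estimators are unbiased under the assumed model, not that the model is
true of any particular population.

## Problem sizes used in the automated studies

Parameter-recovery studies average 200 replicates of 1,000 + 1,000 pairs
(continuous) and 2,000 + 2,000 pairs (binary); the package's bias at
these sizes is well under 0.01 on standardized components.  The
model-selection study uses 60 replicates at study scale (91 + 114 pairs),
where minimum-AIC selection of the true independent-genetic-factors model
runs ≈ 65%, and a 5-replicate check at tenfold size, where it is
essentially certain.  These sizes were chosen so the whole study suite
runs comfortably on a laptop.

## Known limitations

* LRT p-values ignore the boundary problem (see above).
* Binary fits are threshold + tetrachoric-style ML on concordance cells;
  covariate effects on the threshold are not modelled.
* The bivariate ladder covers the six standard models only; sex-limitation
  and dominance models are out of scope.
* The df convention for binary traits (observations − our parameter
  count) need not match other software's bookkeeping, which sometimes
  counts constrained quantities differently; −2LL values are unaffected.
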