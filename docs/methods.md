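# Methods

## The implication model

For two dichotomous variables A and B observed on n subjects, the fourfold
table (a, b, c, d) counts (A=1,B=1), (A=1,B=0), (A=0,B=1), (A=0,B=0).
Statistical implication A⇒B is the claim that the counterexample cell b is
small relative to what the margins predict; it is probabilistic (rare, not
absent, counterexamples) and directional, and it is *not* causal: an
implication can be induced by a web of dependencies among outcomes.

### The full-information index

Cells are smoothed with a per-cell pseudo-count α (default 0.5,
Jeffreys-style): π_ij = (n_ij + α)/(n + 4α). The directed index is

    ι(A⇒B) = ½ [ ln( π11 π+0 / (π10 π+1) ) + ln( π00 π1+ / (π10 π0+) ) ]

- the first term is the log ratio of the odds of B given A to the marginal
  odds of B (direct evidence);
- the second is the log ratio of the odds of ¬A given ¬B to the marginal
  odds of ¬A (contrapositive evidence);
- both are penalized by the counterexample probability π10.

Properties (all exercised by the test suite):

- **Contrapositive equivariance, exact.** Relabeling the table for ¬B⇒¬A
  maps (a,b,c,d) → (d,b,c,a) and swaps the two terms, so ι is unchanged
  bit-for-bit — the index really does pool "A implies B" with "not-B
  implies not-A".
- **Independence zero.** If the smoothed table factors into its margins
  (e.g. all cells equal) the index is exactly 0; under simulated
  independence its mean converges to 0.
- **Monotone in counterexamples.** With a, c, d fixed, ι strictly decreases
  in b.
- **Finite everywhere.** Smoothing keeps ι finite even when a column is
  constant; such tables are flagged `degenerate_margin` because a constant
  outcome carries no implicative information.
- **Direction decomposition.** Summing the two directions gives
  ι(A⇒B) + ι(B⇒A) = ln OR̃, the smoothed log odds ratio, and the gap is
  ι(A⇒B) − ι(B⇒A) = ln(c̃/b̃) + ln(odds̃(A)/odds̃(B)) (tildes: smoothed).
  The symmetric part of the index is therefore the ordinary association,
  and the asymmetry is driven by the imbalance of the two counterexample
  cells corrected for unequal margins.

The index is documented as an "Iota-style full-information index": the
operational definition above is this package's pinned contract, chosen to
satisfy the published qualitative properties of such indices (range,
sign/zero interpretation, contrapositive use, asymmetry). A variant
reconciled against other published formulations could be added behind the
same function signature without touching the inference machinery.

### The counterexample-rarity comparator

`gras_intensity` is the classical SIA intensity that uses counterexample
rarity only: with λ = (a+b)(b+d)/n, the expected number of counterexamples
under independence, φ(A⇒B) = P(N ≥ b) for N ~ Poisson(λ). It is reported
alongside ι as an auxiliary column; it errors on an empty (a+b) or (b+d)
margin, where the implication is undefined (the tabular pipeline stores NaN
there).

## Inference

Significance is judged by a case-resampling bootstrap: subjects are drawn
with replacement (the subject, not the cell, is the sampling unit), ι is
recomputed on each replicate's smoothed table, and the percentile interval
at level 0.95 is compared against zero. Defaults: 2000 replicates, 95% CI,
α = 0.5 smoothing. Choices worth stating:

- **Percentile CIs** (not BCa): the simplest method consistent with
  "check whether the 95% CI contains zero". Measured type-I error under
  independence at n = 219 is close to nominal (the acceptance script
  recomputes it; runs here land near 0.05 with 500 × 1000 simulations).
- **Degenerate replicates are kept.** A replicate in which a resampled
  column is constant still yields a finite smoothed ι; rejecting such
  replicates would bias the CI for thin margins. Their fraction is reported
  per pair (`degenerate_fraction`).
- **No multiple-testing correction by default** — every directed pair is
  reported at the nominal level, matching common practice for exploratory
  implication graphs; a Bonferroni option adjusts the per-pair CI level.
- **Determinism and order-independence.** Every (source, target, stratum)
  triple derives its own substream from the root seed via CRC-32 label
  hashes fed to numpy's SeedSequence, so adding an outcome or re-ordering
  the analysis never perturbs existing pairs, and identical inputs give
  byte-identical output files.
- **Stratified re-analysis** subsets rows by a binary baseline covariate
  and repeats the all-pairs analysis per level; a level with fewer than two
  subjects is skipped with a warning rather than failing the run.

Complete-case inclusion is applied before analysis: a subject enters only
if every analyzed outcome is observed (missingness in the stratum alone
does not exclude a subject from the unstratified analysis). The number of
dropped subjects is always reported, since source cohorts rarely publish it.

## Synthetic cohorts

The generator specifies structure *conditionally*: a link source→target
with parameters (ε, q) means P(target=1 | source=1) = 1−ε and
P(target=1 | source=0) = q, so the planted direction and counterexample
rate are explicit inputs. Root outcomes are Bernoulli at their baseline
probability; multiple links into one target combine by noisy-OR (each link
is an independent causal channel), preserving "counterexamples are rare
when any source is present". Links must form a DAG. An optional binary
stratum can carry different link lists per level, emulating implications
that hold in one baseline subgroup only. A latent-severity (threshold)
generator would be a natural extension but is intentionally not the
default: conditional specification makes planted effects unambiguous.

`study_like_spec()` emulates a four-outcome early-intervention cohort at
n = 219: a hub outcome "working" (margin 0.45) implying "living" (ε=0.10,
q=0.45), "symptomatic" (ε=0.05, q=0.45) and "functional" (ε=0.05, q=0.25),
plus a symptomatic→functional link (ε=0.10, q=0.20) that makes both
directions of that pair strong (b and c cells both rare → reciprocal), and
a baseline-work stratum at prevalence 0.30. The reference study's true
outcome margins are not public; these are plausible placeholders for a
36-month early-psychosis cohort and are labelled as such.

What the generator does *not* emulate: demographic covariates, measurement
error in the dichotomizations, informative missingness, or longitudinal
ordering. Passing tests on these cohorts therefore validates the
*machinery* (index algebra, calibration, power, reproducibility), not any
clinical claim.

## A structural property of full-information indices at moderate n

Because ι(A⇒B) + ι(B⇒A) equals the smoothed log odds ratio, any positive
dependence makes *both* directed population indices strictly positive; the
reverse index of a genuinely planted one-way link is small but not zero,
and its sampling variability is low precisely because reverse
counterexamples are plentiful. Empirically (design experiments with exact
multinomial laws and real percentile bootstraps at n = 219), the bootstrap
significance events of the two directions are strongly coupled, and no 2×2
law simultaneously gives a reliably significant forward direction and a
reliably non-significant reverse. Two consequences users should expect:

1. With n in the low hundreds, strong planted one-way implications classify
   as *reciprocal with unequal strengths* — the direction information is in
   the ordering and gap of the two indices (recovered in ≥ 90% of planted
   runs, see the acceptance script), not in one-sided significance.
2. Forward-only significance patterns, when they occur in real data, sit in
   a marginal-power regime and should be interpreted with corresponding
   caution; reporting both directed estimates with their CIs is the honest
   summary.

## Problem sizes used in validation

Oracle grids use 200 deterministic tables (cells 0–46) plus 1000 random
tables (cells 0–119); calibration uses 500 Monte-Carlo repetitions × 1000
bootstrap replicates at n = 219; power/direction recovery uses 100
repetitions at n = 219 with 1000 replicates; graph recovery uses a single
seeded n = 219 cohort at the default 2000 replicates. These sizes were
chosen to keep Monte-Carlo standard errors comfortably inside the asserted
tolerances (e.g. s.e. ≈ 0.01 on a 0.05 rate at 500 repetitions).

## Known limitations

- Binary variables only; polytomous or continuous implication indices are
  out of scope, as are Bayesian posterior versions of the index.
- No imputation: complete cases only, so informatively missing outcomes
  bias the analyzed sample.
- No analytic standard errors; inference is bootstrap-only.
- Magnitude guidelines for ι do not yet exist in the literature; the
  package reports raw values, CIs and significance and deliberately avoids
  small/medium/large labels.
- Cross-sectional: implication is not temporal precedence and never
  causality.
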