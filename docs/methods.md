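# Methods

`ymazeqtl` implements the statistical pipeline for a group-tested olfactory
appetitive-conditioning study of recombinant inbred lines (RILs) from an
8-founder multiparent panel (DSPR population A style): scoring of y-maze
chamber counts, selection of extreme lines conditional on founder ancestry,
and a haplotype-probability genome scan with binomial generalized linear
mixed models.

## The behavioral data model

A vial of flies (typically 60–80) is conditioned to associate one odorant
(OCT = 3-octanol or MCH = 4-methylcyclohexanol) with a sucrose reward and
then released into the start chamber of a y-maze whose two arms carry the
CS+ and CS− odors. Each fly yields up to two Bernoulli decisions:

* **climbing** — it left the start chamber for either arm (score 1) or
  stayed (0); climbing reflects activity and motivation, not learning;
* **correctness** — given that it climbed, it chose the CS+ arm (1) or the
  CS− arm (0).

Group-level proportions derived from the terminal chamber counts are:
climbing score `(n+ + n−) / (n+ + n− + nNC)`, and the choice proportion
`n+ / (n+ + n−)`, which serves as the performance score (learning and
memory assays), the baseline preference score (untrained flies, focal odor
in the numerator) and the odor-acuity selection score (odor vs odor-free
arm). No-choice flies never enter a choice denominator; with zero climbers
the choice score is undefined rather than 0 or 0.5. Per-RIL scores pool
counts across replicate vials (fly-weighted) by default, because a mean of
per-vial proportions lets small vials inflate a line's score; per-replicate
averaging is available as an option.

The preference–performance differential is `PPD = performance − preference`
for the same trained odor. The phrasing of the original definition is
directionally ambiguous; this package fixes the sign as performance minus
preference, documents it, and interprets only |PPD| (distance from
baseline-driven choice). A line "overrides" its preference when
performance > 0.5 and preference < 0.5, both strict; the neutral preference
band 0.45–0.55 is inclusive at both ends. The heat-box place assay's
performance index is `(t_cool − t_hot) / t_total` in [−1, 1].

Memory assays re-test only the flies that chose CS+ during learning, so
memory sample sizes are assay-specific inputs, never derived from learning
counts.

## Line selection at prior QTL peaks

The 5-step selection reproduces how study lines were picked from a larger
previously phenotyped panel: founder calls at each prior peak (argmax
probability, ambiguous below a 0.5 call threshold), empirical-CDF
percentiles of both phenotypes averaged into a cumulative score, candidate
high/low groups by whether every call falls in the peak's high- or
low-performing founder set, exclusion of mixed lines, and top/bottom-k by
cumulative score (ties broken by line identifier, deterministically). The
high/low founder sets per peak are inputs: they derive from the prior
study's effect estimates, which this package does not recompute.

## The genome scan

Per-vial binomial outcomes `y_v ~ Binomial(n_v, p_v)` are modeled on the
logit scale with a RIL random intercept (SD `sd_ril`) and a vial (replicate
nested in RIL) random intercept (SD `sd_rep`). At each genomic position the
base model (intercept only) is compared against an alternative adding the
position's founder-ancestry probabilities `g_ij` as fixed covariates, by
likelihood-ratio test; `−log10 p` comes from an upper-tail chi-square
probability, and each odor × assay combination (OCT/MCH × learning/memory)
plus climbing is scanned separately.

**Founder drop rule.** A founder enters a position's design only if at
least `min_ril_count = 4` RILs harbor it, "harbor" meaning `g_ij > 0.5`
(both config-exposed); coefficients estimated from fewer lines overfit.
The retained count is `n_hap ≤ 8`.

**Identifiability and degrees of freedom.** When the retained founder
probabilities sum to ~1 for every RIL (tolerance 0.01) they are collinear
with the intercept, so estimation drops the most frequent retained founder
as reference (n_hap − 1 estimated coefficients); otherwise all n_hap
columns are estimable. The chi-square reference for the p-value uses
**df = n_hap** in either case. This resolves a genuinely open convention:
(i) it matches parameter counting for the unconstrained sum-of-probabilities
model formula as TMB-based mixed-model software reports it, and (ii) in
null-calibration simulations at the study's panel size (50 RILs; see the
acceptance checks) chi-square with df = n_hap − 1 is clearly
anti-conservative while df = n_hap is close to calibrated. Output tables
report `n_hap`, `df` and the estimated-coefficient count per position so
either convention can be recomputed.

**Estimation.** Both models are fit by Laplace-approximate maximum
likelihood, written for this package because no installed Python library
provides ML binomial GLMMs: for candidate fixed effects and variance
components the joint mode of the random effects is found by damped Newton
— per-RIL blocks are independent and their Hessians are arrow matrices
(diagonal in the vial effects plus one coupled RIL effect), so each Newton
step and log-determinant is O(#vials) and fully vectorized across blocks —
and the outer optimization over (β, log sd_ril, log sd_rep) uses L-BFGS-B
(inner gradient tolerance 1e-10, outer ftol 1e-13, log-SD bounds [−8, 4],
derivative-free polish on the rare line-search stall). Fits agree with
lme4's Laplace `glmer` to ~1e-4 in log-likelihood and ~1e-6 in the LRT on
shared fixtures (asserted in the test suite). The base model does not
depend on position and is fit once per phenotype. Non-converged positions
are emitted with missing statistics and enter multiplicity correction as
p = 1, never silently dropped. Because covariates are constant within a
vial, per-fly Bernoulli records and per-vial binomial aggregates give
identical likelihood differences (they differ by a fixed binomial
coefficient, included in reported log-likelihoods for comparability).

**Known limitation — finite-panel calibration.** The LRT tests ~7–8
RIL-level covariates whose effective sample size is the number of lines,
not flies. At 50 lines the chi-square reference is intrinsically somewhat
anti-conservative: in the package's own null calibration (acceptance
checks) the type-I rate at α = 0.05 exceeds the nominal level by a few
percentage points even with df = n_hap, and the same behavior is
reproduced by lme4 on identical data, i.e. it is a property of the
procedure, not of this implementation. Genome-wide conclusions should rest
on the q-values rather than nominal per-position thresholds; calibration
improves with panel size.

**Multiplicity.** Storey positive-FDR q-values are computed internally:
π0(λ) = #{p > λ}/(m(1 − λ)) over λ = 0.05…0.95, smoothed by a cubic
polynomial evaluated at the largest λ (a deterministic stand-in for the
customary smoothing spline); for m < 100 the tail estimate is too noisy
and a single fixed λ = 0.5 is used. q-values are the monotone step-up
transform, capped at 1. Positions are significant only at q ≤ 0.05; on
null-like data the pipeline reports "no significant QTLs" rather than
forcing peaks.

**Odor-differential suggestive peaks.** `d = |Δ(−log10 p)|` between the
two odors' scans of the same assay; candidates need d strictly greater
than 2; peaks are chosen greedily by descending d, suppressing candidates
within `min_separation = 10` scan positions (config-exposed — "unique
positions" has no stated distance rule) of an already chosen peak on the
same chromosome, up to k = 3 per assay. At each peak, per-founder mean
phenotype proportions (lines assigned by argmax founder, ambiguous lines
dropped) with standard errors `sd/√n_rils` are reported per trained odor.

## The synthetic study generator

The generator emulates the study's data shapes with known ground truth, so
every stage is testable without the deposited raw data.

* **Haplotypes.** Each RIL's genome is a first-order Markov founder mosaic:
  uniform start, and per interval the ancestry is redrawn uniformly from
  all 8 founders with probability `recomb_prob` (an actual switch therefore
  has probability 7/8 of that). The chain is symmetric with uniform
  stationary distribution, so founder frequencies are 1/8 at every
  position. Hard calls are softened by mixing each one-hot row with a flat
  Dirichlet draw at weight 1/(c + 1), c = `soft_prob_noise` = 50 by default
  (≈0.98 probability on the true founder, emulating near-certain
  HMM-inferred ancestry). The HMM itself is consumed upstream of the study
  and is not re-implemented.
* **Outcomes.** Per-fly Bernoulli draws for climbing and (for climbers)
  correctness, with per-RIL and per-vial normal intercepts on the logit
  scale (drawn once each), planted founder effects `Σ_j g_ij·effect_j`
  restricted to a training odor and/or phenotype, and a memory retest of
  the learning CS+ choosers. Defaults mirror the study design: 50 RILs,
  vials of 60–80 flies, three vials per RIL per odor (~400 flies per line
  across odors, matching the reported per-line totals), chance-level
  baselines (logit 0, since mean reported performance and climbing are
  ≈0.5), sd_ril = 0.3 and sd_rep = 0.2 (moderate line/vial heterogeneity;
  the real variances are unreported, so these are config-exposed choices,
  not assertions), recomb_prob = 0.02 on the default 500-position grid (a
  handful of ancestry switches per chromosome, as in real RIL mosaics).
* **Acuity/preference.** Per-RIL latent proportions drawn once from Beta
  distributions (preference and odor acuity centred on 0.5; sucrose acuity
  centred ≈0.6 as starved flies favor sucrose), binomial counts around
  them, plus a censored count for sucrose plates (lid/boundary flies),
  always present in the schema.

All randomness flows from one integer seed through three fixed,
order-documented streams (haplotypes, outcomes, acuity), so identical
configs reproduce byte-identical tables.

What the generator does *not* emulate: sex/age structure, environmental
covariates, linkage-map estimation, sequence-level variation, real LD
patterns, or odor-concentration effects — so green tests demonstrate that
the machinery is correct under the stated model, not that the model
captures every feature of real panels.

## Calibration-study design choices

The null-calibration check simulates its 500 positions as 10 independent
replicate studies of 50 positions with `recomb_prob = 1` (independent
positions): a uniformity test presupposes approximately independent
p-values, and within one study all positions share the single phenotype
realization. The planted-effect recovery check uses a 100-position
chromosome with `recomb_prob = 0.1`, so ancestry correlation decays within
the ±5-position localization window; 50 RILs × 300 flies, +2 logits on one
founder. These sizes keep each check to minutes on one CPU; they are the
package's desk-scale study conditions, stated here once and reused by the
test suite and the acceptance script.

## Numerical and degenerate-input conventions

Zero uncensored flies, zero climbers, or zero total time raise explicit
undefined-score errors. Ties in cumulative scores break by RIL id;
differential-peak ties break by (d, chromosome, position). The LRT is
floored at 0 (the warm-started alternative never falls below its nested
base beyond optimizer tolerance 1e-6). Chi-square survival probabilities
are floored at 1e-300 before taking log10. Scan output is invariant to
phenotype row order and to the per-fly vs aggregated representation.
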