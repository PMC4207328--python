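# Methods

`epistat` implements the statistical workflow of a gene-gene interaction
replication study in a case-control setting: a candidate pair of loci is
tested for interaction on the multiplicative and the additive odds-ratio
scales, cross-checked with case-only statistics and an exhaustive
genetic-model search, and the outcome is placed in context with a power
calculation and a confidence-interval-based replication verdict.  This
note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

Three marker kinds cover the genotypes such studies use:

* **SNPs**, stored as minor-allele dosage 0/1/2;
* **presence/absence markers** (gene deletions such as a GSTM1-type
  null allele), where heterozygotes are unobservable by assay design:
  the only states are "carrier" (at least one native allele) and
  "null" (homozygous deletion);
* **binary carrier markers** (pre-called carriage of an allele group,
  e.g. the HLA-DRB1 shared epitope).

Genetic codings map genotypes to regression covariates: dominant
(any risk state → 1), additive (dosage; SNPs only, since dosage is
undefined without heterozygotes), recessive (homozygous risk → 1), and
a 2-df codominant coding (separate heterozygote and homozygote
indicators) inside the model-selection grid.  Missing data are handled
complete-case per analysis: each statistic drops exactly the records
missing one of its own variables, so denominators differ between
analyses, as they do in practice when antibody status is available
only for a typed subset of patients.

Every downstream operation also accepts aggregated contingency tables
directly (genotype count tables, 3x3 joint tables, 2x4
exposure-by-outcome tables), so published tables are first-class
inputs; the bundled fixtures expose one such published set.

## Marker QC and single-marker association

A marker passes QC when its call rate exceeds 0.90 and its control
genotype counts are compatible with Hardy-Weinberg proportions at
P > 0.05.  HWE is tested in controls only — cases can legitimately
deviate under association — by the 1-df chi-square of observed versus
expected counts at the allele frequency estimated from the same table.
The chi-square is used rather than an exact test; at these sample
sizes the approximation is adequate, though for a rare allele with a
single-digit expected homozygote count the chi-square can be slightly
anticonservative (one bundled control row sits at p = 0.046 where an
exact test would be milder).

Association is the allelic 2x2 chi-square (no Yates correction) with
the cross-product odds ratio and a Wald CI on the log scale
(SE = sqrt of the sum of reciprocal cells).  Zero cells receive the
Haldane-Anscombe 0.5 correction for the estimate and CI — never for
the chi-square — and the output is flagged.  For binary marker kinds
the analogous carrier odds ratio is provided, with an orientation
switch because published tables sometimes orient a deletion
polymorphism on native-allele carriage.

## Multiplicative interaction (ROR)

The interaction between loci 1 and 2 is the coefficient `b3` of

    logit P(case) = b0 + b1*x1 + b2*x2 + b3*x1*x2,

and `exp(b3)` is the ratio of odds ratios (ROR); under binary codings
it equals `OR11 / (OR10 * OR01)` exactly, which the tests exploit as a
brute-force oracle.  Inference is Wald throughout (point estimate, CI
and p from the coefficient and its standard error), matching how
interaction terms are reported by mainstream packages; likelihood-ratio
intervals are not offered.

The fitter is Newton scoring on grouped (frequency-weighted) data with
step-halving, so the log-likelihood path is non-decreasing and
saturated contingency-table fits are exact.  Convergence is declared
at a score sup-norm below 1e-8 within 50 iterations.  Separation is
detected as a standardized coefficient exceeding 15 (or a singular
information matrix) and raised as an error naming the empty exposure
cell where one exists; no Firth-type correction is applied.
Stratified odds ratios (target-locus OR within carriers and
non-carriers of the other locus) accompany the ROR, whose point
estimate they reproduce as a ratio.

## Additive interaction (RERI, AP, S)

For two binary exposures, the indicator-parameterized model
`logit ~ I(1,0) + I(0,1) + I(1,1)` gives `OR10`, `OR01`, `OR11`, and

    RERI = OR11 - OR10 - OR01 + 1,
    AP   = RERI / OR11,
    S    = (OR11 - 1) / (OR10 - 1 + OR01 - 1).

Confidence intervals follow the Hosmer-Lemeshow delta method on the
coefficient covariance: symmetric intervals for RERI and AP, a
log-scale interval for S.  S is reported as missing when its
denominator is non-positive (no single-exposure excess to apportion)
or the index itself is non-positive.  The delta-method variance is
first-order: against a nonparametric bootstrap it agrees to within a
few percent once all eight cells reach ~150, but understates the
skewed bootstrap variance by ~20% at cell counts near 50 — the CIs at
small counts should be read as approximate.  The analysis is
outcome-agnostic; in the bundled example the outcome is
antibody-positive versus antibody-negative patients, with the deletion
null genotype and shared-epitope carriage as exposures and the
doubly-unexposed category as reference.  No covariates are included
and no automatic re-orientation of exposures is performed (a published
effect's direction is part of what is being replicated); the CLI
exposes the crude table alongside.

## Case-only statistics

Under population-level linkage equilibrium between the loci, a
multiplicative interaction induces inter-locus association within
cases.  `t_pearson` is the Pearson chi-square of independence on the
case genotype cross-table, with zero-margin levels dropped and the
degrees of freedom reduced accordingly.  `t_awu_co` targets gametic
phase disequilibrium: each case with dosages (g1, g2) contributes
fractionally to a 2x2 allele-combination table (g1*g2/2 to the
minor-minor cell, and analogously, two units per person), and the
statistic is the squared log cross-ratio over its variance, referred
to chi-square(1).  Because the two gametes of one person are not
independent observations, the naive four-cell variance is wrong; the
adjusted variance used here is the multinomial delta method over the
nine genotype-cell proportions, which requires neither phase
information nor HWE.  A seeded permutation null — shuffling one
locus's genotypes among cases — is the assumption-free calibration; it
is engaged automatically when any allele-combination cell falls below
one, and it serves as the independent reference implementation in the
tests, so correctness does not rest on the analytic variance alone.
Null calibration is verified at both loci MAF 0.3 (inside the
0.23-0.40 range of the bundled partner SNPs), where all nine expected
genotype cells stay comfortably above 5 at 1,000 cases.

## Genetic-model selection

The model grid crosses each locus's coding {absent, dominant,
recessive, additive, codominant 2-df} and adds, for every two-locus
combination, an interaction variant whose terms are all pairwise
products of the two loci's coding columns (up to 4 parameters): 41
models including the intercept-only null.  Models are ranked by
AIC = -2 loglik + 2k (k counts all coefficients, intercept included),
with ties broken by fewer parameters then enumeration order, and a
ΔAIC < 2 read as "not meaningfully different".  Non-converging or
separated fits are excluded with a warning.  One behaviour of this
grid is worth stating plainly: on truly null data the intercept-only
model stays within 2 AIC units of the best model in only ~70-75% of
replicates, because with ~8 df of penalized alternatives some 1-df
direction exceeds the ΔAIC = 2 slack about a quarter of the time.
AIC over a large grid is a ranking tool, not a calibrated test; the
simulation studies in the test suite document this rate.

## Interaction power and replication verdicts

Power for the ROR Wald test of a dominant-by-dominant design: control
exposure-cell probabilities come from independent carrier frequencies,
case cells are re-weighted by the model odds {1, or1, or2,
or1*or2*ror}, the SE of the log ratio is the square root of the sum of
reciprocal expected cell counts, and

    power = Phi(lambda/SE - z) + Phi(-lambda/SE - z),  lambda = ln ror.

At ror = 1 this returns exactly alpha.  The SE is evaluated under the
alternative, which is what matches empirical rejection rates in both
directions; a consequence is that reciprocal effects (r and 1/r) have
similar but not identical power.  A warning is raised when an expected
cell drops below one.

Post-hoc type II errors for the six bundled replication designs need
the discovery study's effect sizes, which are not machine-readable
from its published figure.  They are reconstructed per SNP as the
protective interaction ratio at which the discovery case-control
stages (1,624 cases / 2,506 controls, at the anchor-locus and
partner-SNP carrier frequencies observed here) would attain a Wald
p of 3e-4 — the geometric mean of that study's reported joint-p range
(1.5e-5 to 6.1e-3) — solved by a short fixed-point iteration.  The
resulting β of 0.05-0.08 per SNP is a reconstruction, not a
reproduction, and brackets the originally reported 0.071-0.136.

When no power formula exists for an estimand (the attributable
proportion), replication is judged by mutual CI containment of the two
point estimates: both inside each other's CI → equivalent; neither →
the studies exclude each other's effect; one-sided containment →
uncertain.  Formal TOST-style equivalence testing is out of scope.

## Synthetic cohorts

The generator draws control genotypes from HWE at stated frequencies
(optionally with pairwise LD through a positive-D haplotype
construction, rejected when infeasible for the allele frequencies) and
case genotypes retrospectively, with probability proportional to the
control genotype probability times exp(linear predictor).  This
preserves every odds ratio of the generating model exactly in
expectation, delivers the requested case/control counts exactly, and
makes the baseline disease odds cancel out of the genotype
distribution — so prevalence is deliberately not a generator
parameter.  Patients receive antibody status from a 2x4 exposure-cell
odds model (baseline positivity 67.3% by default, the typical anti-CCP
rate in such cohorts); controls are never antibody-typed.  Default
cohort dimensions are 1,744 cases / 1,650 controls, the scale of the
study the fixtures come from; replicate-heavy simulation studies use
counts-level multinomial equivalents of the same model
(`simulate_two_locus_tables`, `simulate_two_by_four`) to keep hundreds
of replicates cheap.

What the generator does **not** emulate: population structure, family
structure, genotyping error, missingness mechanisms, and
covariate-confounded antibody status.  Passing recovery and
calibration tests on these cohorts therefore demonstrates correctness
of the statistics under their stated assumptions, not robustness of
the statistics on real data.

## Problem sizes in the test and acceptance runs

Simulation studies run at the sizes the analyses are meant for:
type-I-error calibration with 5,000 null replicates of 1,000 cases;
ROR recovery with 100 replicates of 25,000 + 25,000 (large enough that
CI coverage, not bias, is what is measured); power validation with
2,000 replicates at 1,700/1,650; model-selection behaviour with 100
replicates of 2,000 + 2,000; additive-null AP coverage with 500
replicates of 736 patients.  All are seeded and deterministic.

## Known limitations

* Wald inference everywhere; no profile-likelihood or Firth options.
* The chi-square HWE test is slightly anticonservative for rare
  alleles (no exact test).
* Delta-method CIs for RERI/AP/S are first-order (see above).
* Case-only statistics are only interaction tests under linkage
  equilibrium; the CLI prints this assumption whenever they run.
* The published interaction-ratio table of the bundled study cannot be
  recomputed from the fixtures, because the individual-level joint
  genotypes behind it were never printed; it is supported as a report
  format, with simulation-based validation standing in for value
  reproduction.
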