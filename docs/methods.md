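# Methods

## The problem

Regional gray-matter volumes (VOIs, here the 116 regions of the AAL
atlas) scale with overall head size, summarised by the total
intracranial volume (TIV = gray matter + white matter + CSF).  Adult
female and male samples differ in TIV by a standardised difference of
roughly d = 1.6, so any raw comparison of regional volumes between the
sexes conflates a genuine group effect with a head-size effect.  The
package implements the statistical machinery for separating the two:
adjustment methods that remove TIV scaling, benchmark subsamples that
estimate each effect in isolation, and a validation suite that measures
whether an adjustment actually worked.

## Adjustment methods

Let `VOI` be one region's volume and `TIV` the subject's intracranial
volume (both ml).  All fits pool both groups: in a sex comparison there
is no control group whose parameters could be privileged.

| method | formula | parameters | output |
|---|---|---|---|
| proportion | `VOI / TIV` | none | dimensionless ratio |
| power-corrected proportion (PCP) | `VOI / TIV^b` | `b` = OLS slope of log VOI on log TIV | ratio |
| residuals | `VOI − b·(TIV − mean TIV)` | `b` = OLS slope of VOI on TIV | ml, mean-preserving |
| covariate regression | `VOI = b0 + b_tiv·TIV + b_sex·sex + ε` | full two-predictor OLS | no adjusted volumes; the sex coefficient is the test |

The proportion method implicitly assumes the allometric exponent is 1.
Where the true exponent is below 1 (most regions) it over-corrects:
the adjusted values acquire a *negative* relationship with TIV, so a
group with smaller heads comes out with larger "adjusted" volumes — an
inverted, not removed, confound.  PCP estimates the exponent per region;
the residuals method removes the fitted linear trend.  Both leave
adjusted values uncorrelated with TIV (exactly so, in-sample, for the
residuals method — OLS orthogonality).

Sex is coded 0 = F (reference), 1 = M (comparison) throughout, so every
positive effect sign means M > F.  The covariate method's effect size is
`d_sex = b_sex / SD(VOI)` with the whole-sample SD by default
(`d_sd="pooled"` switches to the pooled within-group SD).

Group tests are pooled-variance Student t tests, two-sided, one per
region, with Cohen's d (pooled SD) and a 95% CI.  The default CI uses
the large-sample standard error `sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`
with ±1.96; this reproduces published worked examples at printed
precision.  A noncentral-t inversion is available
(`ci_method="noncentral"`); the two differ in the third decimal at
n ≈ 350.

## Criterial subsamples

* **TIV matching**: cross-group pairs with TIV gap ≤ 10 ml (caliper).
  The default algorithm greedily accepts the smallest-gap admissible
  pair; it is deterministic (ties break on subject id) and invariant to
  row order.  Greedy can lose a pair to the exact assignment optimum in
  rare near-tie blocking configurations (an example lives in the test
  suite), so `method="optimal"` solves the assignment problem exactly
  (maximum pairs, then minimum total gap) via the Hungarian algorithm.
* **Calibrated splits**: within one group, subjects are median-split by
  TIV into frozen small/large pools; equal-size subgroups are drawn and
  refined by stochastic local search — within-pool replacements and
  between-group permutations, accepting only moves that bring the pooled
  Cohen's d of the TIV gap closer to the target (1.6 by default,
  tolerance 0.06, at most 10 000 proposals).  Non-convergence returns a
  flagged result with the best achieved d rather than raising.  The
  accepted-move trace is monotone by construction.

## Validation suite

* **TIV regressions**: per-region OLS of (adjusted) volume on TIV.  A
  valid adjustment drives every slope to ~0 and destroys the rank
  correlation between slope and the group test's p/d values.
* **Concordance**: trinary per-region codes (+1 significant M>F, 0
  none, −1 significant F>M) feed Randolph's free-marginal multi-rater
  kappa (computed on the binarised significant/not codes, as a nominal
  agreement; CI by a 2 000-resample bootstrap over regions,
  seed-controlled), Kendall's W over p-value rankings (midrank tie
  correction; p values are the ranked quantity because they are
  comparable across methods), and the pairwise Spearman matrix.
* **Criterion agreement**: unweighted Cohen's kappa of a method's
  trinary codes against the TIV-matched benchmark, with the Landis-Koch
  verbal bands and a five-way taxonomy (hits on significant same-sign,
  hits on joint absence, false positives, false negatives, reversions)
  that partitions the 116 regions.
* **Replication score**: signed sum of the trinary codes across the
  TIV-free datasets (matched subsample, covariate, PCP, residuals).
  |score| ≥ n_datasets − 1 ("all or all but one") flags a replicable
  difference; score = 0 is the strict criterion for consistent absence.
  The per-region mean d (over all datasets, significant or not) converts
  to the percent of overlap `200·Φ(−|d|/2)` and the percent of
  superiority `100·Φ(d/√2)` of two unit-variance normal populations.
* **Multiplicity**: two-stage adaptive FDR
  (Benjamini-Krieger-Yekutieli, stage one at α/(1+α)), Benjamini-
  Hochberg, Holm and Bonferroni-Dunn, via statsmodels.  For any p
  vector the rejection sets nest Bonferroni ⊆ Holm ⊆ BH; the adaptive
  procedure usually, but not provably always, rejects at least as many
  as BH (its single-comparison threshold is α/(1+α), not α).

## Synthetic cohort generator

The generator draws

    TIV_i ~ Normal(mu_g, sd_g) truncated at 0
    VOI_ij = c_j · TIV_i^{b_j} · exp(delta_j·[i is comparison] + eps_ij),
    eps_ij ~ Normal(0, sigma_j), independent across regions given TIV.

Noise is multiplicative log-normal: volumes stay positive and the PCP
model is exactly correct, giving clean recovery oracles, while the
linear methods are exercised under mild, realistic misspecification.

Default calibration (the study design all property tests use):

| parameter | default | why |
|---|---|---|
| n per group | 171 F / 185 M | the study's sample sizes |
| TIV means | 1484.5 / 1606.8 ml | the printed matched-sample means (1545.111 / 1546.191) shifted apart to a population d of 1.6 |
| TIV SDs | 77.372 / 75.397 ml | printed matched-sample SDs |
| exponents b | U[0.430, 1.155] per region | the range estimated from real regional volumes (mean 0.863) |
| scale constants c | region means geometric 0.04 → 11.5 ml, shuffled | spans the observed range of regional mean volumes |
| noise sigma | 0.05 log-units | makes TIV explain ~23–68% of a region's variance in this design, bracketing the 9.6–59.8% seen in real data |
| effects (with_effects mode) | 19 regions, 10 F>M / 9 M>F, \|d\| ~ U[0.22, 0.38], applied as delta = d·sigma | the count, direction split and size band of replicable differences reported for real cohorts |

What the generator does *not* emulate: between-region correlation of
the noise (regions are independent given TIV; real neighbouring regions
co-vary), co-variation of exponent and region size (b and c are drawn
independently), non-Normal TIV distributions, and any age/education
structure.  Passing tests therefore demonstrate the statistical
machinery under the assumed power-law model, not robustness to every
feature of real morphometry.  One visible consequence: in real data the
TIV-volume slope correlates with the size of the raw group difference
(|rho| ≈ 0.4) because steep-slope regions are also strongly scaling
regions; with c independent of b the ml-scale slope is dominated by
region size and that correlation vanishes.  The mechanism test
accordingly pins c to a common value, which yields |rho| ≈ 0.9.

## Known statistical properties and limitations

* **Conservative residuals/PCP inference under strong confounding.**
  When the adjustment slope is fitted on the pooled sample and the
  groups differ in TIV, the slope estimate absorbs part of the
  between-group noise: the adjusted between-group difference has
  variance `sigma²[(1/n1+1/n2) − (x̄1−x̄2)²/Sxx]` (x = the regressor),
  a deflation factor of ~0.61 at the default design.  The nominal-5%
  pooled t test on residual- or PCP-adjusted values then rejects true
  nulls at ~1.3%, uniformly across regions.  This is a property of the
  residual-adjustment strategy itself (a standard criticism of it), not
  of this implementation; the covariate regression, which models group
  and TIV jointly, is exactly calibrated (measured 5.1% over 200
  simulated cohorts).  Consequence: use the covariate regression when
  calibrated per-region inference matters; use residuals/PCP for
  TIV-free *adjusted volumes* and effect-size estimation.
* **Effect shrinkage under with_effects.**  Because group membership
  correlates with TIV, whole-sample PCP/residual fits absorb part of a
  genuine group offset, shrinking recovered effects somewhat; the
  replication score consequently flags a subset of the seeded regions,
  essentially never an unseeded one.
* **Degenerate inputs** are explicit errors (constant TIV → degenerate
  design; zero volumes → PCP exclusion advice; missing volumes are
  never imputed) except where a degenerate *result* is meaningful: an
  empty matching is a valid result, calibration non-convergence is a
  flagged result, and a degenerate contingency margin is reported as
  untestable.
* **Numerical choices.**  Natural logs for PCP (the slope is
  base-invariant); chi-squared without continuity correction (matches
  the published worked value on the 41/11/30/34 table); Kendall's W
  returns 1 when all rankings are fully tied; bootstrap and search
  randomness always flows from an explicit seed, and a fixed seed fixes
  every output bit for bit.

## Problem sizes

Property suites run at the study scale (n = 356, 116 regions).  The
type-I-error suite uses 200 simulated cohorts; exponent-recovery and
calibration checks use 25–30; small-sample oracles use 5–20 subjects.
The whole test suite completes in well under a minute on one CPU.
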