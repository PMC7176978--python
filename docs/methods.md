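# Methods

## The decision procedure

A specimen is measured in `n` PCR replicates (default 3). Each replicate
yields a crossing point (Cp, in cycles) for the methylated *SEPT9* marker
and for the *ACTB* internal control; either may be non-detected, an
explicit state in the data model.

Thresholds follow the assay definitions with strict inequalities on the
stated side:

| quantity | rule | default |
| --- | --- | --- |
| replicate invalid | ACTB non-detected, or ACTB Cp **>** threshold | 36.0 plasma / 38.0 stool |
| marker detected | SEPT9 Cp **<** detection threshold | 45.0 |
| sample positive | detected replicates ≥ k, and censored mean Cp **<** cutoff when one is set | k = 1 (plasma), k = 3 + cutoff 40.0 (stool) |
| censor value | Cp substituted for non-detects in the mean | 50.0 (total cycles) |

Boundary behaviour is therefore: ACTB exactly at the threshold is valid,
SEPT9 exactly at 45.0 is not detected, a mean of exactly 40.0 is negative.

**Sample validity.** The assay defines validity per specimen but measures
per replicate. The default policy treats a sample as invalid if *any*
replicate is invalid — the conservative choice used by commercial kits —
with `all_replicates_invalid` and `majority_invalid` available. Invalid
samples are excluded from every denominator (PDR, sensitivity, specificity,
ROC, pairing); exclusion counts are logged by the CLI.

**Censored mean Cp.** The mean is taken over all `n` replicates with every
non-detected replicate contributing the censor value 50.0. A replicate
whose Cp is at/above the detection threshold also enters at the censor
value, so a single definition serves the calling cutoff and the ROC score;
under the 3/3 rule (where the cutoff is actually used) the two readings
coincide anyway, because all replicates are detected.

## Accuracy statistics

- **PDR / sensitivity / specificity.** PDR = positives / valid samples.
  Sensitivity is the PDR of a diseased group; specificity is 1 − PDR of
  normals, with the interval transformed accordingly. Confidence intervals
  are Wilson score intervals (95% by default): they behave sensibly at 0/N
  and N/N, both of which occur in real paired subgroups. Stage-stratified
  counts pool by summing numerators and denominators.
- **Paired concordance.** Plasma/stool calls from the same subject are
  cross-tabulated into the four agreement categories; the concordance rate
  is the agreeing fraction. Subjects with only one specimen or an invalid
  call are excluded with a logged warning. No chance-corrected agreement
  (kappa) is computed — the raw rate is the reported quantity.
- **Proportion comparisons.** Two-sided Fisher's exact test by default
  (strata are small); chi-square with continuity correction as an
  alternative. No multiple-testing correction is applied. The choice of
  test for subgroup tables is deliberately configurable because published
  comparisons of this kind rarely name the method.
- **Group Cp comparison.** Welch's unequal-variance t-test on censored mean
  Cps. When both groups are constant and equal the statistic is defined as
  t = 0, p = 1.
- **ROC / AUC.** Scores are per-sample censored mean Cps; lower score =
  more disease, so a sample is test-positive at threshold c iff score ≤ c.
  The AUC is the Mann–Whitney estimator (ties count 1/2), identical to a
  brute-force pairwise comparison (property-tested). The 95% CI uses
  DeLong's structural-components variance, truncated to [0, 1]; a fully
  tied score set yields AUC 0.5 with the uninformative interval [0, 1] and
  a warning. The heavy tie mass at 50.0 from non-detected normals is
  handled by the tie convention, not dropped.

## Rule search

`evaluate_grid` recomputes calls for every (k, cutoff) combination and
reports sensitivity, specificity and Youden's J = sens + spec − 1.
"Best balance" is formalized as maximal J (ties broken by higher
specificity, then smaller k); a constrained criterion — maximal sensitivity
subject to a specificity floor — matches the workflow of raising
specificity without sacrificing sensitivity, and returns an explicit
no-solution (`None`) when the floor is unattainable. The default cutoff
grid is {none, 36, 37, …, 45} cycles. Selection is in-sample, as in the
study design this mirrors; the selected rule's accuracy is optimistic for
unseen cohorts, and no cross-validation is attempted.

## Synthetic cohorts

Published comparisons of these assays report only group-level counts, so
the pipeline is validated on simulated cohorts with known ground truth.

**Model.** Each sample is a *shedder* with probability `p_shedder`;
replicates are conditionally independent given that state. This two-level
mixture is essential: with i.i.d. replicates, the large observed gaps
between 1/3 and 3/3 positivity could not arise. A shedder replicate draws
a latent Cp ~ Normal(`mu_cp`, `sigma_cp`) and is non-detected if an
amplification dropout occurs (probability `p_dropout`) or the draw falls
outside (0, 45) — so the detection probability per replicate is
q = (1 − p_dropout)·(Φ((45 − μ)/σ) − Φ(−μ/σ)) and a detected Cp follows the
correspondingly truncated normal; draws at or below zero count as failures
because a Cp is a positive cycle number. Non-shedder replicates show
false signal at rate `p_background` with their own weak Cp distribution.
ACTB Cp is Normal(`mu_actb`, `sigma_actb`) clipped to (0, 50]; invalid
replicates are injected as ACTB non-detects at rate `p_invalid` (the
generator does not know the caller's threshold, and a missing internal
control is invalid under any threshold). Paired subjects share a subject
id across specimens; with probability `cross_specimen_correlation` the
stool shedder state copies the plasma state, otherwise it is drawn
independently. One integer seed drives all randomness.

**Expected positivity oracle.** P(positive | valid) has closed form up to
one integral: the detection count is Binomial(n, q) per mixture branch, and
the mean-Cp-cutoff term — P(sum of the d detected Cps < n·cutoff −
(n−d)·50) — integrates d-fold convolutions of the truncated-normal density
on a 0.01-cycle grid (error ≪ the Monte-Carlo noise it is compared to).
Validity is independent of marker detection, so conditioning on validity
changes nothing. Tests require empirical PDRs of 2000-sample groups to lie
within 3 binomial standard errors of this formula for every algorithm.

**Study-like preset.** `study_preset()` mirrors the published cohort
layout (90/13/81 plasma and 72/12/76 stool CRC/AA/normal samples, stage
cells 18/27/26/10/9 and 15/18/23/9/7). Shedding parameters were derived
analytically from the anchors the published counts imply, via the
expected-positivity formula — e.g. plasma CRC `p_shedder = 0.87` with
per-replicate q ≈ 0.83 gives 1/3 positivity 0.87·(1 − 0.17³) ≈ 0.866;
stool CRC `p_shedder = 0.98`, μ = 37.0, σ = 2.2, dropout 0.053 gives
q ≈ 0.947 and 3/3 + cutoff positivity 0.98·0.947³·0.99 ≈ 0.824; stool
normals mix 18% weak shedders (μ = 40) with 20% per-replicate background
at μ = 43.5, giving ≈ 0.53 under 1/3 but ≈ 0.07 under the final rule.
Stage cells share one parameter set per specimen/group — stage-specific
PDR differences in simulated output are sampling noise, not signal. The
preset is a *structural* stand-in: it reproduces the qualitative pattern
(stool signal stronger than plasma, normals mostly non-detected, stool AUC
above plasma AUC), and tests assert only that pattern plus internal
consistency, never the published AUC values, which depend on unpublished
Cp distributions.

**What passing synthetic tests does not show.** Real cohorts have
covariate structure (age, stage, tumor location) correlated with shedding,
batch effects, and non-normal Cp distributions; none of these are modeled.
Agreement between empirical and analytic positivity validates the
pipeline's arithmetic, not the biological realism of the preset.

## Numerical and I/O choices

- Cp values are stored as decimal cycles at full precision; report
  percentages round to one decimal and AUCs to three only at output time.
- Non-detects on disk: written as `ND`, accepted as `ND` (case-insensitive)
  or an empty field. Replicate indices are 1-based in files and ordering is
  by index, not file order. Round-trip I/O preserves Cp to 4 decimals and
  non-detect states exactly.
- Wilson bounds are clamped to exact 0/1 at zero/full counts (the analytic
  values), removing floating-point dust from `0.0` comparisons.
- Grid sizes used in the shipped checks: 10,000 random samples for rule
  monotonicity, 500 random vectors for the AUC oracle, all 2×2 tables with
  margins ≤ 15 for the Fisher enumeration, a 19×3 binomial grid × 2000
  draws for Wilson coverage, and 2000 samples/group for parameter recovery.

## Known limitations

- Sample-level validity policies beyond the three provided (e.g. retest
  workflows) are out of scope; invalid samples are only flagged and
  excluded, never re-queued.
- The DeLong interval is asymptotic; for very small groups it can be wide
  or touch the truncation bounds, and the degenerate all-tied case is
  reported as uninformative rather than estimated.
- Fisher p-values for the strata tables are not expected to reproduce any
  particular published table, since the test used there is typically
  unstated; they are internally exact (validated against integer
  enumeration).
- The paired-subject generator couples only the shedder *state* across
  specimens, not the Cp levels; cross-specimen Cp correlation among
  double-positive subjects is therefore absent.
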