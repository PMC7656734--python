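# Methods

This note documents the models implemented by `mireqtl`, the parameters that
matter, the numerical choices, and the limits of what the synthetic cohorts
demonstrate.

## The prognostic model

The outcome is time to MCI-to-AD conversion under right censoring. The model
is a Cox proportional-hazards regression

    h(t | C, I) = h0(t) · exp(β₁C₁ + β₂C₂ + β₃C₃ + β₄I₁ + … + β_nI_m)

over three clinical covariates — C₁ = age (years), C₂ = sex (male = 1,
female = 0), C₃ = APOE4 allele count (0/1/2) — and m miR-eQTL pair
covariates. Risk is summarized by the prognostic index PI = Σ βᵢxᵢ, the bare
linear predictor with no centering and no baseline term; the baseline hazard
h0(t) is intentionally not estimated, since stratification and concordance
need only the PI.

**Pair covariates.** A miR-eQTL is a SNP–miRNA pair whose genotype dosage
predicts the miRNA's expression. The numeric covariate for a pair is the
product dosage × expression. The product is used because the same miRNA can
legitimately enter the model with several SNPs and the same SNP with several
miRNAs; under either marginal encoding (dosage alone or expression alone)
such rosters would be exactly collinear, while the product is the simplest
pair-specific value. Both marginal encodings remain selectable
(`encoding="dosage" | "expression"`) for sensitivity analysis.

**Feature pipeline.** Candidate SNPs are ranked by the two-sided Wald P of
the dosage term in a per-SNP logistic regression of converter status adjusted
for age, sex and APOE4 (maximum-likelihood fit via statsmodels; monomorphic
SNPs and non-converged fits, including separation, are flagged and excluded
from ranking, ties in P break by SNP id). The top p SNPs are paired with
miRNAs through an ordinary-least-squares eQTL scan whose adjusted P is the
permutation quantity (1 + #{|slope_perm| ≥ |slope_obs|}) / (n_perm + 1),
permuting expression sample labels against fixed genotypes (two-sided via
|slope|, +1 smoothing so the adjusted P can never fall below 1/(n_perm+1)).
Pairs with adjusted P < 0.1 (strict) among the pre-selected SNPs become
covariates.

**Model selection.** The pre-selection size p is chosen by 3-fold
cross-validation stratified by converter status, with one fixed partition
across the whole grid (re-partitioning per p would add selection noise).
Every fold re-runs the entire feature pipeline — association scan,
pre-selection, pair filtering, Cox fit — on its two training thirds only,
and scores Harrell's C on the held-out third; the optimal p maximizes the
mean held-out C (ties to the smallest p). The final model refits on the
whole discovery cohort at the optimal p, and its prognostic-index cutoff is
frozen there before touching validation data.

**Risk stratification.** The cutoff is the candidate minimizing the two-group
log-rank P over midpoints between consecutive distinct prognostic indices.
Candidates that would leave either risk group below `min_group_frac = 0.1`
of the cohort are skipped — a guard against degenerate one-patient groups;
the guard is configurable and the skipped candidates are deterministic.
Classification is strict: PI > cutoff means high risk. On exact P ties the
smaller cutoff wins.

**Model comparison.** The bootstrap comparison resamples the full cohort
with replacement; each replicate refits the Cox coefficients and the
minimum-P cutoff for both the full model and the clinical-only model,
holding the pair roster fixed, and records each arm's log-rank P. The two
per-replicate distributions are compared with Welch's unequal-variance t on
log10(P) — raw P values are bounded and heavily skewed, so the comparison is
made on the log scale. Replicates degenerate in either arm (no admissible
cutoff, too few events, non-convergence) are dropped from both arms to keep
the samples paired; more than 20% dropped aborts the comparison.

## Survival machinery

Cox fitting delegates to lifelines' `CoxPHFitter` (Newton–Raphson with
step-halving on the Efron-tie-corrected partial likelihood; Breslow
available behind the `ties` flag) behind pre-checks that enforce this
package's contracts: at least two events, no constant columns, and a
QR-based rank check that names collinear columns instead of silently
regularizing. The default stopping precision is 1e-9 so that fits agree with
direct numeric maximization of the partial likelihood to ~1e-6 on small
cohorts.

Kaplan–Meier curves, the log-rank test, Harrell's C and the cutoff scan are
implemented in-package. The log-rank core is vectorized over many candidate
cutoffs at once (group-membership matrix times at-risk/event incidence
matrices), which the cutoff scan inside the bootstrap loop needs; lifelines
and scikit-survival serve as independent cross-checks in the test suite.
Conventions: samples censored exactly at an event time count as at risk for
that event time; Harrell's C counts a pair as comparable when the
shorter-time member has the event (or, at tied times, exactly one member
does), with score ties worth 1/2; a log-rank variance of zero yields
statistic 0 and P = 1.

## Upstream preprocessing

**miRNA arrays.** Background mean and SD come from the negative-control
signals after trimming floor(0.05·n) values from each tail (the common
trimmed-moment convention; the SD is the population SD, a fixed documented
choice). Signals above mean + 2·SD become log2(signal − mean); detected but
weaker signals become min(effective) − 0.1 on that array; undetected entries
are filled with the per-miRNA minimum across arrays (a miRNA undetected
everywhere gets 0 with a warning). Finally every value is divided by the
mean of the array's three internal-control values. The division is applied
on the log2 scale, following the listed order of operations (the log step
precedes standardization); linear-scale averaging would be the alternative
reading and can be emulated upstream. After standardization the control mean
is exactly 1 on every array, which the tests assert. The transform is
one-shot: expression matrices carry a provenance flag and re-normalization
is rejected.

**Genotypes.** QC keeps SNPs with call rate ≥ 0.99 and MAF ≥ 0.01
(inclusive, matching the "≥" thresholds). LD pruning slides 50-SNP windows
advanced by 5 SNPs over the order index (windows are SNP counts, not base
pairs) and greedily removes, while any retained pair exceeds r² = 0.1, the
SNP in the most violating pairs — ties by lower MAF, then later order index.
SNPs with any missing call are dropped before pruning; constant-dosage SNPs
have undefined correlation and are treated as r² = 0. The greedy order is
this package's documented rule: exact equivalence with PLINK's internal
removal order is not guaranteed, but the post-condition (no retained
within-window pair above threshold) is asserted by re-checking.

**RNA-seq counts.** Per gene, the floor(0.05·n) largest counts are replaced
by the maximum of the remaining values and the smallest by the minimum of
the remaining (k = 0 leaves the gene unchanged; boundary ties break by
stable sort order). Genes are retained when CPM = count/library·10⁶ exceeds
1 in strictly more than one fourth of samples, with library sizes computed
from the column sums of the combined matrix.

**Networks.** Target genes require prediction score strictly above 90. The
zero-order network keeps direct interactions only: edges at confidence ≥ 900
(the boundary is inclusive — the cutoff "set to 900" admits 900 — and
configurable) between two seed genes; isolated seeds are dropped because a
zero-order network is edge-induced (retaining them is available behind a
flag upstream of the degree computation). Hubs are nodes of degree ≥ 5; the
separate mutual-adjacency flag reports whether every hub pair is itself
directly connected, decomposing a criterion that conflates both properties.

## The synthetic cohorts

The simulator provides every input the pipeline consumes, with the
statistical structure the analysis assumes:

* **Genotypes**: dosage ~ Binomial(2, MAF), MAF ~ Uniform(0.05, 0.5) per SNP
  (Hardy–Weinberg, no LD by default; `generate_ld_genotypes` plants block LD
  via copy-with-flip-noise for pruning tests).
* **Clinical covariates**: age ~ Normal(75.42, 5.75²) truncated at 60 years;
  sex ~ Bernoulli(73/197); APOE4 ~ Categorical(126, 61, 10)/197 — the
  emulated cohort's pooled profile.
* **Expression**: y = 5 + slope·dosage + Normal(0, 1) for planted causal
  pairs (distinct SNPs, distinct miRNAs — one cis-style effect per miRNA),
  pure noise otherwise, on the normalized log2 scale.
* **Survival**: inverse-transform sampling from the planted Cox model,
  T = −ln(U)/(rate·exp(PI)), with administrative censoring C ~ Uniform(183,
  2555) days — the "at least 6 months, up to 7 years" follow-up support.
  Observed time is min(T, C), event = [T ≤ C]. The baseline rate is not a
  hand-tuned constant: a one-dimensional bisection finds the rate whose
  expected conversion fraction — integrated in closed form over the uniform
  censoring law — equals 42.1%. When pair effects are planted the search
  runs on the realized cohort's prognostic indices, so the calibration holds
  for any configuration. The default clinical log-hazard ratios are the
  reference model's (age 0.077, sex 0.530, APOE4 0.602); `pair_beta`
  defaults to 0 (the default cohort's hazard depends on clinical factors
  only) and planted-effect scenarios set it explicitly (the pipeline tests
  use 0.2, comparable to the reference pair coefficients).
* **eQTL candidate universe**: `cis_candidate_pairs` emulates a
  cis-restricted miR-eQTL database — each miRNA versus a handful of
  candidate SNPs including its causal one. This matters: the per-pair
  permutation threshold of 0.1 admits ~10% of null pairs by construction, so
  scanning the full pre-selected-SNP × miRNA cross product floods a
  desk-scale Cox model with false covariates, whereas a real eQTL database
  is sparse. The cis universe is the package's stand-in for that sparsity;
  the in-house-database construction it emulates is an assumption, not a
  reproduction.
* **Raw arrays / networks**: probe-signal batches with known background
  moments, deliberate sub-threshold and undetected probes, and
  always-effective controls; toy interactomes with planted hubs and edge
  confidences spanning the 900 cutoff.

Every generator is a pure function of (config, seed); per-stage seeds derive
from the master seed via `SeedSequence([seed, stage])`, so regeneration is
byte-identical and stages are independent of call order.

**What passing tests do and do not show.** The synthetic cohorts have
independent SNPs (unless LD is requested), Gaussian expression noise, a
correctly specified proportional-hazards outcome, and no population
structure, batch effects, relatedness, imputation uncertainty or
informative censoring. Recovery of planted effects therefore demonstrates
correctness of the machinery — no leakage, correct test calibration, honest
model comparison — not expected performance on real cohorts, where effect
sparsity, LD and confounding are harsher.

## Problem sizes and defaults

The pipeline-level tests and the worked example run at desk scale chosen to
keep the planted signal comfortably detectable: 197 patients (98/99 split),
150 SNPs, 24 miRNAs, 6 causal pairs with eQTL slope 1.5 and pair log-hazard
ratio 0.2, 199 permutations in the eQTL scan, pre-selection grids drawn from
{25, 150}, and 200–500 bootstrap replicates. The library defaults mirror the
full-scale procedure (pre-selection grid 100…10,000 by 100, 999
permutations, 10,000 bootstrap replicates); all sizes are plain arguments.

## Known limitations

* The logistic scan fits one statsmodels model per SNP; at genome scale a
  dedicated scan (or PLINK itself) would be the tool of choice.
* The permutation-adjusted eQTL P is per-pair, not family-adjusted across
  pairs; a database built this way needs an additional sparsity mechanism
  (here, the cis candidate universe).
* PLINK's exact within-window removal order in LD pruning is not public;
  only the pruning post-condition, not the identical kept set, is
  guaranteed relative to PLINK.
* The bootstrap comparison refits coefficients and cutoff per replicate with
  a fixed pair roster; re-running pre-selection inside every replicate would
  be an alternative (and far costlier) design.
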