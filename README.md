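# mireqtl

Integrative miR-eQTL prognostic modelling of conversion from mild cognitive
impairment (MCI) to Alzheimer's disease (AD).

Not every MCI patient progresses to AD, and identifying the patients at high
risk of conversion is what makes early intervention possible. `mireqtl`
implements, as a tested and reusable Python library, a multi-omics survival
pipeline that combines blood-based miRNA expression with genotype data:

1. **miRNA microarray normalization** — background thresholding from trimmed
   negative-control signals, `log2(signal − mean)` effective-signal transform,
   floor replacement, undetected-value filling, and standardization by three
   internal-control miRNAs (`mirna_norm`);
2. **genotype QC** — call-rate/MAF filtering and PLINK-style windowed LD
   pruning (`--indep-pairwise 50 5 0.1` semantics) (`genotype_qc`);
3. **feature construction** — a covariate-adjusted logistic association scan
   `logit(P) = β₀ + β₁·age + β₂·sex + β₃·APOE4 + β₄·X_SNP` between converters
   and non-converters, top-*p* SNP pre-selection, permutation-based SNP–miRNA
   (miR-eQTL) pairing at adjusted *P* < 0.1, and dosage×expression pair
   covariates (`association`);
4. **survival modelling** — a Cox proportional-hazards model
   `h(t|C,I) = h₀(t)·exp(Σ βᵢCᵢ + Σ βⱼIⱼ)` over the clinical factors
   (age, sex, APOE4 allele count) and the pair covariates; the prognostic
   index `PI = Σ βᵢxᵢ`, Harrell's C-index, Kaplan–Meier curves, the log-rank
   test, and risk stratification at the minimum-log-rank-*P* cutoff
   (`survival`);
5. **pipeline orchestration** — converter-stratified cohort splitting, nested
   3-fold cross-validation of the pre-selection size *p* (the scan is re-run
   inside every fold, so nothing leaks from held-out samples), final-model
   training, independent validation with the frozen discovery cutoff, and a
   bootstrap comparison of the full model against the clinical-only model via
   Welch's *t* on per-replicate log10 log-rank *P* values (`pipeline`);
6. **downstream biology** — miRNA→target mapping (prediction score > 90),
   zero-order PPI sub-network extraction (confidence ≥ 900), and hub-gene
   detection (degree ≥ 5) (`network`); RNA-seq count preprocessing with
   per-gene 5% winsorization and CPM > 1 filtering (`rnaseq_prep`).

Because matched genotype + expression + follow-up data of this kind are not
publicly available, the package ships a first-class **synthetic-cohort
simulator** (`synth`): Hardy–Weinberg genotypes, additive eQTL effects,
clinical covariates matching the emulated cohort profile (age 75.4 ± 5.8
truncated at 60 years, 37% male, APOE4 counts 126/61/10 of 197), and survival
drawn from a planted Cox model whose baseline rate is calibrated so that
~42.1% of patients convert with a mean observed follow-up near 971 days.

## Worked example

```bash
mireqtl run-all --out demo/ --seed 5
```

simulates a 197-patient cohort with six planted miR-eQTL effects, splits it
98/99 stratified by converter status, cross-validates the pre-selection
grid, trains the final model, validates it, and bootstrap-compares it with
the clinical-only model. Output (`demo/manifest.json`):

```json
{
  "seed": 5,
  "n_samples": 197,
  "optimal_p": 150,
  "n_pairs": 18,
  "cutoff": 16.56971658508731,
  "discovery_c_index": 0.9170695425808851,
  "validation_c_index": 0.8993506493506493,
  "validation_logrank_p": 1.2910578488924561e-18,
  "bootstrap_welch_t": -217.7550735641575,
  "bootstrap_welch_p": 0.0,
  "bootstrap_replicates": 200
}
```

Read this as: cross-validation picked the larger pre-selection size (*p* =
150), 18 SNP–miRNA pairs passed the permutation filter and entered the Cox
model; patients above the discovery prognostic-index cutoff (16.57) convert
much faster than those below it in the held-out validation half (log-rank
*P* ≈ 10⁻¹⁸, C-index 0.90), and across 200 bootstrap replicates the model
with miR-eQTLs stratifies risk far better than age + sex + APOE4 alone
(Welch *P* ≪ 0.01; reported as 0.0 below double-precision underflow).

The same steps are available programmatically:

```python
import mireqtl as m
from mireqtl.synth import cis_candidate_pairs

sim = m.simulate_cohort(m.SimulationConfig(seed=5, pair_beta=0.2))
discovery, validation = m.stratified_split(sim.cohort, seed=5)
source = m.EqtlScanSource(
    n_perm=199, seed=5,
    candidate_pairs=cis_candidate_pairs(sim.genotypes, sim.expression,
                                        sim.truth, seed=5),
)
cv = m.cross_validate_p(discovery, sim.genotypes, sim.expression, source,
                        p_grid=(25, 150), seed=5)
model = m.train_final(discovery, sim.genotypes, sim.expression, source,
                      cv.optimal_p)
result = m.evaluate(model, validation, sim.genotypes, sim.expression)
print(result.c_index, result.logrank.p)
```

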