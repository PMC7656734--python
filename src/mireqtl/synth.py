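"""Synthetic-cohort simulator.

Generates data with the statistical structure the downstream analysis assumes:

* Hardy-Weinberg genotypes with configurable minor-allele frequencies;
* additive cis-style eQTL effects of dosage on log2-scale miRNA expression;
* clinical covariates matching a Japanese MCI cohort (age 75.4 +/- 5.8 years
  truncated at 60, 37% male, APOE4 allele counts 0/1/2 with frequencies
  126/61/10 out of 197);
* follow-up generated from a planted Cox proportional-hazards model with
  exponential baseline and uniform administrative censoring between 6 months
  and 7 years, calibrated so that ~42.1% of patients convert during follow-up
  with a mean observed follow-up near 971 days;
* raw microarray signal batches and toy interactome/target-table fixtures for
  the normalization and network stages.

Every generator is a pure function of ``(config, seed)``; per-stage seeds are
derived from the master seed through ``numpy.random.SeedSequence([seed,
stage])`` so stages are independent of call order.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    TruthRecord,
    pair_column,
)
from .exceptions import ConfigurationError

log = logging.getLogger(__name__)

# stage offsets for the seed fan-out
_STAGE_GENOTYPES = 0
_STAGE_CLINICAL = 1
_STAGE_EXPRESSION = 2
_STAGE_SURVIVAL = 3
_STAGE_RAW_ARRAY = 4
_STAGE_NETWORK = 5

# fixed internal seed for the baseline-rate calibration draw (the calibrated
# rate must be a deterministic function of the configuration alone)
_CALIBRATION_SEED = 170904
_CALIBRATION_N = 20000

#: pooled APOE4 allele-count frequencies (0/1/2 alleles) of the emulated cohort
DEFAULT_APOE4_PROBS = (126 / 197, 61 / 197, 10 / 197)

#: clinical log-hazard ratios of the reference prognostic model
DEFAULT_COX_BETAS = {"age": 0.077, "sex": 0.530, "apoe4": 0.602}

#: observed conversion fraction the default survival calibration targets
TARGET_EVENT_FRACTION = 83 / 197


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``baseline_rate`` (events/day) defaults to None, meaning "calibrate so the
    expected conversion fraction equals :data:`TARGET_EVENT_FRACTION`"; the
    calibration is a deterministic one-dimensional search (see
    :func:`calibrate_baseline_rate`).
    """

    n_samples: int = 197
    n_snps: int = 200
    n_mirnas: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_pairs: int = 8
    eqtl_slope: float = 1.0
    expr_mean: float = 5.0
    expr_noise_sd: float = 1.0
    cox_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COX_BETAS)
    )
    pair_beta: float = 0.0
    baseline_rate: float | None = None
    admin_censor_days: float = 7 * 365.0
    min_followup_days: float = 183.0
    age_mean: float = 75.42
    age_sd: float = 5.75
    age_min: float = 60.0
    male_frac: float = 73 / 197
    apoe4_probs: tuple[float, float, float] = DEFAULT_APOE4_PROBS
    n_background_probes: int = 40
    raw_bg_mean: float = 100.0
    raw_bg_sd: float = 5.0
    raw_undetected_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_mirnas", "n_causal_pairs"):
            if getattr(self, name) <= 0 and not (
                name == "n_causal_pairs" and self.n_causal_pairs == 0
            ):
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if abs(sum(self.apoe4_probs) - 1.0) > 1e-12:
            raise ConfigurationError("apoe4_probs must sum to 1")
        if not 0.0 <= self.male_frac <= 1.0:
            raise ConfigurationError("male_frac must be a probability")
        if self.n_causal_pairs > min(self.n_snps, self.n_mirnas):
            raise ConfigurationError(
                "n_causal_pairs cannot exceed n_snps or n_mirnas"
            )
        if self.admin_censor_days <= self.min_followup_days:
            raise ConfigurationError(
                "admin_censor_days must exceed min_followup_days"
            )
        if self.baseline_rate is not None and self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")


def _snp_ids(n: int) -> pd.Index:
    return pd.Index([f"rs{i + 1:06d}" for i in range(n)], name="snp")


def _mirna_ids(n: int) -> pd.Index:
    return pd.Index([f"MIMAT{i + 1:07d}" for i in range(n)], name="mirna")


# ---------------------------------------------------------------------------
# genotypes


def generate_genotypes(
    config: SimulationConfig, maf: float | np.ndarray | None = None
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages, Binomial(2, MAF) per SNP.

    Per-SNP MAFs are Uniform over ``config.maf_range`` unless ``maf`` is given
    (a scalar or per-SNP array override, e.g. 0 for a monomorphic fixture).
    """
    rng = _rng(config, _STAGE_GENOTYPES)
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    if maf is not None:
        mafs = np.broadcast_to(np.asarray(maf, dtype=float), (config.n_snps,)).copy()
        if ((mafs < 0) | (mafs > 0.5)).any():
            raise ConfigurationError("MAF override must lie in [0, 0.5]")
    dosages = rng.binomial(2, mafs[None, :], size=(config.n_samples, config.n_snps))
    frame = pd.DataFrame(
        dosages.astype(float), index=_sample_ids(config.n_samples),
        columns=_snp_ids(config.n_snps),
    )
    return GenotypeMatrix(frame, configured_maf=pd.Series(mafs, index=frame.columns))


# ---------------------------------------------------------------------------
# clinical covariates


def generate_clinical(
    config: SimulationConfig, n: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw age (truncated normal, >= 60 years), sex and APOE4 allele count."""
    n = config.n_samples if n is None else n
    rng = _rng(config, _STAGE_CLINICAL) if rng is None else rng
    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = rng.binomial(1, config.male_frac, size=n)
    apoe4 = rng.choice(3, size=n, p=np.asarray(config.apoe4_probs))
    return pd.DataFrame(
        {"age": age, "sex": sex, "apoe4": apoe4}, index=_sample_ids(n)
    )


# ---------------------------------------------------------------------------
# expression with planted eQTL effects


def generate_expression(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, TruthRecord]:
    """Plant additive eQTL effects: y = mu + slope * dosage + N(0, sd^2).

    Causal pairs use distinct SNPs and distinct miRNAs (one cis-style effect
    per miRNA), drawn without replacement from the generated universe.
    """
    rng = _rng(config, _STAGE_EXPRESSION)
    n, q = geno.n_samples, config.n_mirnas
    mirnas = _mirna_ids(q)
    values = config.expr_mean + rng.normal(0.0, config.expr_noise_sd, size=(n, q))
    snp_pick = rng.choice(geno.n_snps, size=config.n_causal_pairs, replace=False)
    mir_pick = rng.choice(q, size=config.n_causal_pairs, replace=False)
    truth = TruthRecord()
    for sj, mj in zip(snp_pick, mir_pick):
        snp, mir = geno.snp_ids[sj], mirnas[mj]
        values[:, mj] += config.eqtl_slope * geno.dosages.iloc[:, sj].to_numpy()
        truth.causal_pairs.append((snp, mir))
        truth.true_eqtl_slopes[(snp, mir)] = config.eqtl_slope
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=geno.sample_ids, columns=mirnas), normalized=True
    )
    return expr, truth


# ---------------------------------------------------------------------------
# survival


def _expected_event_fraction(
    rate: float, pi: np.ndarray, a: float, b: float
) -> float:
    """Analytic conversion probability under Uniform(a, b) censoring.

    For hazard lam = rate * exp(pi), P(T <= C) integrated over C ~ U(a, b) is
    1 - (exp(-lam a) - exp(-lam b)) / (lam (b - a)).
    """
    lam = rate * np.exp(pi)
    with np.errstate(over="ignore"):
        frac = 1.0 - (np.exp(-lam * a) - np.exp(-lam * b)) / (lam * (b - a))
    return float(np.mean(frac))


def calibrate_baseline_rate(
    config: SimulationConfig,
    pi: np.ndarray | None = None,
    target_event_frac: float = TARGET_EVENT_FRACTION,
    n_mc: int = _CALIBRATION_N,
) -> float:
    """One-dimensional search for the exponential baseline rate.

    Finds the rate (events/day) at which the expected conversion fraction
    equals ``target_event_frac`` under uniform administrative censoring, given
    the prognostic indices ``pi`` of the cohort. When ``pi`` is omitted it is
    computed from the configured clinical log-hazard ratios on a large
    reference draw of clinical covariates with a fixed internal seed, so the
    result depends only on the configuration's clinical parameters.
    """
    if pi is None:
        rng = np.random.default_rng(_CALIBRATION_SEED)
        clinical = generate_clinical(config, n=n_mc, rng=rng)
        betas = {k: v for k, v in config.cox_betas.items() if k in clinical.columns}
        pi = clinical[list(betas)].to_numpy() @ np.array(list(betas.values()))
    a, b = config.min_followup_days, config.admin_censor_days
    if not np.isfinite(b):
        raise ConfigurationError("cannot calibrate without administrative censoring")

    lo, hi = -60.0, 10.0  # bounds on ln(rate)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _expected_event_fraction(math.exp(mid), pi, a, b) < target_event_frac:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def generate_survival(
    features: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Inverse-transform sampling from the planted Cox model.

    T = -ln(U) / (baseline_rate * exp(PI)) with U ~ Uniform(0, 1); censoring
    C ~ Uniform(min_followup_days, admin_censor_days); observed time is
    min(T, C) and event = [T <= C]. With ``admin_censor_days`` infinite there
    is no censoring. When ``config.baseline_rate`` is None the rate is
    calibrated on this cohort's prognostic indices so the expected conversion
    fraction matches the default target. Returns a frame with ``time`` and
    ``event`` indexed like ``features``.
    """
    unknown = [k for k in config.cox_betas if k not in features.columns]
    if unknown:
        raise ConfigurationError(
            f"cox_betas name covariates absent from the features: {unknown}"
        )
    rng = _rng(config, _STAGE_SURVIVAL)
    betas = config.cox_betas
    if betas:
        pi = features[list(betas)].to_numpy() @ np.array(list(betas.values()))
    else:
        pi = np.zeros(len(features))
    rate = config.baseline_rate
    if rate is None:
        rate = calibrate_baseline_rate(config, pi=pi)
    lam = rate * np.exp(pi)
    u = rng.uniform(size=len(features))
    t_event = -np.log(u) / lam
    if np.isfinite(config.admin_censor_days):
        censor = rng.uniform(
            config.min_followup_days, config.admin_censor_days, size=len(features)
        )
    else:
        censor = np.full(len(features), np.inf)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=features.index)


def generate_ld_genotypes(
    config: SimulationConfig, block_size: int = 5, flip_prob: float = 0.05
) -> GenotypeMatrix:
    """Genotypes with block linkage disequilibrium, for pruning tests.

    SNPs come in consecutive blocks of ``block_size``: the first SNP of each
    block is drawn under Hardy-Weinberg, the rest are copies whose individual
    alleles flip with probability ``flip_prob`` (high within-block r2,
    independence across blocks).
    """
    rng = _rng(config, _STAGE_GENOTYPES)
    n, p = config.n_samples, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=p)
    dosages = np.empty((n, p), dtype=float)
    for j in range(p):
        if j % block_size == 0:
            dosages[:, j] = rng.binomial(2, mafs[j], size=n)
        else:
            tag = dosages[:, j - j % block_size]
            flips = rng.binomial(2, flip_prob, size=n)
            dosages[:, j] = np.abs(tag - flips) % 3
    frame = pd.DataFrame(
        dosages, index=_sample_ids(n), columns=_snp_ids(p)
    )
    return GenotypeMatrix(frame, configured_maf=pd.Series(mafs, index=frame.columns))


def cis_candidate_pairs(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    truth: TruthRecord,
    per_mirna: int = 5,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Candidate SNP-miRNA universe emulating a cis-restricted eQTL database.

    miR-eQTL databases test each miRNA against a limited set of nearby
    candidate SNPs rather than the full genome-wide cross product. Here every
    miRNA gets ``per_mirna`` candidate SNPs — its planted causal SNP (when it
    has one) plus random fillers — so downstream permutation filtering sees a
    realistic mix of true and null pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    causal = {m: s for s, m in truth.causal_pairs}
    snps = list(geno.snp_ids)
    pairs: list[tuple[str, str]] = []
    for mir in expr.mirna_ids:
        chosen: list[str] = []
        if mir in causal:
            chosen.append(causal[mir])
        fillers = rng.choice(
            [s for s in snps if s not in chosen],
            size=max(0, per_mirna - len(chosen)),
            replace=False,
        )
        chosen.extend(fillers)
        pairs.extend((s, mir) for s in chosen)
    return pairs


# ---------------------------------------------------------------------------
# raw microarray batches


@dataclass
class RawArrayBatch:
    """Bundle of raw arrays plus the control-probe ids they share."""

    arrays: list  # list of mirna_norm.RawSignalArray
    control_ids: tuple[str, str, str]


def generate_raw_array(config: SimulationConfig) -> RawArrayBatch:
    """Emit raw probe-signal arrays for the normalization stage.

    Per array: background probe signals N(bg_mean, bg_sd^2); linear-scale
    probe signals log-normal above background with a tail deliberately below
    the detection threshold; a configurable fraction flagged undetected; the
    first three miRNA ids serve as always-detected internal controls.
    """
    from .mirna_norm import RawSignalArray  # local import avoids a cycle

    if config.n_mirnas < 4:
        raise ConfigurationError("raw arrays need at least 4 probes")
    rng = _rng(config, _STAGE_RAW_ARRAY)
    mirnas = list(_mirna_ids(config.n_mirnas))
    controls = tuple(mirnas[:3])
    arrays = []
    for i in range(config.n_samples):
        bg = config.raw_bg_mean + config.raw_bg_sd * rng.standard_normal(
            config.n_background_probes
        )
        signals: dict[str, float | None] = {}
        for j, mir in enumerate(mirnas):
            if mir in controls:
                # controls sit far above background so they are always effective
                signals[mir] = config.raw_bg_mean + np.exp(
                    8.0 + 0.2 * rng.standard_normal()
                )
                continue
            if rng.uniform() < config.raw_undetected_rate:
                signals[mir] = None  # undetected on this array
                continue
            if rng.uniform() < 0.15:
                # weak probe: near background, below the mean + 2 SD threshold
                signals[mir] = config.raw_bg_mean + 0.5 * config.raw_bg_sd
            else:
                signals[mir] = config.raw_bg_mean + np.exp(
                    5.0 + 1.0 * rng.standard_normal()
                )
        arrays.append(
            RawSignalArray(
                array_id=f"A{i + 1:04d}",
                signals=signals,
                background=list(bg),
                control_ids=controls,
            )
        )
    return RawArrayBatch(arrays=arrays, control_ids=controls)


# ---------------------------------------------------------------------------
# network fixtures


def generate_network_fixture(
    config: SimulationConfig,
    n_hubs: int = 2,
    hub_degree: int = 6,
    n_seed_genes: int = 20,
    n_decoy_genes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Build a toy interactome and miRNA target table with planted hubs.

    Returns ``(interactome, target_table, planted_hubs)``. Hub genes are
    connected to ``hub_degree`` seed genes (and to each other) at confidence
    950; filler edges span the 900 confidence cutoff, and the target table
    spans the score-90 cutoff so strictness is exercised downstream.
    """
    rng = _rng(config, _STAGE_NETWORK)
    mirnas = list(_mirna_ids(max(config.n_mirnas, 3)))
    genes = [f"GENE{i + 1:03d}" for i in range(n_seed_genes)]
    decoys = [f"DECOY{i + 1:03d}" for i in range(n_decoy_genes)]
    hubs = [f"HUB{i + 1:02d}" for i in range(n_hubs)]

    # target table: every seed gene and hub is a high-score target of some
    # miRNA; decoys get scores at or below the cutoff
    rows = []
    for g in genes + hubs:
        rows.append((rng.choice(mirnas), g, float(rng.uniform(91, 100))))
    for g in decoys:
        rows.append((rng.choice(mirnas), g, float(rng.choice([90.0, rng.uniform(0, 90)]))))
    targets = pd.DataFrame(rows, columns=["mirna", "gene", "score"])

    edges = []
    for h in hubs:
        neighbours = rng.choice(genes, size=hub_degree, replace=False)
        for g in neighbours:
            edges.append((h, g, 950.0))
    for i in range(len(hubs)):
        for j in range(i + 1, len(hubs)):
            edges.append((hubs[i], hubs[j], 950.0))
    # filler edges among seed genes spanning the confidence cutoff
    for _ in range(3 * n_seed_genes):
        a, b = rng.choice(genes + decoys, size=2, replace=False)
        edges.append((a, b, float(rng.uniform(700, 1000))))
    interactome = (
        pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence"])
        .drop_duplicates(subset=["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    return interactome, targets, hubs


# ---------------------------------------------------------------------------
# full cohort convenience


@dataclass
class SimulatedCohort:
    """Everything one synthetic study provides."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    cohort: pd.DataFrame  # clinical covariates + time + event
    features: pd.DataFrame  # clinical + planted pair covariates
    truth: TruthRecord


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate genotypes, expression, clinical covariates and survival.

    The planted survival model uses the configured clinical log-hazard ratios
    plus ``config.pair_beta`` on every causal dosage-x-expression pair
    covariate (0 by default: the default cohort's conversion hazard depends on
    clinical factors only, with eQTL structure present in expression).
    """
    geno = generate_genotypes(config)
    expr, truth = generate_expression(geno, config)
    clinical = generate_clinical(config)
    features = clinical.copy()
    betas = dict(config.cox_betas)
    for snp, mir in truth.causal_pairs:
        col = pair_column(snp, mir)
        features[col] = (
            geno.dosages[snp].to_numpy() * expr.values[mir].to_numpy()
        )
        if config.pair_beta != 0.0:
            betas[col] = config.pair_beta
    truth.true_betas = dict(betas)
    surv_config = config.replace(cox_betas=betas, baseline_rate=config.baseline_rate)
    surv = generate_survival(features, surv_config)
    cohort = clinical.join(surv)
    return SimulatedCohort(
        config=config, genotypes=geno, expression=expr, cohort=cohort,
        features=features, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers


def write_cohort_tsvs(sim: SimulatedCohort, outdir) -> dict[str, str]:
    """Write genotype/expression/cohort/truth tables as TSV; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _w(name, frame):
        path = os.path.join(outdir, name)
        frame.to_csv(path, sep="\t")
        paths[name] = path

    _w("genotypes.tsv", sim.genotypes.dosages)
    _w("expression.tsv", sim.expression.values)
    _w("cohort.tsv", sim.cohort)
    truth = pd.DataFrame(
        [(s, m, b) for (s, m), b in sim.truth.true_eqtl_slopes.items()],
        columns=["snp", "mirna", "slope"],
    )
    path = os.path.join(outdir, "eqtl_truth.tsv")
    truth.to_csv(path, sep="\t", index=False)
    paths["eqtl_truth.tsv"] = path
    return paths


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal unphased-GT VCF (order index as position)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        samples = "\t".join(geno.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for pos, snp in enumerate(geno.snp_ids, start=1):
            col = geno.dosages[snp]
            calls = "\t".join(
                "./." if np.isnan(v) else gt_map[v] for v in col.to_numpy()
            )
            fh.write(f"1\t{pos}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")
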