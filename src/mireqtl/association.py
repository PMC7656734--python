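"""Per-SNP association scan, pre-selection, eQTL pairing, feature building.

The scan fits, per SNP, the covariate-adjusted logistic model

    logit(P) = b0 + b1*age + b2*sex + b3*APOE4 + b4*dosage

between converters and non-converters and reports a two-sided Wald P for b4.
Pre-selection ranks SNPs by ascending P and keeps the top ``p``. eQTL pairing
regresses miRNA expression on dosage and attaches a permutation-adjusted P
per pair ((1 + #{|slope_perm| >= |slope|}) / (n_perm + 1), expression labels
permuted against fixed genotypes). Pairs with adjusted P < 0.1 among the
pre-selected SNPs become model covariates; a pair covariate is the
dosage x expression product by default (marginal encodings are selectable,
but the product keeps pairs sharing a SNP or a miRNA from being collinear).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, check_cohort, pair_column
from .exceptions import InputError

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["snp", "mirna", "slope", "p_nominal", "p_adjusted"]


def logistic_scan(
    geno: GenotypeMatrix, clinical: pd.DataFrame, outcome: pd.Series
) -> pd.DataFrame:
    """Covariate-adjusted logistic association scan.

    Returns a frame indexed like the SNP panel with columns ``beta``, ``se``,
    ``z``, ``p``, ``converged`` and ``note``. Monomorphic SNPs and fits that
    fail (separation, non-convergence) are flagged with ``converged=False``
    and a missing P.
    """
    check_cohort(clinical)
    outcome = outcome.loc[clinical.index].astype(float)
    if outcome.nunique() < 2:
        raise InputError("outcome must contain both classes")
    base = sm.add_constant(
        clinical.loc[:, ["age", "sex", "apoe4"]].astype(float), prepend=True
    )
    dosages = geno.dosages.loc[clinical.index]
    y = outcome.to_numpy()

    records = []
    for snp in geno.snp_ids:
        d = dosages[snp].to_numpy(dtype=float)
        if np.isnan(d).any():
            records.append((snp, np.nan, np.nan, np.nan, np.nan, False, "missing"))
            continue
        if np.ptp(d) == 0:
            records.append((snp, np.nan, np.nan, np.nan, np.nan, False, "monomorphic"))
            continue
        design = base.to_numpy()
        X = np.column_stack([design, d])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta, se = fit.params[-1], fit.bse[-1]
            conv = bool(fit.mle_retvals.get("converged", False)) and np.isfinite(se)
            if not conv or se > 1e3:
                records.append((snp, beta, se, np.nan, np.nan, False, "nonconverged"))
                continue
            z = beta / se
            p = 2.0 * stats.norm.sf(abs(z))
            records.append((snp, beta, se, z, p, True, ""))
        except Exception as exc:  # separation, singular design, ...
            records.append((snp, np.nan, np.nan, np.nan, np.nan, False, type(exc).__name__))
    result = pd.DataFrame(
        records, columns=["snp", "beta", "se", "z", "p", "converged", "note"]
    ).set_index("snp")
    return result


def preselect(results: pd.DataFrame, p: int) -> list[str]:
    """Top-``p`` SNPs by ascending Wald P (ties by SNP id; flagged excluded)."""
    if p < 1:
        raise InputError("p must be >= 1")
    usable = results[results["converged"] & results["p"].notna()]
    if usable.empty:
        raise InputError("no converged association results to pre-select from")
    ordered = usable.reset_index().sort_values(["p", "snp"], kind="stable")
    return list(ordered["snp"].head(p))


def eqtl_scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    candidate_pairs="all",
    n_perm: int = 999,
    seed: int = 0,
    permutations=None,
) -> pd.DataFrame:
    """OLS slope of expression on dosage with a permutation-adjusted P.

    ``candidate_pairs`` is either ``"all"`` (every SNP x miRNA combination) or
    an explicit list of ``(snp, mirna)`` tuples. ``permutations`` may supply
    explicit index arrays (e.g. the full enumeration on a toy cohort),
    overriding ``n_perm``/``seed``. Zero-variance dosage or expression pairs
    are skipped with a warning.
    """
    shared = geno.sample_ids.intersection(expr.sample_ids)
    if permutations is None:
        if len(shared) < 10:
            raise InputError("need at least 10 shared samples")
        if n_perm < 19:
            raise InputError("need at least 19 permutations")
    elif len(shared) < 4:
        raise InputError("need at least 4 shared samples")

    if candidate_pairs == "all":
        snps = list(geno.snp_ids)
        mirnas = list(expr.mirna_ids)
        wanted = None
    else:
        snps = sorted({s for s, _ in candidate_pairs}, key=list(geno.snp_ids).index)
        mirnas = sorted({m for _, m in candidate_pairs}, key=list(expr.mirna_ids).index)
        wanted = set(candidate_pairs)

    X = geno.dosages.loc[shared, snps].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InputError("eqtl_scan requires complete dosages (run QC first)")
    Y = expr.values.loc[shared, mirnas].to_numpy(dtype=float)
    n = len(shared)

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx2 = (Xc**2).sum(axis=0)
    sy2 = (Yc**2).sum(axis=0)
    bad_x = sx2 == 0
    bad_y = sy2 == 0
    if bad_x.any() or bad_y.any():
        warnings.warn(
            "zero-variance dosage or expression: "
            f"{[s for s, b in zip(snps, bad_x) if b]} "
            f"{[m for m, b in zip(mirnas, bad_y) if b]}; pairs skipped",
            stacklevel=2,
        )
    sx2_safe = np.where(bad_x, 1.0, sx2)
    sy2_safe = np.where(bad_y, 1.0, sy2)

    cross = Xc.T @ Yc  # p x q
    slopes = cross / sx2_safe[:, None]
    r = cross / np.sqrt(np.outer(sx2_safe, sy2_safe))
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r2))
    p_nominal = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = (rng.permutation(n) for _ in range(n_perm))
        n_b = n_perm
    else:
        permutations = list(permutations)
        n_b = len(permutations)
    abs_obs = np.abs(slopes)
    exceed = np.zeros_like(slopes)
    for perm in permutations:
        slopes_b = (Xc.T @ Yc[perm]) / sx2_safe[:, None]
        exceed += np.abs(slopes_b) >= abs_obs
    p_adjusted = (1.0 + exceed) / (n_b + 1.0)

    rows = []
    for i, snp in enumerate(snps):
        if bad_x[i]:
            continue
        for j, mir in enumerate(mirnas):
            if bad_y[j]:
                continue
            if wanted is not None and (snp, mir) not in wanted:
                continue
            rows.append(
                (snp, mir, slopes[i, j], p_nominal[i, j], p_adjusted[i, j])
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def filter_pairs(
    pairs: pd.DataFrame, threshold: float = 0.1, preselected: list[str] | None = None
) -> pd.DataFrame:
    """Pairs whose SNP is pre-selected and adjusted P < threshold (strict).

    Output order: SNP's pre-selection rank, then miRNA id. With
    ``preselected=None`` every SNP qualifies (rank by SNP id).
    """
    kept = pairs[pairs["p_adjusted"] < threshold].copy()
    if preselected is not None:
        rank = {s: i for i, s in enumerate(preselected)}
        kept = kept[kept["snp"].isin(rank)]
        kept["_rank"] = kept["snp"].map(rank)
    else:
        kept["_rank"] = kept["snp"]
    kept = kept.sort_values(["_rank", "mirna"], kind="stable").drop(columns="_rank")
    return kept.reset_index(drop=True)


def build_features(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    pairs: pd.DataFrame,
    clinical: pd.DataFrame,
    encoding: str = "product",
) -> pd.DataFrame:
    """Clinical covariates followed by one column per SNP-miRNA pair.

    ``encoding``: ``"product"`` (dosage x expression, default),
    ``"dosage"`` or ``"expression"`` for sensitivity analyses.
    """
    check_cohort(clinical)
    if encoding not in ("product", "dosage", "expression"):
        raise InputError(f"unknown pair encoding {encoding!r}")
    samples = clinical.index
    features = clinical.loc[:, ["age", "sex", "apoe4"]].astype(float).copy()
    for row in pairs.itertuples():
        if row.snp not in geno.dosages.columns:
            raise InputError(f"SNP {row.snp} absent from the genotype matrix")
        if row.mirna not in expr.values.columns:
            raise InputError(f"miRNA {row.mirna} absent from the expression matrix")
        d = geno.dosages.loc[samples, row.snp].to_numpy(dtype=float)
        e = expr.values.loc[samples, row.mirna].to_numpy(dtype=float)
        if encoding == "product":
            value = d * e
        elif encoding == "dosage":
            value = d
        else:
            value = e
        col = pair_column(row.snp, row.mirna)
        if col in features.columns:
            raise InputError(f"duplicate pair column {col}")
        features[col] = value
    if features.isna().any().any():
        raise InputError("feature matrix contains missing values")
    return features
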