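"""Workflow orchestration: cohort split, nested cross-validated pre-selection,
final model training, independent validation, and bootstrap model comparison.

The nested 3-fold cross-validation re-runs the whole feature pipeline
(association scan on the two training thirds, top-``p`` pre-selection, eQTL
pair filtering, feature construction, Cox fit) inside every fold, so no
information from a held-out third leaks into pre-selection. The pre-selection
grid ``p`` is scored by the mean held-out concordance index; the final model
is refit on the entire discovery cohort at the optimal ``p`` and its
prognostic-index cutoff (minimum log-rank P) is frozen before validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import build_features, eqtl_scan, filter_pairs, logistic_scan, preselect
from .containers import ExpressionMatrix, GenotypeMatrix, check_cohort
from .exceptions import DegenerateModelError, InputError
from .survival import (
    CoxModel,
    KMCurve,
    LogrankResult,
    concordance_index,
    cox_fit,
    km_curve,
    logrank_test,
    optimal_cutoff,
    prognostic_index,
)

log = logging.getLogger(__name__)

DEFAULT_P_GRID = tuple(range(100, 10001, 100))
EQTL_THRESHOLD = 0.1


@dataclass
class EqtlScanSource:
    """Run the permutation eQTL scan on the training samples of each fold.

    ``candidate_pairs`` optionally restricts the scan to an explicit
    SNP-miRNA candidate universe (e.g. cis candidates); otherwise every
    combination of the pre-selected SNPs with every miRNA is tested.
    """

    n_perm: int = 199
    seed: int = 0
    candidate_pairs: list | None = None

    def pairs_for(self, geno, expr, sample_ids, snp_ids) -> pd.DataFrame:
        from .association import PAIR_COLUMNS

        sub_expr = expr.subset_samples(sample_ids)
        if self.candidate_pairs is None:
            sub_geno = geno.subset_samples(sample_ids).subset_snps(snp_ids)
            return eqtl_scan(sub_geno, sub_expr, n_perm=self.n_perm, seed=self.seed)
        wanted = set(snp_ids)
        pairs = [(s, m) for s, m in self.candidate_pairs if s in wanted]
        if not pairs:
            return pd.DataFrame(columns=PAIR_COLUMNS)
        sub_geno = geno.subset_samples(sample_ids)
        return eqtl_scan(
            sub_geno, sub_expr, candidate_pairs=pairs,
            n_perm=self.n_perm, seed=self.seed,
        )


@dataclass
class PrecomputedEqtl:
    """A fixed external eQTL table (the in-house-database analogue)."""

    table: pd.DataFrame

    def pairs_for(self, geno, expr, sample_ids, snp_ids) -> pd.DataFrame:
        return self.table[self.table["snp"].isin(snp_ids)]


def _as_source(eqtl_source):
    if isinstance(eqtl_source, pd.DataFrame):
        return PrecomputedEqtl(eqtl_source)
    if hasattr(eqtl_source, "pairs_for"):
        return eqtl_source
    raise InputError("eqtl_source must be a pair table or expose pairs_for()")


@dataclass
class CVResult:
    p_grid: tuple
    mean_c: pd.Series  # mean held-out C-index per p
    fold_c: pd.DataFrame  # folds x p
    optimal_p: int
    fold_assignment: pd.Series
    fold_preselected: dict = field(default_factory=dict)  # fold -> p -> snp list


@dataclass
class RiskModel:
    model: CoxModel
    pairs: pd.DataFrame
    optimal_p: int
    cutoff: float
    cutoff_min_p: float
    train_c_index: float
    encoding: str
    discovery_ids: pd.Index
    preselected: list[str]


@dataclass
class EvaluationResult:
    c_index: float
    logrank: LogrankResult
    km_high: KMCurve
    km_low: KMCurve
    groups: pd.Series  # "high"/"low" per sample
    prognostic_index: pd.Series


@dataclass
class ComparisonResult:
    logp_full: np.ndarray  # per-replicate log10 log-rank P, full model
    logp_clinical: np.ndarray
    t: float
    df: float
    p: float
    n_replicates: int
    n_dropped: int


# ---------------------------------------------------------------------------
# cohort split and folds


def stratified_split(
    cohort: pd.DataFrame, discovery_frac: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split stratified by converter status; floor within each stratum goes to
    discovery, the remainder to validation."""
    check_cohort(cohort, survival=True)
    rng = np.random.default_rng(seed)
    disc_ids: list = []
    for _, stratum in cohort.groupby("event"):
        if len(stratum) < 2:
            raise InputError("each outcome class needs at least 2 members")
        ids = stratum.index.to_numpy().copy()
        rng.shuffle(ids)
        k = int(np.floor(discovery_frac * len(ids)))
        disc_ids.extend(ids[:k])
    discovery = cohort.loc[cohort.index.isin(disc_ids)]
    validation = cohort.loc[~cohort.index.isin(disc_ids)]
    if len(validation) == 0:
        warnings.warn("validation cohort is empty", stacklevel=2)
    return discovery, validation


def _fold_assignment(cohort: pd.DataFrame, n_folds: int, seed: int) -> pd.Series:
    """Round-robin fold labels within each converter stratum."""
    rng = np.random.default_rng(seed)
    labels = pd.Series(0, index=cohort.index)
    for _, stratum in cohort.groupby("event"):
        ids = stratum.index.to_numpy().copy()
        rng.shuffle(ids)
        labels.loc[ids] = np.arange(len(ids)) % n_folds
    return labels


# ---------------------------------------------------------------------------
# per-cohort model construction helper


def _fit_on(
    train_cohort: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    source,
    p: int,
    encoding: str,
) -> tuple[CoxModel, pd.DataFrame, list[str]]:
    """Association scan + pre-selection + pair filtering + Cox fit on one
    training cohort; returns (model, pairs, preselected)."""
    ids = train_cohort.index
    scan = logistic_scan(
        geno.subset_samples(ids), train_cohort, train_cohort["event"]
    )
    selected = preselect(scan, p)
    table = source.pairs_for(geno, expr, ids, selected)
    pairs = filter_pairs(table, EQTL_THRESHOLD, selected)
    if pairs.empty:
        warnings.warn("empty pair set; model degenerates to clinical-only",
                      stacklevel=2)
    features = build_features(geno, expr, pairs, train_cohort, encoding)
    model = cox_fit(features, train_cohort)
    return model, pairs, selected


def _score(
    model: CoxModel,
    pairs: pd.DataFrame,
    cohort: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    encoding: str,
) -> float:
    features = build_features(geno, expr, pairs, cohort, encoding)
    pi = prognostic_index(model, features)
    return concordance_index(pi, cohort["time"], cohort["event"])


# ---------------------------------------------------------------------------
# nested cross-validation over the pre-selection grid


def cross_validate_p(
    discovery: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    eqtl_source,
    p_grid=DEFAULT_P_GRID,
    seed: int = 0,
    n_folds: int = 3,
    encoding: str = "product",
) -> CVResult:
    """3-fold CV of the whole pipeline per pre-selection size ``p``.

    One fixed stratified partition is used across the entire grid; the optimal
    ``p`` attains the maximal mean held-out C-index (ties go to the smallest
    ``p``). Folds whose training part has no events are skipped with a
    warning; if every fold is skipped an error is raised.
    """
    check_cohort(discovery, survival=True)
    p_grid = tuple(sorted(set(int(p) for p in p_grid)))
    source = _as_source(eqtl_source)
    folds = _fold_assignment(discovery, n_folds, seed)
    fold_c = pd.DataFrame(
        np.nan, index=range(n_folds), columns=list(p_grid), dtype=float
    )
    fold_preselected: dict = {}

    for k in range(n_folds):
        test_ids = folds.index[folds == k]
        train_ids = folds.index[folds != k]
        train = discovery.loc[train_ids]
        test = discovery.loc[test_ids]
        if train["event"].sum() == 0 or test["event"].sum() == 0:
            warnings.warn(f"fold {k} skipped: no events", stacklevel=2)
            continue
        # the association scan is p-independent; run once per fold
        scan = logistic_scan(geno.subset_samples(train_ids), train, train["event"])
        fold_preselected[k] = {}
        for p in p_grid:
            try:
                selected = preselect(scan, p)
                table = source.pairs_for(geno, expr, train_ids, selected)
                pairs = filter_pairs(table, EQTL_THRESHOLD, selected)
                features = build_features(geno, expr, pairs, train, encoding)
                model = cox_fit(features, train)
                c = _score(model, pairs, test, geno, expr, encoding)
            except (DegenerateModelError, InputError) as exc:
                warnings.warn(f"fold {k}, p={p} degenerate: {exc}", stacklevel=2)
                continue
            fold_c.loc[k, p] = c
            fold_preselected[k][p] = selected
    if fold_c.isna().all(axis=None):
        raise InputError("all cross-validation folds were skipped")
    mean_c = fold_c.mean(axis=0, skipna=True)
    optimal_p = int(mean_c.idxmax())  # idxmax takes the first (smallest p) on ties
    return CVResult(
        p_grid=p_grid,
        mean_c=mean_c,
        fold_c=fold_c,
        optimal_p=optimal_p,
        fold_assignment=folds,
        fold_preselected=fold_preselected,
    )


def train_final(
    discovery: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    eqtl_source,
    optimal_p: int,
    encoding: str = "product",
    min_group_frac: float = 0.1,
) -> RiskModel:
    """Refit on the entire discovery cohort at the chosen ``p`` and freeze the
    minimum-log-rank-P prognostic-index cutoff."""
    check_cohort(discovery, survival=True)
    source = _as_source(eqtl_source)
    model, pairs, selected = _fit_on(
        discovery, geno, expr, source, optimal_p, encoding
    )
    features = build_features(geno, expr, pairs, discovery, encoding)
    pi = prognostic_index(model, features)
    cutoff, min_p = optimal_cutoff(
        pi, discovery["time"], discovery["event"], min_group_frac
    )
    train_c = concordance_index(pi, discovery["time"], discovery["event"])
    return RiskModel(
        model=model,
        pairs=pairs,
        optimal_p=optimal_p,
        cutoff=cutoff,
        cutoff_min_p=min_p,
        train_c_index=train_c,
        encoding=encoding,
        discovery_ids=discovery.index,
        preselected=selected,
    )


def evaluate(
    risk_model: RiskModel,
    validation: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    check_disjoint: bool = True,
) -> EvaluationResult:
    """Score a frozen model on a validation cohort.

    Risk groups come from the *discovery* cutoff — it is never re-estimated.
    Overlapping sample ids raise unless ``check_disjoint`` is disabled (e.g.
    to re-score the discovery cohort itself).
    """
    check_cohort(validation, survival=True)
    overlap = validation.index.intersection(risk_model.discovery_ids)
    if check_disjoint and len(overlap) > 0:
        raise InputError(
            f"validation overlaps the discovery cohort ({len(overlap)} samples)"
        )
    features = build_features(
        geno, expr, risk_model.pairs, validation, risk_model.encoding
    )
    pi = prognostic_index(risk_model.model, features)
    if pi.nunique() < 2:
        raise DegenerateModelError("constant prognostic index; cutoff inapplicable")
    c = concordance_index(pi, validation["time"], validation["event"])
    high = pi > risk_model.cutoff
    if high.all() or (~high).all():
        raise DegenerateModelError("cutoff puts every sample in one risk group")
    groups = pd.Series(np.where(high, "high", "low"), index=pi.index)
    lr = logrank_test(validation["time"], validation["event"], groups)
    km_high = km_curve(
        validation.loc[high, "time"], validation.loc[high, "event"]
    )
    km_low = km_curve(
        validation.loc[~high, "time"], validation.loc[~high, "event"]
    )
    return EvaluationResult(
        c_index=c, logrank=lr, km_high=km_high, km_low=km_low,
        groups=groups, prognostic_index=pi,
    )


# ---------------------------------------------------------------------------
# Welch's t and the bootstrap model comparison


def welch_t(x, y) -> tuple[float, float, float]:
    """Unequal-variance t statistic, Welch-Satterthwaite df, two-sided P.

    Convention: two zero-variance samples with equal means give (0, df, 1);
    zero-variance with unequal means is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise InputError("zero-variance samples with unequal means")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        sx**2 / (x.size - 1) + sy**2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def _replicate_logp(
    features: pd.DataFrame, cohort: pd.DataFrame, min_group_frac: float
) -> float:
    """Refit coefficients and cutoff on one bootstrap replicate; log10 of the
    log-rank P at the replicate's own optimal cutoff."""
    model = cox_fit(features, cohort)
    pi = prognostic_index(model, features)
    _, p = optimal_cutoff(pi, cohort["time"], cohort["event"], min_group_frac)
    return float(np.log10(max(p, 1e-300)))


def bootstrap_compare(
    cohort: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    eqtl_source,
    optimal_p: int,
    B: int = 10000,
    seed: int = 0,
    encoding: str = "product",
    min_group_frac: float = 0.1,
    clinical_pairs: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Bootstrap comparison of the full model against the clinical-only model.

    The feature roster (pre-selected pairs) is determined once on the input
    cohort; each replicate resamples the cohort with replacement, refits the
    Cox coefficients and the minimum-P cutoff for both arms, and records each
    arm's log-rank P. The two per-replicate distributions of log10(P) are
    compared with Welch's t test. Replicates degenerate in either arm are
    dropped (paired) and counted; more than 20% dropped is an error.
    ``clinical_pairs`` optionally replaces the clinical-only arm's (normally
    empty) pair roster, e.g. for a null self-comparison.
    """
    if B < 10:
        raise InputError("need at least 10 bootstrap replicates")
    check_cohort(cohort, survival=True)
    source = _as_source(eqtl_source)
    _, pairs, _ = _fit_on(cohort, geno, expr, source, optimal_p, encoding)
    empty_pairs = (
        pairs.iloc[0:0] if clinical_pairs is None else clinical_pairs
    )
    features_full = build_features(geno, expr, pairs, cohort, encoding)
    features_clin = build_features(geno, expr, empty_pairs, cohort, encoding)

    rng = np.random.default_rng(seed)
    logp_full, logp_clin = [], []
    dropped = 0
    n = len(cohort)
    for _ in range(B):
        take = rng.integers(0, n, size=n)
        boot_ids = [f"b{i}" for i in range(n)]
        boot_cohort = cohort.iloc[take].set_axis(boot_ids)
        try:
            f_full = features_full.iloc[take].set_axis(boot_ids)
            f_clin = features_clin.iloc[take].set_axis(boot_ids)
            lp_f = _replicate_logp(f_full, boot_cohort, min_group_frac)
            lp_c = _replicate_logp(f_clin, boot_cohort, min_group_frac)
        except (DegenerateModelError, InputError):
            dropped += 1
            continue
        logp_full.append(lp_f)
        logp_clin.append(lp_c)
    if dropped > 0.2 * B:
        raise InputError(f"{dropped}/{B} bootstrap replicates were degenerate")
    t, df, p = welch_t(logp_full, logp_clin)
    return ComparisonResult(
        logp_full=np.asarray(logp_full),
        logp_clinical=np.asarray(logp_clin),
        t=t, df=df, p=p,
        n_replicates=len(logp_full),
        n_dropped=dropped,
    )
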