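"""Core in-memory containers.

The package is DataFrame-centric, in the style of statsmodels/lifelines:

* a *clinical/survival cohort* is a :class:`pandas.DataFrame` indexed by sample
  id with columns ``age`` (years), ``sex`` (male = 1, female = 0), ``apoe4``
  (0/1/2 alleles) and, once follow-up exists, ``time`` (days > 0) and ``event``
  (1 = MCI-to-AD conversion, 0 = censored);
* a *feature matrix* is a DataFrame indexed by sample id whose first columns
  are the clinical covariates followed by one column per SNP-miRNA pair;
* an *eQTL pair table* is a DataFrame with columns ``snp``, ``mirna``,
  ``slope``, ``p_nominal``, ``p_adjusted``.

Genotypes and expression carry a little extra state and get thin dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

CLINICAL_COLUMNS = ("age", "sex", "apoe4")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix.

    Dosages are 0/1/2 stored as floats so that missing calls can be NaN.
    ``configured_maf`` holds the generating allele frequency when the matrix
    came from the simulator (None for data read from disk).
    """

    dosages: pd.DataFrame
    configured_maf: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise InputError("dosages must be 0, 1, 2 or missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing calls."""
        return self.dosages.notna().mean(axis=0)

    @property
    def maf(self) -> pd.Series:
        """Per-SNP empirical minor-allele frequency among non-missing calls."""
        f = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[sample_ids], self.configured_maf)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.dosages.columns]
        if missing:
            raise InputError(f"unknown SNP id(s): {missing[:5]}")
        cm = None
        if self.configured_maf is not None:
            cm = self.configured_maf.loc[snp_ids]
        return GenotypeMatrix(self.dosages.loc[:, snp_ids], cm)


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs log2-scale expression values.

    ``normalized`` is a provenance flag: arrays that already went through
    :func:`mireqtl.mirna_norm.normalize_batch` (or that the simulator emits on
    the normalized scale) must not be normalized again.
    """

    values: pd.DataFrame
    normalized: bool = True

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[sample_ids], self.normalized)


@dataclass
class TruthRecord:
    """Ground truth planted by the simulator, for parameter-recovery tests."""

    causal_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_betas: dict[str, float] = field(default_factory=dict)
    true_eqtl_slopes: dict[tuple[str, str], float] = field(default_factory=dict)

    def pair_columns(self) -> list[str]:
        return [pair_column(s, m) for s, m in self.causal_pairs]


def pair_column(snp: str, mirna: str) -> str:
    """Canonical feature-matrix column name for a SNP-miRNA pair."""
    return f"{snp}:{mirna}"


def check_cohort(cohort: pd.DataFrame, survival: bool = False) -> pd.DataFrame:
    """Validate a cohort frame's column contract; returns the frame."""
    for col in CLINICAL_COLUMNS:
        if col not in cohort.columns:
            raise InputError(f"cohort lacks required column {col!r}")
    if survival:
        for col in ("time", "event"):
            if col not in cohort.columns:
                raise InputError(f"cohort lacks required column {col!r}")
        if (cohort["time"] <= 0).any():
            raise InputError("follow-up times must be positive")
        if not cohort["event"].isin((0, 1)).all():
            raise InputError("event indicator must be 0/1")
    return cohort
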