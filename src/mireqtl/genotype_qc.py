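"""Variant-level QC and windowed LD pruning.

``qc_filter`` keeps SNPs by inclusive call-rate and MAF thresholds (defaults
0.99 / 0.01). ``ld_prune`` reproduces PLINK-style ``--indep-pairwise 50 5
0.1`` semantics over a SNP-count order index: sliding 50-SNP windows advanced
by 5 SNPs; within each window, while any retained pair of dosage columns has
squared Pearson correlation above the threshold, the SNP participating in the
most violating pairs is removed (ties broken by lower MAF, then later order
index). SNPs with any missing call are dropped before pruning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .exceptions import InputError

log = logging.getLogger(__name__)


def qc_filter(
    geno: GenotypeMatrix, min_call_rate: float = 0.99, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Keep SNPs with call rate >= min_call_rate and MAF >= min_maf."""
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise InputError("thresholds must lie in [0, 1]")
    if geno.n_snps == 0 or geno.n_samples == 0:
        raise InputError("empty genotype matrix")
    keep = (geno.call_rate >= min_call_rate) & (geno.maf >= min_maf)
    return geno.subset_snps(list(geno.snp_ids[keep]))


def _r2_matrix(block: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation; constant columns get r2 = 0."""
    centred = block - block.mean(axis=0)
    norms = np.sqrt((centred**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        log.info("constant-dosage SNP(s) in window treated as r2 = 0")
    safe = np.where(constant, 1.0, norms)
    unit = centred / safe
    r2 = (unit.T @ unit) ** 2
    r2[constant, :] = 0.0
    r2[:, constant] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.1,
) -> list[str]:
    """Windowed greedy LD pruning; returns the kept SNP ids in order."""
    if not window > step > 0:
        raise InputError("need window > step > 0")
    complete = geno.dosages.notna().all(axis=0)
    if not complete.all():
        log.info("dropping %d SNP(s) with missing calls before pruning",
                 int((~complete).sum()))
    snps = list(geno.snp_ids[complete])
    data = geno.dosages.loc[:, snps].to_numpy(dtype=float)
    maf = geno.maf.loc[snps].to_numpy()
    n = len(snps)
    removed = np.zeros(n, dtype=bool)

    start = 0
    while True:
        idx = np.arange(start, min(start + window, n))
        idx = idx[~removed[idx]]
        if idx.size >= 2:
            r2 = _r2_matrix(data[:, idx])
            alive = np.ones(idx.size, dtype=bool)
            while True:
                viol = (r2 > r2_threshold) & np.outer(alive, alive)
                counts = viol.sum(axis=1)
                if counts.max(initial=0) == 0:
                    break
                # most violating pairs; ties -> lower MAF, then later order index
                cand = np.flatnonzero(counts == counts.max())
                cand_global = idx[cand]
                order = np.lexsort((-cand_global, maf[cand_global]))
                drop_local = cand[order[0]]
                alive[drop_local] = False
                r2[drop_local, :] = 0.0
                r2[:, drop_local] = 0.0
            removed[idx[~alive]] = True
        if start + window >= n:
            break
        start += step
    return [s for s, r in zip(snps, removed) if not r]


# ---------------------------------------------------------------------------
# file I/O


def read_genotype_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(frame.astype(float))


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    geno.dosages.to_csv(path, sep="\t")


def read_vcf(path) -> GenotypeMatrix:
    """Read unphased GT dosages from a VCF (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows = [], []
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gts = variant.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        row = np.array([
            np.nan if g == 3 else (2.0 if g == 2 else float(g)) for g in gts
        ])
        rows.append(row)
    frame = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    frame.index.name = "sample"
    return GenotypeMatrix(frame)
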