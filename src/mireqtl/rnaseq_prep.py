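"""RNA-seq count preprocessing: per-gene 5% winsorization and CPM filtering.

``winsorize_counts`` replaces, per gene, the k = floor(0.05 n) largest counts
with the maximum of the remaining values and the k smallest with the minimum
of the remaining values (k = 0 leaves the gene untouched; boundary ties break
by stable sort order). ``cpm_filter`` keeps genes with CPM strictly above the
threshold in strictly more than the given fraction of samples, with library
sizes taken from the raw column sums.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .exceptions import InputError


def winsorize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (row-wise) 5% winsorization of a genes x samples count matrix."""
    if counts.shape[1] < 1:
        raise InputError("need at least one sample")
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    values = counts.to_numpy(dtype=float).copy()
    n = values.shape[1]
    k = math.floor(0.05 * n)
    if k == 0:
        return counts.copy()
    order = np.argsort(values, axis=1, kind="stable")
    rows = np.arange(values.shape[0])[:, None]
    low_idx = order[:, :k]
    high_idx = order[:, n - k:]
    keep_min = values[rows, order[:, k: k + 1]]
    keep_max = values[rows, order[:, n - k - 1: n - k]]
    values[rows, low_idx] = keep_min
    values[rows, high_idx] = keep_max
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    if (counts.dtypes == int).all() or np.issubdtype(counts.to_numpy().dtype, np.integer):
        out = out.astype(counts.to_numpy().dtype)
    return out


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.25
) -> list:
    """Genes with CPM > min_cpm in strictly more than min_frac of samples."""
    lib = counts.sum(axis=0)
    zero = lib == 0
    if zero.any():
        warnings.warn(
            f"sample(s) with zero library size excluded: {list(lib.index[zero])}",
            stacklevel=2,
        )
    use = counts.loc[:, ~zero]
    lib = lib[~zero]
    if use.shape[1] == 0:
        raise InputError("no samples with non-zero library size")
    cpm = use.div(lib, axis=1) * 1e6
    n_pass = (cpm > min_cpm).sum(axis=1)
    keep = n_pass > min_frac * use.shape[1]
    return list(counts.index[keep])


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    return counts
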