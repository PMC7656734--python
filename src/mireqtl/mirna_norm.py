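"""3D-Gene-style miRNA microarray signal normalization.

The procedure, per array:

1. background mean and SD from the negative-control signals after trimming
   the top and bottom 5% of values (``floor(0.05 n)`` per tail; population SD);
2. probe signals above ``mean + 2 SD`` become *effective* signals and are
   replaced by ``log2(signal - mean)``;
3. detected but non-effective signals become ``min(effective) - 0.1`` on that
   array;
4. across arrays, undetected entries are filled with the per-miRNA minimum of
   the filled values;
5. every value is divided by the mean of the array's three internal-control
   values (log2 scale), so the control mean is exactly 1 on every array.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import InputError, NormalizationError

log = logging.getLogger(__name__)


@dataclass
class RawSignalArray:
    """One raw microarray: linear-scale probe signals plus background.

    ``signals`` maps miRNA id to a linear-scale signal, or None when the probe
    was flagged undetected. ``control_ids`` are the three internal-control
    miRNAs used for cross-array standardization.
    """

    array_id: str
    signals: dict[str, float | None]
    background: list[float]
    control_ids: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.control_ids) != 3:
            raise InputError("exactly 3 internal-control miRNA ids are required")
        missing = [c for c in self.control_ids if c not in self.signals]
        if missing:
            raise InputError(
                f"array {self.array_id}: control probe(s) absent: {missing}"
            )
        if len(self.background) == 0:
            raise InputError(f"array {self.array_id}: background list is empty")


def background_stats(background: list[float]) -> tuple[float, float]:
    """Mean and population SD after trimming floor(0.05 n) values per tail."""
    values = np.sort(np.asarray(background, dtype=float))
    n = values.size
    if n < 3:
        raise InputError("need at least 3 background values")
    k = math.floor(0.05 * n)
    trimmed = values[k: n - k] if k > 0 else values
    return float(trimmed.mean()), float(trimmed.std(ddof=0))


def _effective_transform(array: RawSignalArray) -> tuple[dict[str, float], float, float]:
    """Apply the per-array background thresholding; returns filled detected
    values (log2 scale), plus the background mean and SD used."""
    mean, sd = background_stats(array.background)
    threshold = mean + 2.0 * sd
    effective: dict[str, float] = {}
    detected_weak: list[str] = []
    for mir, signal in array.signals.items():
        if signal is None:
            continue
        if signal > threshold:
            effective[mir] = math.log2(signal - mean)
        else:
            detected_weak.append(mir)
    bad_controls = [c for c in array.control_ids if c not in effective]
    if bad_controls:
        raise NormalizationError(
            f"array {array.array_id}: internal control probe(s) not effective: "
            f"{bad_controls}"
        )
    floor = min(effective.values()) - 0.1
    values = dict(effective)
    for mir in detected_weak:
        values[mir] = floor
    return values, mean, sd


def normalize_batch(arrays: list[RawSignalArray]) -> ExpressionMatrix:
    """Normalize a batch of raw arrays into one expression matrix.

    Raises :class:`NormalizationError` naming the offending array when an
    internal-control probe is undetected or not effective, and refuses input
    that has already been normalized.
    """
    if isinstance(arrays, ExpressionMatrix) or (
        arrays and isinstance(arrays[0], ExpressionMatrix)
    ):
        raise InputError("input is already a normalized ExpressionMatrix")
    if not arrays:
        raise InputError("no arrays to normalize")
    control_ids = arrays[0].control_ids
    for a in arrays:
        if a.control_ids != control_ids:
            raise InputError("all arrays must share the same control probes")

    mirnas = sorted({m for a in arrays for m in a.signals})
    filled = pd.DataFrame(
        np.nan, index=[a.array_id for a in arrays], columns=mirnas, dtype=float
    )
    for array in arrays:
        values, _, _ = _effective_transform(array)
        for mir, v in values.items():
            filled.loc[array.array_id, mir] = v

    # undetected entries: per-miRNA minimum of the filled values
    col_min = filled.min(axis=0, skipna=True)
    never = col_min.isna()
    if never.any():
        warnings.warn(
            f"miRNA(s) undetected on every array set to 0: "
            f"{list(col_min.index[never])}",
            stacklevel=2,
        )
        col_min = col_min.fillna(0.0)
    filled = filled.fillna(col_min)

    # standardize by the mean of the three internal-control values per array
    control_mean = filled[list(control_ids)].mean(axis=1)
    if (control_mean == 0).any():
        bad = list(control_mean.index[control_mean == 0])
        raise NormalizationError(f"zero control mean on array(s): {bad}")
    standardized = filled.div(control_mean, axis=0)
    standardized.index.name = "sample"
    standardized.columns.name = "mirna"
    return ExpressionMatrix(standardized, normalized=True)


# ---------------------------------------------------------------------------
# file I/O


def read_raw_dir(raw_dir, controls: tuple[str, str, str]) -> list[RawSignalArray]:
    """Read one TSV per array (columns: probe, signal, detected) plus a
    ``background.tsv`` (one signal per line) from ``raw_dir``."""
    import os

    bg_path = os.path.join(raw_dir, "background.tsv")
    background = list(np.loadtxt(bg_path, ndmin=1))
    arrays = []
    for name in sorted(os.listdir(raw_dir)):
        if name == "background.tsv" or not name.endswith(".tsv"):
            continue
        table = pd.read_csv(os.path.join(raw_dir, name), sep="\t")
        signals = {
            row.probe: (float(row.signal) if int(row.detected) else None)
            for row in table.itertuples()
        }
        arrays.append(
            RawSignalArray(
                array_id=name[: -len(".tsv")],
                signals=signals,
                background=background,
                control_ids=tuple(controls),
            )
        )
    return arrays


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_expression_tsv(path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0), normalized=True)
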