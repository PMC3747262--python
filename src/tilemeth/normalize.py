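"""From raw two-channel intensities to a replicate-averaged methylation matrix.

The pipeline is: log2(bound/input) per probe per array, quantile
normalization across all arrays of one cell type, then averaging of the
technical replicate arrays of each sample.  Quantile normalization follows
the standard procedure of forcing every array's empirical distribution onto
the across-array mean of order statistics; ties within an array receive the
mean of the reference quantiles they span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import validate_sample_sheet


def compute_log_ratios(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-array log2(bound/input), as a probes x arrays matrix.

    Raises DomainError on non-positive channel values; intensities are never
    silently offset.
    """
    if len(intensities) == 0:
        raise DomainError("empty intensity table")
    bound = intensities["bound"].to_numpy(dtype=float)
    inp = intensities["input"].to_numpy(dtype=float)
    if (bound <= 0).any() or (inp <= 0).any():
        raise DomainError("non-positive channel intensity")
    long = intensities.assign(log_ratio=np.log2(bound) - np.log2(inp))
    wide = long.pivot(index="probe_id", columns="array_id", values="log_ratio")
    if wide.isna().any().any():
        raise DomainError("intensity table is not complete over (probe, array) pairs")
    return wide


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (arrays) of a probes x arrays matrix.

    After normalization every column's sorted value vector equals the
    across-column mean of sorted vectors; rank order within each column is
    preserved and tied values within a column get the mean of the reference
    quantiles they jointly occupy.
    """
    values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise DomainError("empty matrix")
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average assigned reference values over groups of tied raw values
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def average_replicates(
    matrix: pd.DataFrame, sheet: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate arrays to one column per subject.

    ``matrix`` is probes x arrays; the sample sheet maps array_id to
    subject_id.  ``method`` is 'mean' (default) or 'median'.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown replicate reduction {method!r}")
    sheet = validate_sample_sheet(sheet)
    mapping = sheet.set_index("array_id")["subject_id"]
    missing = [a for a in matrix.columns if a not in mapping.index]
    if missing:
        raise DomainError(f"arrays absent from sample sheet: {missing[:5]}")
    subjects = mapping.loc[list(matrix.columns)]
    grouped = matrix.T.groupby(subjects.to_numpy())
    collapsed = grouped.mean().T if method == "mean" else grouped.median().T
    # stable subject order: first appearance in the sheet
    order = [s for s in sheet["subject_id"].drop_duplicates() if s in collapsed.columns]
    return collapsed[order]


def normalize_study(
    intensities: pd.DataFrame,
    sheet: pd.DataFrame,
    cell_type: str | None = None,
    method: str = "mean",
) -> pd.DataFrame:
    """Full reduction for one cell type: log-ratios -> quantile norm -> averaging.

    Arrays of other cell types are excluded before normalization, so each
    cell type is normalized jointly across all of its arrays but
    independently of the other.
    """
    sheet = validate_sample_sheet(sheet)
    if cell_type is not None:
        sheet = sheet[sheet["cell_type"] == cell_type].reset_index(drop=True)
        if len(sheet) == 0:
            raise DomainError(f"no arrays for cell type {cell_type!r}")
        intensities = intensities[intensities["array_id"].isin(set(sheet["array_id"]))]
    ratios = compute_log_ratios(intensities)
    normalized = quantile_normalize(ratios)
    return average_replicates(normalized, sheet, method=method)
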