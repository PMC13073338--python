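"""log10 transform, additive batch-effect removal, merging and z-scoring.

Batch removal fits, per analyte, the additive model ``value ~ batch`` with
sum-to-zero batch coding and subtracts the estimated batch terms, which
protects the (unweighted-over-batches) grand mean — the same contract as
limma's ``removeBatchEffect`` for a single factor.  No covariates are
included in the batch model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, DegenerateInputError, StratomicsError

logger = logging.getLogger(__name__)


def log10_normalize(matrix: AnalyteMatrix) -> AnalyteMatrix:
    """Elementwise log10; missing values are preserved.

    Raises on zero or negative values, naming the first offending
    analyte/sample pair.
    """
    data = matrix.data
    bad = (data <= 0)
    if bad.any().any():
        row_pos, col_pos = np.argwhere(bad.to_numpy()).T
        analyte = data.index[row_pos[0]]
        sample = data.columns[col_pos[0]]
        raise StratomicsError(
            f"non-positive abundance {data.loc[analyte, sample]!r} at "
            f"analyte {analyte!r}, sample {sample!r}: log10 undefined"
        )
    return AnalyteMatrix(np.log10(data), dataset=matrix.dataset, scale="log10")


def remove_batch_effect(matrix: AnalyteMatrix, batch: pd.Series) -> AnalyteMatrix:
    """Subtract per-analyte additive batch terms (sum-to-zero coding).

    With a single batch level this is the identity.  After removal the
    per-batch means of every analyte agree (up to missing-value imbalance)
    and the unweighted mean of batch means is preserved.
    """
    data = matrix.data
    batch = batch.reindex(data.columns)
    if batch.isna().any():
        missing = batch.index[batch.isna()][0]
        raise StratomicsError(f"sample {missing!r} has no batch label")
    levels = batch.unique()
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise DegenerateInputError(
            f"batch {small!r} has fewer than 2 samples"
        )
    if len(levels) == 1:
        return matrix.copy()
    # per-analyte batch means (over non-missing values)
    batch_means = data.T.groupby(batch).mean().T  # analytes x levels
    grand = batch_means.mean(axis=1)              # unweighted mean of batch means
    adjusted = data.copy()
    for level in levels:
        cols = batch.index[batch == level]
        offset = batch_means[level] - grand
        adjusted[cols] = adjusted[cols].sub(offset, axis=0)
    return AnalyteMatrix(adjusted, dataset=matrix.dataset, scale=matrix.scale)


def merge_and_standardize(matrices: list[AnalyteMatrix],
                          zscore: bool = False) -> AnalyteMatrix:
    """Column-concatenate datasets on their common analytes; optionally
    z-score each analyte within each source dataset (divisor n-1).

    Z-scoring puts effect sizes on the per-SD scale; it is off by default
    for the primary path and recorded in the output's ``scale``.
    """
    if not matrices:
        raise StratomicsError("no matrices to merge")
    common = matrices[0].analytes
    for m in matrices[1:]:
        common = common.intersection(m.analytes)
    if len(common) == 0:
        raise StratomicsError("empty analyte intersection across datasets")
    dropped = sum(m.shape[0] for m in matrices) - len(common) * len(matrices)
    if dropped:
        logger.info("merge: intersection of %d analytes (%d rows dropped)",
                    len(common), dropped)
    blocks = []
    for m in matrices:
        block = m.data.loc[common].copy()
        if zscore:
            mean = block.mean(axis=1)
            sd = block.std(axis=1, ddof=1)
            degenerate = (sd == 0) | sd.isna()
            if degenerate.any():
                analyte = common[degenerate.to_numpy().nonzero()[0][0]]
                raise DegenerateInputError(
                    f"analyte {analyte!r} has zero variance in dataset "
                    f"{m.dataset!r}: cannot z-score"
                )
            block = block.sub(mean, axis=0).div(sd, axis=0)
        blocks.append(block)
    merged = pd.concat(blocks, axis=1)
    if merged.columns.has_duplicates:
        raise StratomicsError("duplicate sample ids across merged datasets")
    scale = "zscore" if zscore else matrices[0].scale
    return AnalyteMatrix(merged, dataset="merged", scale=scale)
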