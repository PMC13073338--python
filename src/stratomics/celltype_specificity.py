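"""Cell-type assignment by the 1.5x dominance rule and fold enrichment.

For each gene, the proportional contribution of every reference cell type
(its mean expression divided by the gene's total across types) is computed;
the gene is assigned to the top cell type when that contribution is at
least 1.5x the second highest (inclusive), otherwise it stays unassigned.
Because the row total cancels, the ratio test on proportions equals the
ratio test on raw means.  Zero-total genes and exact top ties are
unassigned.

Fold enrichment of a differentially-expressed gene set against a background
is, per cell type t,

    fe_t = log2[ (dep assigned to t / |dep|) / (background assigned to t / |background|) ],

with 0.5 added to both counts whenever either is zero so the value stays
finite and sign-correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DegenerateInputError, StratomicsError

UNASSIGNED = "unassigned"


def assign_cell_specificity(reference: pd.DataFrame,
                            dominance_ratio: float = 1.5) -> pd.Series:
    """Per-gene cell-type assignment (or ``unassigned``).

    ``reference`` is a genes x cell-types matrix of nonnegative mean
    expression with at least 2 cell types.
    """
    if reference.shape[1] < 2:
        raise StratomicsError("cell-type reference needs >= 2 cell types")
    values = reference.to_numpy(dtype=float)
    if (values < 0).any():
        gene = reference.index[np.argwhere(values < 0)[0][0]]
        raise StratomicsError(f"negative expression for gene {gene!r}")
    totals = values.sum(axis=1)
    assignment = pd.Series(UNASSIGNED, index=reference.index, dtype=object)
    ok = totals > 0
    props = np.zeros_like(values)
    props[ok] = values[ok] / totals[ok, None]
    order = np.argsort(props, axis=1)
    top_idx = order[:, -1]
    top = props[np.arange(len(props)), top_idx]
    second = props[np.arange(len(props)), order[:, -2]]
    dominant = ok & (top >= dominance_ratio * second) & (top > second)
    assignment[dominant] = reference.columns.to_numpy()[top_idx[dominant]]
    return assignment


def celltype_fold_enrichment(dep_genes: set[str], assignments: pd.Series,
                             background: set[str]) -> pd.DataFrame:
    """log2 fold enrichment of a gene set over the background, per cell type.

    Returns one row per cell type (plus an ``unassigned`` row carrying
    counts only) with dep/background counts and ``log2_fe``.
    """
    dep_genes = set(dep_genes)
    background = set(background)
    if not dep_genes:
        raise DegenerateInputError("empty differentially-expressed gene set")
    if not dep_genes <= background:
        stray = sorted(dep_genes - background)[:5]
        raise StratomicsError(f"dep genes outside background: {stray}")
    missing = background - set(assignments.index)
    if missing:
        raise StratomicsError(
            f"assignments do not cover background: {sorted(missing)[:5]}"
        )
    asn = assignments.loc[sorted(background)]
    cell_types = sorted(set(asn) - {UNASSIGNED})
    n_dep = len(dep_genes)
    n_bg = len(background)
    dep_asn = asn.loc[sorted(dep_genes)]
    rows = []
    for ct in cell_types:
        a = int((dep_asn == ct).sum())
        b = int((asn == ct).sum())
        if a == 0 or b == 0:
            fe = np.log2(((a + 0.5) / n_dep) / ((b + 0.5) / n_bg))
        else:
            fe = np.log2((a / n_dep) / (b / n_bg))
        rows.append((ct, a, b, float(fe)))
    rows.append((UNASSIGNED, int((dep_asn == UNASSIGNED).sum()),
                 int((asn == UNASSIGNED).sum()), np.nan))
    return pd.DataFrame(rows, columns=["cell_type", "dep_count",
                                       "background_count", "log2_fe"])
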