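"""Spearman lncRNA-mRNA correlation and threshold-retained matrix blocks.

The rank correlation is the tie-corrected Spearman coefficient (Pearson
on mid-ranks); for tie-free data it coincides with the classical closed
form 1 - 6*sum(d_i^2) / (n*(n^2-1)).  Thresholding at alpha keeps every
row (mRNA) and column (lncRNA) that has at least one entry with
|C| >= alpha, preserving sub-threshold entries inside surviving
rows/columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = ["ThresholdedCorrelation", "spearman", "correlation_block", "threshold_matrix"]


@dataclass
class ThresholdedCorrelation:
    """Retained correlation block C_ML(alpha) with per-row/col hit counts."""

    alpha: float
    matrix: pd.DataFrame  # rows: mRNAs, columns: lncRNAs
    n_r: pd.Series  # per-row count of |C| >= alpha
    n_c: pd.Series  # per-column count of |C| >= alpha

    @property
    def row_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def col_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def empty(self) -> bool:
        return self.matrix.size == 0


def spearman(x, y) -> float:
    """Tie-corrected Spearman rank correlation of two equal-length vectors.

    Returns NaN for a constant vector (undefined correlation; callers
    exclude such features downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def correlation_block(
    expr: ExpressionMatrix,
    rows,
    cols,
    samples=None,
) -> pd.DataFrame:
    """Full Spearman block between ``rows`` (mRNAs) and ``cols`` (lncRNAs).

    ``samples`` restricts the computation (e.g. to tumor samples, the
    default use).  Features whose expression is constant across the
    selected samples yield NaN entries.
    """
    rows, cols = pd.Index(rows), pd.Index(cols)
    if rows.empty or cols.empty:
        raise ValueError("empty feature set")
    vals = expr.values if samples is None else expr.values.loc[:, samples]
    sub = vals.loc[rows.append(cols)]
    ranks = sub.rank(axis=1).to_numpy()
    constant = np.ptp(sub.to_numpy(), axis=1) == 0
    r = np.corrcoef(ranks)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    p = len(rows)
    return pd.DataFrame(r[:p, p:], index=rows, columns=cols)


def threshold_matrix(c_full: pd.DataFrame, alpha: float) -> ThresholdedCorrelation:
    """Drop rows/columns with no entry |C| >= alpha; count surviving hits.

    An all-sub-threshold input returns an empty (flagged, not error)
    result.  NaN entries never count as hits.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    hits = c_full.abs() >= alpha
    keep_rows = hits.any(axis=1)
    keep_cols = hits.any(axis=0)
    mat = c_full.loc[keep_rows, keep_cols]
    sub_hits = hits.loc[keep_rows, keep_cols]
    return ThresholdedCorrelation(
        alpha=alpha,
        matrix=mat,
        n_r=sub_hits.sum(axis=1),
        n_c=sub_hits.sum(axis=0),
    )
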