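"""Fuse expression and structure correlations into the adjusted matrix.

AC(m,l) = sign-preserving max: +max(|C|, E') when C >= 0, -max(|C|, E')
when C < 0.  The adjustment never shrinks a correlation and never flips
its sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import ThresholdedCorrelation

__all__ = ["AdjustedCorrelation", "AdjustmentSummary", "fuse", "adjustment_summary"]


@dataclass
class AdjustedCorrelation:
    """Adjusted correlation block AC_ML(alpha)."""

    alpha: float
    matrix: pd.DataFrame


@dataclass
class AdjustmentSummary:
    n_total: int
    n_unchanged: int
    n_adjusted: int
    min_adjustment: float  # NaN when nothing was adjusted
    max_adjustment: float


def _as_frame(c) -> tuple[pd.DataFrame, float]:
    if isinstance(c, ThresholdedCorrelation):
        return c.matrix, c.alpha
    return c, np.nan


def fuse(c, eprime: pd.DataFrame) -> AdjustedCorrelation:
    """Entrywise signed maximum of |C| and the normalized structure score.

    ``c`` may be a :class:`ThresholdedCorrelation` or a plain DataFrame;
    ``eprime`` must be shape-aligned and inside [0, 1].
    """
    cm, alpha = _as_frame(c)
    if cm.shape != eprime.shape:
        raise ValueError(f"shape mismatch: C {cm.shape} vs E' {eprime.shape}")
    ep = eprime.to_numpy(dtype=float)
    if (ep < 0).any() or (ep > 1).any():
        raise ValueError("E' entries must lie in [0, 1]")
    cv = cm.to_numpy(dtype=float)
    mag = np.maximum(np.abs(cv), ep)
    ac = np.where(cv >= 0, mag, -mag)
    return AdjustedCorrelation(
        alpha=alpha, matrix=pd.DataFrame(ac, index=cm.index, columns=cm.columns)
    )


def adjustment_summary(c, ac, tolerance: float = 1e-6) -> AdjustmentSummary:
    """Count unchanged vs adjusted entries and the adjustment range.

    An entry is unchanged when |AC - C| <= tolerance; the default
    tolerance matches 6-decimal printed precision, where an unchanged
    value can still differ by one unit in the last printed digit.
    """
    cm, _ = _as_frame(c)
    am, _ = _as_frame(ac) if not isinstance(ac, AdjustedCorrelation) else (ac.matrix, None)
    if cm.shape != am.shape:
        raise ValueError("shape mismatch between C and AC")
    delta = np.abs(am.to_numpy(dtype=float) - cm.to_numpy(dtype=float)).ravel()
    # small absolute guard so a difference of exactly one printed ulp is not
    # pushed over the tolerance by float representation error
    unchanged = delta <= tolerance + 1e-12
    adjusted = delta[~unchanged]
    return AdjustmentSummary(
        n_total=delta.size,
        n_unchanged=int(unchanged.sum()),
        n_adjusted=int(adjusted.size),
        min_adjustment=float(adjusted.min()) if adjusted.size else float("nan"),
        max_adjustment=float(adjusted.max()) if adjusted.size else float("nan"),
    )
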