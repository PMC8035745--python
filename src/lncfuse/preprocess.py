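"""Cohort filtering, TMM normalization, log2-CPM and differential expression.

The differential-expression path is deliberately plain: Welch t-tests on
TMM-normalized log2-CPM values, Benjamini-Hochberg correction applied
within each feature class (mRNA / lncRNA) separately, and strict
threshold filtering on adjusted p and |logFC|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "filter_cohort",
    "tmm_factors",
    "log_cpm",
    "differential_expression",
    "bh_adjust",
    "filter_dysregulated",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression values (features x samples) with feature classes.

    ``values.loc[j, i]`` is the expression of sample ``i`` on feature ``j``.
    ``feature_class`` maps every feature id to ``"mRNA"`` or ``"lncRNA"``.
    """

    values: pd.DataFrame
    feature_class: pd.Series = field(default=None)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValueError("feature ids are not unique")
        if self.feature_class is None:
            self.feature_class = pd.Series("mRNA", index=self.values.index)
        self.feature_class = self.feature_class.reindex(self.values.index)

    @property
    def samp_no(self) -> int:
        return self.values.shape[1]

    def features_of_class(self, cls: str) -> pd.Index:
        return self.values.index[self.feature_class == cls]


def filter_cohort(sample_sheet: pd.DataFrame, min_os_days: int = 10) -> pd.DataFrame:
    """Drop tumor samples with overall survival shorter than ``min_os_days``.

    Normal samples carry no overall-survival semantics and are always kept.
    A tumor sample with missing ``os_days`` is an error.
    """
    if "os_days" not in sample_sheet.columns:
        raise ValueError("sample sheet lacks an os_days column")
    tumor = sample_sheet["group"] == "tumor"
    if sample_sheet.loc[tumor, "os_days"].isna().any():
        bad = sample_sheet.index[tumor & sample_sheet["os_days"].isna()].tolist()
        raise ValueError(f"tumor samples with missing os_days: {bad}")
    keep = ~tumor | (sample_sheet["os_days"] >= min_os_days)
    return sample_sheet.loc[keep].copy()


def _upper_quartile_rate(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    # 75th percentile of nonzero-inclusive counts, scaled by library size
    q = np.percentile(counts, 75, axis=0)
    return q / lib


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref_column: str | int | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample column.

    Follows the canonical definition: the reference sample is the one whose
    upper-quartile count rate is closest to the mean rate; per sample, genes
    expressed in both sample and reference contribute a log-ratio M and an
    average log-abundance A; the top/bottom ``trim_m`` of M and ``trim_a``
    of A are discarded and the remaining M are averaged with inverse
    delta-method variance weights.  Factors are rescaled to geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("a sample column has zero total count")

    if ref_column is None:
        uq = _upper_quartile_rate(x, lib)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(ref_column, str):
        ref_idx = counts.columns.get_loc(ref_column)
    else:
        ref_idx = int(ref_column)
    ref = x[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        log_factors[j] = _tmm_one(x[:, j], lib[j], ref, ref_lib, trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_one(obs, lib_obs, ref, lib_ref, trim_m, trim_a) -> float:
    use = (obs > 0) & (ref > 0)
    if not use.any():
        return 0.0
    o, r = obs[use], ref[use]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else f


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
    feature_class: pd.Series | None = None,
) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior_count) / (lib_size * factor) * 1e6)
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    lib = x.sum(axis=0)
    f = np.ones_like(lib) if factors is None else factors.reindex(counts.columns).to_numpy()
    eff = lib * f
    vals = np.log2((x + prior_count) / eff * 1e6)
    df = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(df, feature_class)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix, groups: pd.Series, adjust_jointly: bool = False
) -> pd.DataFrame:
    """Per-feature Welch t-test of tumor vs normal on normalized values.

    logFC is mean(tumor) - mean(normal) on the log2 scale.  BH correction
    is applied within each feature class separately unless
    ``adjust_jointly`` is set.  Returns a DETable-style frame with columns
    feature, class, logFC, p, adj_p (direction is added by
    :func:`filter_dysregulated`).
    """
    groups = groups.reindex(expr.values.columns)
    tum = expr.values.loc[:, (groups == "tumor").to_numpy()]
    nrm = expr.values.loc[:, (groups == "normal").to_numpy()]
    if tum.shape[1] < 2 or nrm.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    t, p = stats.ttest_ind(tum, nrm, axis=1, equal_var=False)
    logfc = tum.mean(axis=1) - nrm.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    de = pd.DataFrame(
        {
            "feature": expr.values.index,
            "class": expr.feature_class.to_numpy(),
            "logFC": logfc.to_numpy(),
            "t": t,
            "p": p,
        }
    ).set_index("feature", drop=False)
    if adjust_jointly:
        de["adj_p"] = bh_adjust(de["p"].to_numpy())
    else:
        de["adj_p"] = np.nan
        for cls, sub in de.groupby("class"):
            de.loc[sub.index, "adj_p"] = bh_adjust(sub["p"].to_numpy())
    return de


def filter_dysregulated(
    de: pd.DataFrame, lfc_thresh: float = 1.5, p_thresh: float = 0.01
) -> pd.DataFrame:
    """Annotate direction: up/down iff adj_p < p_thresh AND |logFC| > lfc_thresh.

    Both inequalities are strict; everything else is "ns".
    """
    de = de.copy()
    sig = (de["adj_p"] < p_thresh) & (de["logFC"].abs() > lfc_thresh)
    de["direction"] = "ns"
    de.loc[sig & (de["logFC"] > 0), "direction"] = "up"
    de.loc[sig & (de["logFC"] < 0), "direction"] = "down"
    return de
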