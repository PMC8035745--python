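"""Survival screening cascade, risk scoring, KM curves and independence tests.

Functional surface over the estimators in :mod:`lncfuse.estimators`:
univariate Cox screen -> random-survival-forest screen -> lasso-Cox
selection on the union, then a multivariate Cox risk model on the union
of the lasso survivors and any pathogenic-rescued lncRNAs.  Risk scores
are dichotomized at the cohort median and compared by Kaplan-Meier /
log-rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .estimators import (
    CoxRiskModel,
    LassoCoxSelector,
    RSFImportanceSelector,
    UnivariateCoxSelector,
    check_survival_y,
)

__all__ = [
    "SurvivalTable",
    "univariate_cox_screen",
    "rsf_screen",
    "lasso_cox_select",
    "multivariate_cox",
    "risk_scores",
    "assign_risk",
    "km_curve",
    "independence_cox",
    "split_cohort",
    "screen_cascade",
]


@dataclass
class SurvivalTable:
    """Per-sample expression profile plus overall survival and vital status.

    ``expression`` is samples x features; ``os_days`` and ``event`` are
    aligned to its index.
    """

    expression: pd.DataFrame
    os_days: pd.Series
    event: pd.Series

    def __post_init__(self):
        self.os_days = self.os_days.reindex(self.expression.index)
        self.event = self.event.reindex(self.expression.index)
        if (self.os_days <= 0).any() or self.os_days.isna().any():
            raise ValueError("overall survival must be positive for every sample")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be binary")
        if len(self.expression) < 2:
            raise ValueError("need at least 2 samples")

    @property
    def y(self) -> tuple[np.ndarray, np.ndarray]:
        return self.os_days.to_numpy(dtype=float), self.event.to_numpy(dtype=bool)

    def subset(self, samples) -> "SurvivalTable":
        return SurvivalTable(
            self.expression.loc[samples], self.os_days.loc[samples], self.event.loc[samples]
        )


def univariate_cox_screen(surv: SurvivalTable, candidates, p_thresh: float = 0.05) -> list:
    sel = UnivariateCoxSelector(p_threshold=p_thresh)
    sel.fit(surv.expression.loc[:, list(candidates)], surv.y)
    return sel.selected_features_


def rsf_screen(
    surv: SurvivalTable,
    candidates,
    importance_thresh: float = 9.0,
    n_trees: int = 1000,
    seed: int = 0,
    **kwargs,
) -> list:
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    sel = RSFImportanceSelector(
        importance_threshold=importance_thresh,
        n_trees=n_trees,
        random_state=seed,
        **kwargs,
    )
    sel.fit(surv.expression.loc[:, candidates], surv.y)
    return sel.selected_features_


def lasso_cox_select(surv: SurvivalTable, candidates, cv_folds: int = 10, seed: int = 0, **kwargs) -> list:
    sel = LassoCoxSelector(cv=cv_folds, random_state=seed, **kwargs)
    sel.fit(surv.expression.loc[:, list(candidates)], surv.y)
    return sel.selected_features_


def multivariate_cox(
    surv: SurvivalTable, features, drop_p: float = 0.8, keep_p: float = 0.05
) -> CoxRiskModel:
    model = CoxRiskModel(drop_p=drop_p, keep_p=keep_p)
    model.fit(surv.expression.loc[:, list(features)], surv.y)
    return model


def risk_scores(model: CoxRiskModel, expression: pd.DataFrame) -> pd.Series:
    """R(i) = sum_j beta_j * e_ij over the model's signature features."""
    return model.predict(expression)


def assign_risk(scores: pd.Series, cut_off: float | None = None) -> pd.Series:
    """Dichotomize risk scores; default cutoff is the median, ties -> high."""
    scores = pd.Series(scores)
    if scores.empty:
        raise ValueError("no scores")
    cut = float(np.median(scores)) if cut_off is None else cut_off
    return pd.Series(np.where(scores >= cut, "high", "low"), index=scores.index, name="risk_level")


def km_curve(times, events, groups):
    """Product-limit survival per group plus a log-rank comparison.

    Returns ``(curves, statistic, p)`` where ``curves`` maps each group
    label to a DataFrame with columns ``time`` and ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) == 0 or len(times) == 0:
        raise ValueError("empty input")
    curves = {}
    for lab in labels:
        m = groups == lab
        if m.sum() == 0:
            raise ValueError(f"group {lab} has zero samples")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(labels) == 1:
        return curves, np.nan, np.nan
    if len(labels) == 2:
        a, b = labels
        res = logrank_test(times[groups == a], times[groups == b], events[groups == a], events[groups == b])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def _cph(df: pd.DataFrame, time, event) -> CoxPHFitter:
    d = df.copy()
    d["_time"] = np.asarray(time, dtype=float)
    d["_event"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    cph.fit(d, duration_col="_time", event_col="_event")
    return cph


_SUMMARY_COLS = {
    "exp(coef)": "HR",
    "exp(coef) lower 95%": "ci_low",
    "exp(coef) upper 95%": "ci_high",
}


def independence_cox(surv_y, risk: pd.Series, clinical: pd.DataFrame):
    """Univariate and joint Cox fits of risk score against clinical covariates.

    ``clinical`` columns (age, gender, stage, T, N, M, ...) must be coded
    numerically; constant columns are excluded with a warning.  Returns
    ``(univariate, multivariate)`` frames with HR/CI/p and coef/z/p
    schemas respectively.
    """
    time, event = check_survival_y(surv_y)
    cols = []
    for c in clinical.columns:
        vals = pd.to_numeric(clinical[c], errors="coerce")
        if vals.nunique(dropna=True) <= 1:
            warnings.warn(f"excluding constant clinical column {c}", stacklevel=2)
            continue
        cols.append(c)
    df = clinical[cols].apply(pd.to_numeric).copy() if cols else pd.DataFrame(index=risk.index)
    df["risk_score"] = np.asarray(risk, dtype=float)

    uni_rows = []
    for c in df.columns:
        fit = _cph(df[[c]], time, event)
        row = fit.summary.rename(columns=_SUMMARY_COLS).loc[c, ["HR", "ci_low", "ci_high", "p"]]
        uni_rows.append(row.rename(c))
    univariate = pd.DataFrame(uni_rows)

    joint = _cph(df, time, event)
    multivariate = joint.summary[["coef", "z", "p"]].copy()
    return univariate, multivariate


def split_cohort(samples, proportion: float = 0.5, stratify=None, seed: int = 0):
    """Deterministic stratified train/test split (disjoint and exhaustive).

    Strata of size 1 go to the training set with a warning.
    """
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    samples = pd.Index(samples)
    strata = pd.Series("all", index=samples) if stratify is None else pd.Series(
        np.asarray(stratify), index=samples
    )
    rng = np.random.RandomState(seed)
    train, test = [], []
    for _, idx in strata.groupby(strata).groups.items():
        idx = list(idx)
        if len(idx) == 1:
            warnings.warn(f"stratum of size 1 assigned to train: {idx[0]}", stacklevel=2)
            train.extend(idx)
            continue
        order = rng.permutation(len(idx))
        n_train = int(round(proportion * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[i] for i in order[:n_train])
        test.extend(idx[i] for i in order[n_train:])
    return pd.Index(train), pd.Index(test)


@dataclass
class CascadeResult:
    """Stage-by-stage bookkeeping of the screening cascade."""

    univariate_hits: list
    rsf_hits: list
    union: list = field(default_factory=list)
    lasso_selected: list = field(default_factory=list)
    rescued: list = field(default_factory=list)
    multivariate_input: list = field(default_factory=list)
    model: CoxRiskModel | None = None

    @property
    def signature(self) -> list:
        return [] if self.model is None else self.model.signature_

    def counts(self) -> dict:
        return {
            "n_univariate": len(self.univariate_hits),
            "n_rsf": len(self.rsf_hits),
            "n_union": len(self.union),
            "n_lasso": len(self.lasso_selected),
            "n_rescued": len(self.rescued),
            "n_multivariate_input": len(self.multivariate_input),
            "n_signature": len(self.signature),
        }


def screen_cascade(
    surv: SurvivalTable,
    candidates,
    rescued=(),
    p_thresh: float = 0.05,
    rsf_importance_thresh: float = 9.0,
    rsf_trees: int = 1000,
    rsf_kwargs: dict | None = None,
    lasso_cv: int = 10,
    lasso_kwargs: dict | None = None,
    drop_p: float = 0.8,
    keep_p: float = 0.05,
    seed: int = 0,
) -> CascadeResult:
    """Full screening cascade: (univariate | RSF) -> lasso -> (| rescued) -> Cox.

    Preserves candidate order in all unions.  An empty multivariate input
    yields a result with no model and an empty signature.
    """
    candidates = list(candidates)
    uni = univariate_cox_screen(surv, candidates, p_thresh)
    rsf = rsf_screen(
        surv,
        candidates,
        importance_thresh=rsf_importance_thresh,
        n_trees=rsf_trees,
        seed=seed,
        **(rsf_kwargs or {}),
    )
    union = [c for c in candidates if c in set(uni) | set(rsf)]
    if len(union) >= 2:
        lasso = lasso_cox_select(surv, union, cv_folds=lasso_cv, seed=seed, **(lasso_kwargs or {}))
    else:
        lasso = list(union)
    rescued = [r for r in rescued if r in surv.expression.columns]
    multi_in = lasso + [r for r in rescued if r not in set(lasso)]
    result = CascadeResult(
        univariate_hits=uni,
        rsf_hits=rsf,
        union=union,
        lasso_selected=lasso,
        rescued=rescued,
        multivariate_input=multi_in,
    )
    if multi_in:
        result.model = multivariate_cox(surv, multi_in, drop_p=drop_p, keep_p=keep_p)
    return result
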