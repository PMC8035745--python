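"""Sklearn-style estimators for the survival screening cascade and risk model.

Each screening stage is a selector with ``fit``/``transform``/``get_support``
(DataFrame-aware), and the final multivariate Cox risk model is a
fit/predict estimator.  Feature matrices ``X`` are samples x features
(DataFrame preferred; columns become feature ids), and ``y`` is anything
:func:`check_survival_y` understands: a ``(time, event)`` tuple, a
DataFrame with ``os_days``/``event`` columns, or a scikit-survival
structured array.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "check_survival_y",
    "UnivariateCoxSelector",
    "RSFImportanceSelector",
    "LassoCoxSelector",
    "CoxRiskModel",
]


def check_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce ``y`` to (time, event) float/bool arrays with time > 0."""
    if isinstance(y, pd.DataFrame):
        tcol = "os_days" if "os_days" in y.columns else "time"
        time = y[tcol].to_numpy(dtype=float)
        event = y["event"].to_numpy()
    elif isinstance(y, np.ndarray) and y.dtype.names:
        event_f, time_f = y.dtype.names
        time, event = y[time_f].astype(float), y[event_f]
    else:
        time, event = y
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
    event = event.astype(bool)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    return time, event


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def cox_score_test(X, time, event) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Cox score (log-rank trend) test at beta = 0, Breslow ties.

    Returns (chi-square statistics, p-values), one per feature column.
    Vectorized over features: risk-set sums are suffix cumulative sums
    over samples sorted by time.
    """
    x = np.asarray(X, dtype=float)
    n, p = x.shape
    order = np.argsort(time, kind="mergesort")
    xs, ts, es = x[order], time[order], event[order]
    s0 = np.arange(n, 0, -1, dtype=float)  # risk-set sizes at each sorted index
    s1 = np.cumsum(xs[::-1], axis=0)[::-1]
    s2 = np.cumsum((xs ** 2)[::-1], axis=0)[::-1]
    u = np.zeros(p)
    v = np.zeros(p)
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        deaths = es[i:j]
        d = int(deaths.sum())
        if d:
            mean_r = s1[i] / s0[i]
            u += xs[i:j][deaths].sum(axis=0) - d * mean_r
            v += d * (s2[i] / s0[i] - mean_r ** 2)
        i = j
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(v > 0, u ** 2 / v, 0.0)
    return chi2, stats.chi2.sf(chi2, df=1)


class _SelectorBase(BaseEstimator):
    """Shared DataFrame-aware selection surface."""

    def get_support(self, indices: bool = False):
        mask = self.support_
        return np.where(mask)[0] if indices else mask

    @property
    def selected_features_(self) -> list:
        return list(np.asarray(self.feature_names_in_)[self.support_])

    def transform(self, X):
        X = _as_frame(X)
        return X.loc[:, self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def _setup(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return X


class UnivariateCoxSelector(_SelectorBase):
    """Keep features whose single-covariate Cox score-test p < threshold.

    Constant features have an undefined test; they are excluded with a
    warning rather than raising.
    """

    def __init__(self, p_threshold: float = 0.05):
        self.p_threshold = p_threshold

    def fit(self, X, y):
        X = self._setup(X)
        time, event = check_survival_y(y)
        if X.shape[1] == 0:
            self.statistics_ = np.empty(0)
            self.pvalues_ = np.empty(0)
            self.support_ = np.empty(0, dtype=bool)
            return self
        constant = np.ptp(X.to_numpy(), axis=0) == 0
        if constant.any():
            warnings.warn(
                f"excluding constant features: {list(X.columns[constant])}",
                stacklevel=2,
            )
        self.statistics_, self.pvalues_ = cox_score_test(X.to_numpy(), time, event)
        self.pvalues_[constant] = np.nan
        self.support_ = np.where(constant, False, self.pvalues_ < self.p_threshold)
        return self


class RSFImportanceSelector(_SelectorBase):
    """Keep features with random-survival-forest permutation importance
    (concordance drop x 100) at or above ``importance_threshold``.

    Importance is measured on a held-out fraction of the training data
    when ``holdout`` is set, otherwise on the training data itself.
    """

    def __init__(
        self,
        importance_threshold: float = 9.0,
        n_trees: int = 1000,
        max_depth: int | None = None,
        min_samples_leaf: int = 15,
        n_repeats: int = 5,
        holdout: float | None = None,
        random_state: int = 0,
    ):
        self.importance_threshold = importance_threshold
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.n_repeats = n_repeats
        self.holdout = holdout
        self.random_state = random_state

    def fit(self, X, y):
        from sksurv.ensemble import RandomSurvivalForest

        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        X = self._setup(X)
        time, event = check_survival_y(y)
        ys = Surv.from_arrays(event=event, time=time)
        rng = np.random.RandomState(self.random_state)
        if self.holdout:
            n = len(X)
            idx = rng.permutation(n)
            n_hold = max(int(round(self.holdout * n)), 2)
            hold, tr = idx[:n_hold], idx[n_hold:]
        else:
            hold = tr = np.arange(len(X))
        self.forest_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X.iloc[tr].to_numpy(), ys[tr])
        result = permutation_importance(
            self.forest_,
            X.iloc[hold].to_numpy(),
            ys[hold],
            n_repeats=self.n_repeats,
            random_state=self.random_state,
        )
        self.importances_ = result.importances_mean * 100.0
        self.support_ = self.importances_ >= self.importance_threshold
        return self


def breslow_loglik(eta, time, event) -> np.ndarray:
    """Breslow Cox partial log-likelihood for one or many linear predictors.

    ``eta`` has shape (n,) or (n, k); returns a scalar-shaped array of k
    log-likelihoods.
    """
    eta = np.atleast_2d(np.asarray(eta, dtype=float).T).T  # (n, k)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    e2, t2, d2 = eta[order], time[order], event[order]
    # suffix log-sum-exp over the risk set, per column
    rev = e2[::-1]
    lse = np.logaddexp.accumulate(rev, axis=0)[::-1]
    # risk set for a tied group starts at the group's first index
    n = len(t2)
    group_start = np.zeros(n, dtype=int)
    for i in range(1, n):
        group_start[i] = group_start[i - 1] if t2[i] == t2[i - 1] else i
    idx = group_start[d2]
    return (e2[d2].sum(axis=0) - lse[idx].sum(axis=0)).ravel()


class LassoCoxSelector(_SelectorBase):
    """L1-penalized Cox selection with the penalty chosen by cross-validation.

    The regularization path comes from an elastic-net Cox fit
    (``l1_ratio = 1`` by default, i.e. pure lasso).  Each penalty is
    scored by the cross-validated partial log-likelihood
    (Verweij & van Houwelingen: the full-data likelihood of the
    fold-trained coefficients minus the training-fold likelihood), the
    Cox analogue of glmnet's partial-likelihood deviance.  The final
    penalty is the best ("best") or the largest within one standard
    error of the best ("1se", the default, favouring sparsity); features
    with non-zero coefficients at that penalty are selected.  Passing
    ``alpha`` skips cross-validation and forces the penalty.
    """

    def __init__(
        self,
        cv: int = 10,
        rule: str = "1se",
        l1_ratio: float = 1.0,
        n_alphas: int = 50,
        alpha_min_ratio: float = 0.01,
        alpha: float | None = None,
        random_state: int = 0,
    ):
        self.cv = cv
        self.rule = rule
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.alpha = alpha
        self.random_state = random_state

    def _fit_path(self, xv, ys, alphas=None):
        kwargs = dict(l1_ratio=self.l1_ratio)
        if alphas is None:
            kwargs.update(n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio)
        else:
            kwargs.update(alphas=alphas)
        fit = CoxnetSurvivalAnalysis(**kwargs)
        fit.fit(xv, ys)
        return np.asarray(fit.alphas_), fit.coef_

    def fit(self, X, y):
        X = self._setup(X)
        time, event = check_survival_y(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events for lasso-Cox selection")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 candidate features")
        ys = Surv.from_arrays(event=event, time=time)
        xv = X.to_numpy(dtype=float)

        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
            alphas, coefs = self._fit_path(xv, ys, alphas=[self.alpha_])
            self.coef_ = coefs[:, 0]
            self.support_ = self.coef_ != 0
            return self

        alphas, full_coefs = self._fit_path(xv, ys)  # descending penalties
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        scores = np.full((self.cv, len(alphas)), np.nan)
        for k, (tr, te) in enumerate(folds.split(xv)):
            if event[te].sum() == 0 or event[tr].sum() < 2:
                continue
            fit_alphas, coefs = self._fit_path(xv[tr], ys[tr], alphas=alphas)
            # map fitted columns back to the requested penalties
            col_of = {round(float(a), 12): i for i, a in enumerate(fit_alphas)}
            cols = [col_of.get(round(float(a), 12)) for a in alphas]
            ok = [i for i, c in enumerate(cols) if c is not None]
            beta = coefs[:, [cols[i] for i in ok]]  # (p, n_ok)
            ll_all = breslow_loglik(xv @ beta, time, event)
            ll_tr = breslow_loglik(xv[tr] @ beta, time[tr], event[tr])
            scores[k, ok] = ll_all - ll_tr
        mean = np.nanmean(scores, axis=0)
        nf = np.sum(~np.isnan(scores), axis=0)
        se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(np.maximum(nf, 1))
        best = int(np.nanargmax(mean))
        if self.rule == "1se":
            cutoff = mean[best] - se[best]
            chosen = next(
                i for i in range(len(alphas)) if not np.isnan(mean[i]) and mean[i] >= cutoff
            )
        else:
            chosen = best
        self.cv_scores_ = mean
        self.alphas_ = alphas
        self.alpha_ = float(alphas[chosen])
        self.coef_ = full_coefs[:, chosen]
        self.support_ = self.coef_ != 0
        return self


class CoxRiskModel(BaseEstimator):
    """Multivariate Cox risk model with drop-and-refit signature pruning.

    ``fit`` runs a joint proportional-hazards fit on the supplied
    features, drops covariates with Wald p > ``drop_p`` and refits once;
    the final signature is the refit subset with p < ``keep_p``, and the
    model is refit a last time on that signature so its coefficients are
    the reported risk-score weights.  ``predict`` returns risk scores
    R(i) = sum_j beta_j * e_ij; ``predict_level`` dichotomizes at the
    training-median cutoff (ties go to "high").
    """

    def __init__(self, drop_p: float = 0.8, keep_p: float = 0.05, ties: str = "efron"):
        self.drop_p = drop_p
        self.keep_p = keep_p
        self.ties = ties

    @classmethod
    def from_coefficients(cls, coefficients: dict, cutoff: float = np.nan) -> "CoxRiskModel":
        """Build an already-fitted scorer from published coefficients."""
        model = cls()
        model.coef_ = pd.Series(coefficients, dtype=float)
        model.signature_ = list(model.coef_.index)
        model.feature_names_in_ = np.asarray(model.signature_)
        model.n_features_in_ = len(model.signature_)
        model.cutoff_ = cutoff
        model.dropped_ = []
        return model

    @staticmethod
    def _check_collinear(X: pd.DataFrame):
        x = X.to_numpy(dtype=float)
        sd = x.std(axis=0)
        varying = sd > 0
        if varying.sum() >= 2:
            sub = x[:, varying]
            r = np.corrcoef(sub.T)
            names = X.columns[varying]
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if abs(r[i, j]) > 1 - 1e-10:
                        raise ValueError(
                            f"collinear duplicate features: {names[i]} and {names[j]}"
                        )

    def _fit_cph(self, X: pd.DataFrame, time, event) -> CoxPHFitter:
        df = X.copy()
        df["_time"] = time
        df["_event"] = event.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        return cph

    def fit(self, X, y):
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        time, event = check_survival_y(y)
        if X.shape[1] < 1:
            raise ValueError("need at least one feature")
        self._check_collinear(X)

        first = self._fit_cph(X, time, event)
        keep = first.summary.index[first.summary["p"] <= self.drop_p].tolist()
        self.dropped_ = [c for c in X.columns if c not in keep]
        if keep:
            refit = self._fit_cph(X[keep], time, event) if self.dropped_ else first
            self.summary_ = refit.summary[
                ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "z", "p"]
            ].rename(
                columns={
                    "exp(coef)": "HR",
                    "exp(coef) lower 95%": "ci_low",
                    "exp(coef) upper 95%": "ci_high",
                }
            )
            sig = self.summary_.index[self.summary_["p"] < self.keep_p].tolist()
        else:
            self.summary_ = pd.DataFrame(
                columns=["coef", "HR", "ci_low", "ci_high", "z", "p"]
            )
            sig = []
        self.signature_ = sig
        if sig:
            final = self._fit_cph(X[sig], time, event) if set(sig) != set(keep) else refit
            self.coef_ = final.summary.loc[sig, "coef"]
            self.signature_summary_ = final.summary[
                ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "z", "p"]
            ].rename(
                columns={
                    "exp(coef)": "HR",
                    "exp(coef) lower 95%": "ci_low",
                    "exp(coef) upper 95%": "ci_high",
                }
            )
            scores = self.predict(X)
            self.cutoff_ = float(np.median(scores))
        else:
            self.coef_ = pd.Series(dtype=float)
            self.signature_summary_ = self.summary_.iloc[:0]
            self.cutoff_ = np.nan
        return self

    def predict(self, X) -> pd.Series:
        X = _as_frame(X)
        missing = [f for f in self.coef_.index if f not in X.columns]
        if missing:
            raise ValueError(f"expression matrix lacks model features: {missing}")
        if self.coef_.empty:
            return pd.Series(0.0, index=X.index, name="risk_score")
        scores = X[self.coef_.index].to_numpy(dtype=float) @ self.coef_.to_numpy()
        return pd.Series(scores, index=X.index, name="risk_score")

    def predict_level(self, X, cutoff: float | None = None) -> pd.Series:
        scores = self.predict(X)
        cut = self.cutoff_ if cutoff is None else cutoff
        levels = np.where(scores >= cut, "high", "low")
        return pd.Series(levels, index=scores.index, name="risk_level")
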