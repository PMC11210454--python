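"""Propensity-score case-control matching with greedy 1:k nearest neighbors.

The propensity score is the fitted probability of case status from a
main-effects logistic regression on the matching covariates. Controls are
assigned to cases greedily, without replacement, processing cases in
descending score order (ties broken by input order); an optional caliper
bounds the acceptable score distance. Balance is reported as standardized
mean differences (SMD) per covariate before and after matching:

    SMD = (mean_case - mean_control) / sqrt((var_case + var_control) / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

_EPS = 1e-9


@dataclass
class MatchResult:
    """Scores, matched pairs, unmatched ids and covariate balance."""

    propensity: pd.Series
    pairs: pd.DataFrame              # columns: case_id, control_id, distance
    unmatched: list = field(default_factory=list)
    balance: pd.DataFrame | None = None
    dropped: list = field(default_factory=list)  # samples without complete covariates


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categoricals; drop constant columns with a warning."""
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    const = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if const:
        warnings.warn(f"dropping constant covariate column(s): {const}", UserWarning)
        X = X.drop(columns=const)
    return X.astype(float)


def fit_propensity(covariates: pd.DataFrame, group: pd.Series) -> pd.Series:
    """Fitted case-probabilities from a main-effects logistic model.

    Samples with any missing covariate are dropped with a warning (no
    imputation). On (quasi-)separation the unpenalized fit is replaced by a
    ridge-penalized one so scores stay strictly inside (0, 1).
    """
    covariates = pd.DataFrame(covariates)
    group = pd.Series(group).reindex(covariates.index)
    complete = covariates.notna().all(axis=1) & group.notna()
    if not complete.all():
        warnings.warn(
            f"dropping sample(s) with missing covariates from matching: "
            f"{list(covariates.index[~complete])}",
            UserWarning,
        )
    covariates, group = covariates[complete], group[complete]
    y = (group == "case").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be non-empty to fit a propensity model")
    X = _design_matrix(covariates)
    if X.shape[1] == 0:
        # intercept-only model: every score is the case prevalence
        return pd.Series(y.mean(), index=covariates.index, name="propensity")

    Xv = X.to_numpy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        model.fit(Xv, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    probs = model.predict_proba(Xv)[:, 1]
    # the MLE does not exist when the fitted score perfectly separates the
    # classes (or the optimizer gave up / drove probabilities to the boundary)
    separated = probs[y == 1].min() > probs[y == 0].max() or (
        (probs < _EPS) | (probs > 1 - _EPS)
    ).any()
    if separated or not converged:
        warnings.warn(
            "(quasi-)separation in propensity model; falling back to ridge-penalized fit",
            UserWarning,
        )
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
        model.fit(Xv, y)
        probs = model.predict_proba(Xv)[:, 1]
    return pd.Series(probs, index=covariates.index, name="propensity")


def knn_match(
    scores: pd.Series,
    group: pd.Series,
    k: int = 1,
    caliper: float | None = None,
    logit_distance: bool = False,
    order: str = "descending",
) -> MatchResult:
    """Greedy 1:k nearest-neighbor matching on propensity, without replacement.

    Cases are processed in ``order`` of their score (default descending) and
    each claims its ``k`` nearest unused controls by absolute score distance
    (on the probability scale, or the logit scale with
    ``logit_distance=True``). A control never appears in more than one pair.
    Cases with no admissible control left are recorded unmatched.
    """
    scores = pd.Series(scores).astype(float)
    group = pd.Series(group).reindex(scores.index)
    if scores.isna().any() or not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    metric = scores
    if logit_distance:
        clipped = scores.clip(_EPS, 1 - _EPS)
        metric = np.log(clipped / (1 - clipped))
    case_ids = list(scores.index[group == "case"])
    ctrl_ids = list(scores.index[group == "control"])
    ascending = order == "ascending"
    # stable sort keeps input order on ties
    case_ids = sorted(case_ids, key=lambda s: (-scores[s] if not ascending else scores[s]))

    available = list(ctrl_ids)
    pairs, unmatched = [], []
    for cid in case_ids:
        got = 0
        for _ in range(k):
            if not available:
                break
            dists = [(abs(metric[cid] - metric[c]), i) for i, c in enumerate(available)]
            d, i = min(dists)
            if caliper is not None and d > caliper:
                break
            pairs.append({"case_id": cid, "control_id": available.pop(i), "distance": d})
            got += 1
        if got == 0:
            unmatched.append(cid)
    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "distance"])
    return MatchResult(propensity=scores, pairs=pairs_df, unmatched=unmatched)


def balance_diagnostics(
    covariates: pd.DataFrame,
    group: pd.Series,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Standardized mean differences before and (optionally) after matching.

    Categorical covariates are one-hot encoded (each level becomes a
    proportion). Zero pooled variance yields SMD 0 when the group means are
    equal and a non-evaluable NaN otherwise.
    """
    X = pd.get_dummies(pd.DataFrame(covariates), dtype=float)
    group = pd.Series(group).reindex(X.index)

    def smd(frame: pd.DataFrame, labels: pd.Series) -> pd.Series:
        case = frame[labels == "case"]
        ctrl = frame[labels == "control"]
        diff = case.mean() - ctrl.mean()
        pooled = np.sqrt((case.var(ddof=1) + ctrl.var(ddof=1)) / 2.0)
        out = diff / pooled
        out[(pooled == 0) & (diff == 0)] = 0.0
        out[(pooled == 0) & (diff != 0)] = np.nan
        return out

    result = pd.DataFrame({"smd_pre": smd(X, group)})
    if pairs is not None and len(pairs):
        matched = list(pairs["case_id"]) + list(pairs["control_id"])
        result["smd_post"] = smd(X.loc[matched], group.loc[matched])
    result.index.name = "covariate"
    return result


class PropensityMatcher(BaseEstimator):
    """Estimator-style propensity matching: ``fit(X, y)`` on a covariate
    DataFrame and case/control labels populates ``propensity_``, ``pairs_``,
    ``unmatched_`` and ``balance_``."""

    def __init__(self, k: int = 1, caliper: float | None = None,
                 logit_distance: bool = False, order: str = "descending"):
        self.k = k
        self.caliper = caliper
        self.logit_distance = logit_distance
        self.order = order

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index)
        scores = fit_propensity(X, y)
        res = knn_match(
            scores, y.loc[scores.index], k=self.k, caliper=self.caliper,
            logit_distance=self.logit_distance, order=self.order,
        )
        res.balance = balance_diagnostics(X.loc[scores.index], y.loc[scores.index], res.pairs)
        res.dropped = [s for s in X.index if s not in scores.index]
        self.propensity_ = res.propensity
        self.pairs_ = res.pairs
        self.unmatched_ = res.unmatched
        self.balance_ = res.balance
        self.result_ = res
        self.n_features_in_ = X.shape[1]
        return self


def match_cohort(covariates: pd.DataFrame, group: pd.Series, k: int = 1,
                 caliper: float | None = None, logit_distance: bool = False) -> MatchResult:
    """One-call propensity fit + greedy matching + balance table."""
    m = PropensityMatcher(k=k, caliper=caliper, logit_distance=logit_distance).fit(covariates, group)
    return m.result_
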