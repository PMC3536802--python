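"""Marker-combination selection: multivariate logistic regression scored by
leave-one-out cross-validation (LOOCV) over all candidate subsets.

Each candidate marker contributes one feature per sample — its log2
expression relative to the reference gene (−ΔCt).  For every non-empty
subset up to ``max_size`` a logistic model is fit by iteratively reweighted
least squares, each sample's held-out probability is computed by refitting
without it, and subsets are ranked by the AUC of those held-out scores
(cross-validated deviance available as an alternative criterion).  Ties are
broken toward fewer markers, then lexicographically — the parsimonious panel
wins when discrimination is equal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .diagnostics import roc_curve

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: |log-odds| beyond which a fitted probability is within 1e-6 of 0/1
_SEP_LOGIT = -np.log(1e-6)


class ComboSelectError(ValueError):
    pass


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit for one marker set."""

    marker_set: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one slope per marker
    converged: bool
    n_iterations: int
    log_likelihood: float
    separation_flag: bool
    standard_errors: np.ndarray | None = None
    #: log-likelihood after each IRLS iteration (monotone non-decreasing)
    ll_history: tuple[float, ...] = ()

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coefficients[0] + X @ self.coefficients[1:]
        return _sigmoid(eta)


@dataclass(frozen=True)
class ComboResult:
    marker_set: tuple[str, ...]
    loocv_auc: float
    apparent_auc: float
    rank: int = 0
    loocv_deviance: float = np.nan


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1+e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise ComboSelectError("labels must be 1-D and aligned with features")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ComboSelectError("labels must be binary 0/1")
    if len(set(np.unique(y))) < 2:
        raise ComboSelectError("both classes must be present")
    if np.isnan(X).any():
        raise ComboSelectError("features contain missing values")
    return X, y


def fit_logistic(features, labels, marker_set: tuple[str, ...] = ()) -> LogisticFit:
    """Logistic regression by IRLS (Newton with step-halving).

    Converges when the max absolute coefficient change falls below 1e-8,
    within 100 iterations.  Quasi-complete separation — fitted probabilities
    within 1e-6 of their labels while coefficients diverge — is detected and
    flagged rather than left to iterate silently.
    """
    X, y = _check_xy(features, labels)
    n, p = X.shape
    Xd = np.c_[np.ones(n), X]
    beta = np.zeros(p + 1)
    eta = Xd @ beta
    ll = _log_likelihood(y, eta)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        # ridge epsilon keeps the weighted normal equations solvable as w -> 0
        H = Xd.T @ (Xd * w[:, None]) + 1e-12 * np.eye(p + 1)
        g = Xd.T @ (y - mu)
        step = np.linalg.solve(H, g)
        # step-halving preserves monotone log-likelihood
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_eta = Xd @ new_beta
            new_ll = _log_likelihood(y, new_eta)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        delta = np.max(np.abs(new_beta - beta))
        beta, eta, ll = new_beta, new_eta, new_ll
        history.append(ll)
        if delta < IRLS_TOL:
            converged = True
            break
    abs_eta = np.abs(eta)
    separated = bool(np.any(abs_eta > _SEP_LOGIT)
                     and (not converged or np.max(np.abs(beta)) > _SEP_LOGIT))
    se = None
    if converged and not separated:
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
        se = np.sqrt(np.diag(cov))
    return LogisticFit(marker_set=tuple(marker_set), coefficients=beta,
                       converged=converged, n_iterations=it,
                       log_likelihood=ll, separation_flag=separated,
                       standard_errors=se, ll_history=tuple(history))


def loocv_scores(features, labels, marker_set: tuple[str, ...] = ()
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out predicted probability for each sample under LOOCV.

    Sample i is scored by a model refit on all other samples.  If a fold's
    training labels are single-class (possible only when one class has a
    single member), that sample's score is the training-class prevalence and
    its flag is set.  Fully deterministic.
    """
    X, y = _check_xy(features, labels)
    n = len(y)
    if n < 4:
        raise ComboSelectError("LOOCV needs at least 4 samples")
    scores = np.empty(n)
    flagged = np.zeros(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            scores[i] = float(y_tr.mean())
            flagged[i] = True
        else:
            fit = fit_logistic(X[mask], y_tr, marker_set)
            scores[i] = float(fit.predict_proba(X[i:i + 1])[0])
        mask[i] = True
    return scores, flagged


def _loocv_deviance(y: np.ndarray, scores: np.ndarray) -> float:
    p = np.clip(scores, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def select_best_combination(candidate_markers, features, labels,
                            max_size: int | None = None,
                            criterion: str = "loocv_auc") -> list[ComboResult]:
    """Exhaustively rank all non-empty marker subsets up to ``max_size``.

    ``features`` is a DataFrame (or mapping) with one column per candidate
    marker.  Ranking: higher LOOCV AUC first (or lower cross-validated
    deviance with ``criterion="deviance"``); ties broken by fewer markers,
    then lexicographic marker names.
    """
    markers = list(candidate_markers)
    if not markers:
        raise ComboSelectError("candidate set must be non-empty")
    F = pd.DataFrame(features)
    missing = [m for m in markers if m not in F.columns]
    if missing:
        raise ComboSelectError(f"features missing candidate markers: {missing}")
    if max_size is None:
        max_size = len(markers)
    if max_size > len(markers):
        raise ComboSelectError("max_size exceeds the number of candidates")
    if criterion not in ("loocv_auc", "deviance"):
        raise ComboSelectError(f"unknown selection criterion {criterion!r}")
    y = np.asarray(labels, dtype=float)
    results: list[ComboResult] = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(sorted(markers), size):
            X = F.loc[:, list(subset)].to_numpy(dtype=float)
            cv, _ = loocv_scores(X, y, subset)
            cv_auc = roc_curve(cv, y).auc
            apparent = roc_curve(fit_logistic(X, y, subset).predict_proba(X), y).auc
            results.append(ComboResult(marker_set=subset, loocv_auc=cv_auc,
                                       apparent_auc=apparent,
                                       loocv_deviance=_loocv_deviance(y, cv)))
    if criterion == "loocv_auc":
        keyfun = lambda r: (-r.loocv_auc, len(r.marker_set), r.marker_set)
    else:
        keyfun = lambda r: (r.loocv_deviance, len(r.marker_set), r.marker_set)
    ranked = sorted(results, key=keyfun)
    return [ComboResult(marker_set=r.marker_set, loocv_auc=r.loocv_auc,
                        apparent_auc=r.apparent_auc, rank=i + 1,
                        loocv_deviance=r.loocv_deviance)
            for i, r in enumerate(ranked)]


def combo_frame(results: list[ComboResult]) -> pd.DataFrame:
    """Ranked combinations as a DataFrame (``rank,markers,loocv_auc,apparent_auc``)."""
    return pd.DataFrame(
        [{"rank": r.rank, "markers": "+".join(r.marker_set),
          "loocv_auc": r.loocv_auc, "apparent_auc": r.apparent_auc} for r in results]
    )


class LogisticCombinationSelector(BaseEstimator, ClassifierMixin):
    """Select the best logistic marker combination by LOOCV.

    Fit on a feature table whose columns are candidate markers (log2
    expression, i.e. −ΔCt) and a binary case/control label vector; the
    estimator enumerates all subsets up to ``max_size``, ranks them by
    cross-validated AUC, and exposes the winning model for prediction.

    Attributes
    ----------
    results_ : list of ComboResult
        Full ranking of every evaluated subset.
    best_markers_ : tuple of str
        Marker set of the top-ranked combination.
    best_fit_ : LogisticFit
        Final model refit on all samples with the winning markers.
    ranking_ : DataFrame
        ``rank, markers, loocv_auc, apparent_auc``.
    """

    def __init__(self, candidates: list[str] | None = None,
                 max_size: int | None = None, criterion: str = "loocv_auc"):
        self.candidates = candidates
        self.max_size = max_size
        self.criterion = criterion

    def fit(self, X, y):
        F = pd.DataFrame(X)
        markers = self.candidates if self.candidates is not None else list(F.columns)
        self.results_ = select_best_combination(markers, F, y,
                                                max_size=self.max_size,
                                                criterion=self.criterion)
        self.best_markers_ = self.results_[0].marker_set
        Xb = F.loc[:, list(self.best_markers_)].to_numpy(dtype=float)
        self.best_fit_ = fit_logistic(Xb, np.asarray(y, dtype=float),
                                      self.best_markers_)
        self.ranking_ = combo_frame(self.results_)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "best_fit_")
        F = pd.DataFrame(X)
        p = self.best_fit_.predict_proba(
            F.loc[:, list(self.best_markers_)].to_numpy(dtype=float))
        return np.c_[1 - p, p]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
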