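"""ROC analysis and diagnostic-test evaluation.

Builds empirical ROC curves over all distinct score thresholds (predicted
positive when score >= threshold, ties grouped), computes the trapezoidal
AUC with Hanley-McNeil or DeLong 95% confidence intervals, finds the optimal
cutoff (Youden index J = sensitivity + specificity - 1, or
closest-to-top-left), and evaluates the resulting 2x2 classification table:
sensitivity, specificity, PPV, NPV with exact Clopper-Pearson (or Wilson)
intervals and the odds ratio with a Woolf log-normal interval
(Haldane-Anscombe +0.5 on all cells when any cell is zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.proportion import proportion_confint

Z95 = stats.norm.ppf(0.975)


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve.

    ``thresholds`` are the distinct score values in decreasing order with a
    leading +inf (the predict-nobody-positive vertex); ``tpr``/``fpr`` are
    the corresponding sensitivity and 1-specificity, running from (0,0) to
    (1,1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    higher_is_positive: bool = True
    auc_ci: tuple[float, float] | None = None

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.tpr.tolist(), self.fpr.tolist()))


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("confusion counts must be non-negative")
        if self.total == 0:
            raise DiagnosticsError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticReport:
    """Diagnostic metrics at one cutoff, each with a 95% CI."""

    cutoff: float | None
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    youden_j: float
    confusion: ConfusionTable | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "odds_ratio": self.odds_ratio, "odds_ratio_ci": list(self.odds_ratio_ci),
            "youden_j": self.youden_j,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
        }
        if self.confusion is not None:
            d["confusion"] = {"tp": self.confusion.tp, "fp": self.confusion.fp,
                              "fn": self.confusion.fn, "tn": self.confusion.tn}
        if self.undefined:
            d["undefined"] = list(self.undefined)
        return d


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DiagnosticsError("scores and labels must be 1-D of equal length")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise DiagnosticsError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if uniq != {0, 1}:
        raise DiagnosticsError("both classes must be present")
    return s, y.astype(int)


def roc_curve(scores, labels, higher_is_positive: bool = True) -> RocCurve:
    """Empirical ROC over all distinct thresholds (score >= t is positive).

    Tied scores are grouped into a single ROC vertex; the AUC is the
    trapezoidal area, which with this construction equals the Mann-Whitney
    U statistic (ties counted 1/2) divided by n_pos * n_neg.
    """
    s, y = _check_scores_labels(scores, labels)
    if not higher_is_positive:
        s = -s
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    # group ties: last index of each run of equal scores
    distinct_mask = np.r_[np.diff(s_sorted) != 0, True]
    tp_cum = np.cumsum(y_sorted)[distinct_mask]
    fp_cum = np.cumsum(1 - y_sorted)[distinct_mask]
    thresholds = np.r_[np.inf, s_sorted[distinct_mask]]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    if not higher_is_positive:
        thresholds = np.r_[np.inf, -s_sorted[distinct_mask]]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    n_pos=n_pos, n_neg=n_neg, higher_is_positive=higher_is_positive)


def auc_ci(curve: RocCurve, method: str = "hanley_mcneil",
           scores=None, labels=None) -> tuple[float, float]:
    """95% confidence interval for the AUC.

    ``hanley_mcneil`` (default) uses the Q1/Q2 variance approximation from
    the curve's AUC and class sizes alone.  ``delong`` needs the raw scores
    and labels and uses the placement-value (structural-components)
    covariance estimator.
    """
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise DiagnosticsError("need at least 2 samples per class for an AUC CI")
    a = curve.auc
    if method == "hanley_mcneil":
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (curve.n_pos - 1) * (q1 - a * a)
               + (curve.n_neg - 1) * (q2 - a * a)) / (curve.n_pos * curve.n_neg)
        se = math.sqrt(max(var, 0.0))
    elif method == "delong":
        if scores is None or labels is None:
            raise DiagnosticsError("delong CI needs the raw scores and labels")
        se = math.sqrt(max(_delong_variance(scores, labels,
                                            curve.higher_is_positive), 0.0))
    else:
        raise DiagnosticsError(f"unknown AUC CI method {method!r}")
    if se == 0.0 and (a in (0.0, 1.0)):
        warnings.warn("degenerate AUC with zero variance estimate; CI clipped")
    lo = float(max(0.0, a - Z95 * se))
    hi = float(min(1.0, a + Z95 * se))
    return lo, hi


def _delong_variance(scores, labels, higher_is_positive: bool = True) -> float:
    s, y = _check_scores_labels(scores, labels)
    if not higher_is_positive:
        s = -s
    x = s[y == 1]
    z = s[y == 0]
    m, n = len(x), len(z)
    # placement values via midranks
    psi = (x[:, None] > z[None, :]).astype(float) + 0.5 * (x[:, None] == z[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def optimal_cutoff(curve: RocCurve, method: str = "youden"
                   ) -> tuple[float, float, float]:
    """Optimal (cutoff, sensitivity, specificity) from a ROC curve.

    ``youden`` maximizes J = sensitivity + specificity - 1;
    ``closest_topleft`` minimizes (1-sens)^2 + (1-spec)^2.  Ties are broken
    toward higher specificity.  The reported cutoff is the midpoint between
    the optimal threshold score and the next lower distinct score, so any
    implementation thresholding with >= reproduces the same table.
    """
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    if method == "youden":
        objective = sens + spec - 1.0
        best_val = objective.max()
        candidates = np.flatnonzero(np.isclose(objective, best_val))
    elif method == "closest_topleft":
        objective = (1 - sens) ** 2 + (1 - spec) ** 2
        best_val = objective.min()
        candidates = np.flatnonzero(np.isclose(objective, best_val))
    else:
        raise DiagnosticsError(f"unknown cutoff method {method!r}")
    # tie-break toward higher specificity (earlier vertex on the curve)
    k = int(candidates[np.argmax(spec[candidates])])
    if method == "youden" and np.isclose(best_val, 0.0) and len(np.unique(
            curve.thresholds[np.isfinite(curve.thresholds)])) == 1:
        warnings.warn("all scores identical; Youden J = 0 and the cutoff is degenerate")
    thresholds = curve.thresholds
    if k == 0:
        # optimum is "call nobody positive": cutoff just above the max score
        cutoff = float(thresholds[1]) + 1.0 if len(thresholds) > 1 else math.inf
    else:
        t = thresholds[k]
        cutoff = float((t + thresholds[k + 1]) / 2.0) if k + 1 < len(thresholds) else float(t)
    return cutoff, float(sens[k]), float(spec[k])


def confusion_at(scores, labels, cutoff: float,
                 higher_is_positive: bool = True) -> ConfusionTable:
    """2x2 classification table with predicted-positive = (score >= cutoff)
    (or <= when ``higher_is_positive`` is False)."""
    s, y = _check_scores_labels(scores, labels)
    pred = s >= cutoff if higher_is_positive else s <= cutoff
    return ConfusionTable(tp=int(np.sum(pred & (y == 1))),
                          fp=int(np.sum(pred & (y == 0))),
                          fn=int(np.sum(~pred & (y == 1))),
                          tn=int(np.sum(~pred & (y == 0))))


def _proportion_ci(count: int, nobs: int, method: str) -> tuple[float, float]:
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=sm_method)
    return float(lo), float(hi)


def diagnostic_metrics(t: ConfusionTable, cutoff: float | None = None,
                       ci_method: str = "clopper_pearson") -> DiagnosticReport:
    """Standard diagnostic metrics for a 2x2 table, each with a 95% CI.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn).  Proportion CIs are exact Clopper-Pearson by default
    (Wilson by flag).  The odds ratio (tp*tn)/(fp*fn) gets a Woolf
    log-normal CI; when any cell is zero all cells get the Haldane-Anscombe
    +0.5 correction first.  A metric with a zero denominator is reported as
    NaN and listed in ``undefined``.
    """
    if ci_method not in ("clopper_pearson", "wilson"):
        raise DiagnosticsError(f"unknown proportion CI method {ci_method!r}")
    undefined: list[str] = []

    def prop(count: int, nobs: int, name: str) -> tuple[float, tuple[float, float]]:
        if nobs == 0:
            undefined.append(name)
            return math.nan, (math.nan, math.nan)
        return count / nobs, _proportion_ci(count, nobs, ci_method)

    sens, sens_ci = prop(t.tp, t.tp + t.fn, "sensitivity")
    spec, spec_ci = prop(t.tn, t.tn + t.fp, "specificity")
    ppv, ppv_ci = prop(t.tp, t.tp + t.fp, "ppv")
    npv, npv_ci = prop(t.tn, t.tn + t.fn, "npv")

    cells = [t.tp, t.fp, t.fn, t.tn]
    if min(cells) == 0:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    odds = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    or_ci = (odds * math.exp(-Z95 * se_log), odds * math.exp(Z95 * se_log))

    j = sens + spec - 1.0 if not (math.isnan(sens) or math.isnan(spec)) else math.nan
    return DiagnosticReport(cutoff=cutoff,
                            sensitivity=sens, sensitivity_ci=sens_ci,
                            specificity=spec, specificity_ci=spec_ci,
                            ppv=ppv, ppv_ci=ppv_ci, npv=npv, npv_ci=npv_ci,
                            odds_ratio=odds, odds_ratio_ci=or_ci,
                            youden_j=j, confusion=t,
                            undefined=tuple(undefined))


def evaluate_scores(scores, labels, cutoff: float | None = None,
                    cutoff_method: str = "youden",
                    auc_ci_method: str = "hanley_mcneil",
                    ci_method: str = "clopper_pearson",
                    higher_is_positive: bool = True) -> DiagnosticReport:
    """Full score-vs-label evaluation: ROC + AUC CI + cutoff + 2x2 metrics.

    When ``cutoff`` is None the optimal cutoff is found on these data;
    passing a frozen cutoff applies it without refitting (blind validation).
    """
    curve = roc_curve(scores, labels, higher_is_positive=higher_is_positive)
    ci = auc_ci(curve, method=auc_ci_method, scores=scores, labels=labels)
    if cutoff is None:
        cutoff, _, _ = optimal_cutoff(curve, method=cutoff_method)
    table = confusion_at(scores, labels, cutoff, higher_is_positive=higher_is_positive)
    report = diagnostic_metrics(table, cutoff=cutoff, ci_method=ci_method)
    return DiagnosticReport(**{**report.__dict__, "auc": curve.auc, "auc_ci": ci})


def plot_roc(curve: RocCurve, path=None, label: str | None = None):
    """Basic ROC plot with the AUC annotated; saves to ``path`` if given.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    name = label or "score"
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post",
            label=f"{name} (AUC = {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


class CutoffClassifier(BaseEstimator, ClassifierMixin):
    """Threshold a single diagnostic score at the ROC-optimal cutoff.

    Parameters
    ----------
    method : {"youden", "closest_topleft"}
        Optimal-cutoff criterion.
    higher_is_positive : bool
        Orientation of the score.

    Attributes
    ----------
    cutoff_ : float
        Fitted decision threshold (adjacent-score midpoint).
    curve_ : RocCurve
        ROC curve on the training scores.
    report_ : DiagnosticReport
        Apparent (training-set) diagnostic metrics at ``cutoff_``.
    """

    def __init__(self, method: str = "youden", higher_is_positive: bool = True,
                 auc_ci_method: str = "hanley_mcneil"):
        self.method = method
        self.higher_is_positive = higher_is_positive
        self.auc_ci_method = auc_ci_method

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DiagnosticsError("CutoffClassifier takes a single score column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        s = self._scores(X)
        self.curve_ = roc_curve(s, y, higher_is_positive=self.higher_is_positive)
        self.cutoff_, self.sensitivity_, self.specificity_ = optimal_cutoff(
            self.curve_, method=self.method)
        self.report_ = evaluate_scores(s, y, cutoff=self.cutoff_,
                                       auc_ci_method=self.auc_ci_method,
                                       higher_is_positive=self.higher_is_positive)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        s = self._scores(X)
        return s - self.cutoff_ if self.higher_is_positive else self.cutoff_ - s

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)
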