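"""Evaluation battery: regression and classification metrics, subset
statistics, the paired consistency t-test and residual-interval summaries.

Regression quality is reported as R^2, RMSE (target units), relative RMSE
(rRMSE = 100*RMSE/mean, %) and residual predictive deviation
(RPD = sd/RMSE, sample sd).  Conventional reading: R^2 > 0.9, rRMSE < 5%
and RPD > 3 indicate a model fit for quantitative work.  Classification is
summarized by accuracy, macro precision/recall, macro F1 and
class-count-weighted F1, all in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    rrmse: float        # percent of the reference mean
    rpd: float          # sd(reference)/RMSE; inf when RMSE is 0
    residuals: np.ndarray

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "rrmse": self.rrmse,
                "rpd": self.rpd}


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float    # macro average, percent
    recall: float
    macro_f1: float
    weighted_f1: float
    confusion: np.ndarray
    classes: tuple
    degenerate_classes: tuple = ()   # classes absent from the references

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "macro_f1": self.macro_f1,
                "weighted_f1": self.weighted_f1}


@dataclass
class SubsetStats:
    n: int
    mean: float
    max: float
    min: float
    sd: float
    cv: float           # percent, 100*sd/mean

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def regression_metrics(y_ref: np.ndarray, y_pred: np.ndarray
                       ) -> RegressionMetrics:
    """R^2, RMSE, rRMSE and RPD of predictions against references."""
    y_ref = np.asarray(y_ref, float)
    y_pred = np.asarray(y_pred, float)
    if y_ref.shape != y_pred.shape or y_ref.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    resid = y_pred - y_ref
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mean = float(y_ref.mean())
    if mean == 0:
        raise ValueError("zero reference mean: rRMSE undefined")
    sd = float(y_ref.std(ddof=1))
    if sd == 0:
        raise ValueError("zero reference variance: RPD undefined")
    return RegressionMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        rrmse=100.0 * rmse / mean,
        rpd=sd / rmse if rmse > 0 else float("inf"),
        residuals=resid,
    )


def classification_metrics(labels_ref, labels_pred, classes=None
                           ) -> ClassificationMetrics:
    """Accuracy, macro precision/recall, macro and weighted F1 (percent).

    Per-class precision/recall use the 0-convention for empty denominators;
    classes predicted but absent from the references are flagged.
    """
    ref = np.asarray(labels_ref, dtype=object)
    pred = np.asarray(labels_pred, dtype=object)
    if ref.size == 0 or ref.shape != pred.shape:
        raise ValueError("need two equal-length nonempty label vectors")
    if classes is None:
        classes = sorted(set(ref) | set(pred))
    classes = tuple(classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        ref, pred, labels=list(classes), zero_division=0)
    weights = support / support.sum()
    return ClassificationMetrics(
        accuracy=100.0 * float(np.mean(ref == pred)),
        precision=100.0 * float(prec.mean()),
        recall=100.0 * float(rec.mean()),
        macro_f1=100.0 * float(f1.mean()),
        weighted_f1=100.0 * float(f1 @ weights),
        confusion=confusion_matrix(ref, pred, labels=list(classes)),
        classes=classes,
        degenerate_classes=tuple(c for c, s in zip(classes, support)
                                 if s == 0),
    )


def subset_stats(y: np.ndarray) -> SubsetStats:
    """Descriptive statistics with the coefficient of variation in percent."""
    y = np.asarray(y, float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(y.mean())
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    sd = float(y.std(ddof=1))
    return SubsetStats(n=int(y.size), mean=mean, max=float(y.max()),
                       min=float(y.min()), sd=sd, cv=100.0 * sd / mean)


def paired_consistency_ttest(y_ref, y_pred, alpha: float = 0.05
                             ) -> tuple[bool, float, float, float]:
    """Two-sided paired t-test of measured vs predicted values.

    Returns ``(reject, p_value, t_statistic, critical_value)`` where the
    critical value is the two-sided Student-t quantile at ``alpha`` with
    n-1 degrees of freedom (1.989 for n = 84 at alpha = 0.05).
    """
    y_ref = np.asarray(y_ref, float)
    y_pred = np.asarray(y_pred, float)
    if y_ref.shape != y_pred.shape or y_ref.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = y_pred - y_ref
    if diff.std(ddof=1) == 0:
        raise ValueError("zero-variance differences")
    t_stat, p_value = stats.ttest_rel(y_pred, y_ref)
    critical = float(stats.t.ppf(1.0 - alpha / 2.0, y_ref.size - 1))
    return bool(p_value < alpha), float(p_value), float(t_stat), critical


def residual_interval(residuals, threshold: float
                      ) -> tuple[float, float, float]:
    """Extreme residuals and the percentage within +/- threshold."""
    r = np.asarray(residuals, float)
    if r.size == 0:
        raise ValueError("empty residual vector")
    within = 100.0 * float(np.mean(np.abs(r) <= threshold))
    return float(r.min()), float(r.max()), within
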