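"""Frailty-model scoring and bootstrap-validated performance.

Given a feature subset, the model is refitted on every bootstrap training
set and scored on the paired out-of-bag validation set; AUC, sensitivity,
specificity and accuracy ``(TP+TN)/(TP+TN+FP+FN)`` are summarised as mean
and 95% confidence interval over the ``B`` validation sets, reported in
percent.

The module also ships the published three-feature logistic frailty scorer

    logit p = 2.722 - 0.022*ph1 + 0.243*ph2 + 0.055*ph3

where ``ph1`` is the mean hip angular velocity range (slowness indicator),
``ph2`` the mean vertical power range (weakness) and ``ph3`` the CV of the
vertical power range (exhaustion).  The source prints the coefficients
without units; this implementation assumes deg/s for ph1, W for ph2 and
percent for ph3, with multiplicative converters exposed for other unit
choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .selection import BootstrapSplit, LogisticModel, fit_logistic

__all__ = [
    "PUBLISHED_MODEL",
    "ConfusionCounts",
    "MetricSummary",
    "ModelPerformance",
    "predict_prob",
    "roc_auc",
    "confusion",
    "metrics",
    "bootstrap_performance",
    "published_score",
]

#: The published three-feature frailty model (fixed printed coefficients).
PUBLISHED_MODEL = LogisticModel(
    feature_names=(
        "mean_hip_angular_velocity_range",
        "mean_vertical_power_range",
        "cv_vertical_power_range",
    ),
    intercept=2.722,
    coef=np.array([-0.022, 0.243, 0.055]),
    converged=True,
    n_iter=0,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSummary:
    """Mean and 95% CI of one metric over the bootstrap validation sets, in %."""

    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ModelPerformance:
    auc: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    accuracy: MetricSummary
    ci_method: str
    B: int

    def as_dict(self) -> dict:
        return {
            name: vars(getattr(self, name))
            for name in ("auc", "sensitivity", "specificity", "accuracy")
        } | {"ci_method": self.ci_method, "B": self.B}


def predict_prob(model: LogisticModel, features: Mapping[str, float]) -> float:
    """Posterior frailty probability of one subject under a logistic model.

    ``features`` must contain a value for every model feature; extras are
    ignored.
    """
    try:
        x = np.array([features[name] for name in model.feature_names], float)
    except KeyError as e:
        raise KeyError(f"missing feature value for {e.args[0]!r}") from None
    return float(expit(model.intercept + x @ model.coef))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties between a positive and a negative counting 1/2.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally a confusion table, predicting frail when score >= threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as proportions.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/(TP+TN+FP+FN); a zero denominator yields NaN.
    """
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    acc = (counts.tp + counts.tn) / counts.total if counts.total else float("nan")
    return sens, spec, acc


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given data."""
    order = np.argsort(scores)
    cand = np.concatenate([[-np.inf], scores[order]])
    best_t, best_j = 0.5, -np.inf
    for t in cand:
        c = confusion(scores, labels, t)
        sens, spec, _ = metrics(c)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def bootstrap_performance(
    subset: Sequence[str],
    table: pd.DataFrame,
    splits: Sequence[BootstrapSplit],
    threshold: float | str = 0.5,
    ci: str = "percentile",
) -> ModelPerformance:
    """Bootstrap-validated performance of the model on a feature subset.

    Per split the model is refitted on the training resample and scored on
    the out-of-bag validation set.  ``threshold`` is the posterior
    probability cut for the confusion metrics (default 0.5), or
    ``"youden"`` to choose the Youden-optimal cut on each training set.
    ``ci`` selects the 95% interval across the B per-iteration values:
    ``"percentile"`` (2.5/97.5) or ``"sem"`` (mean +/- 1.96*SD/sqrt(B), the
    standard-error-of-the-mean interval).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("feature subset is empty")
    if ci not in ("percentile", "sem"):
        raise ValueError(f"unknown ci method {ci!r}")
    X = table.loc[:, subset].to_numpy(float)
    y = table["status"].to_numpy(int)

    per_iter = np.empty((len(splits), 4))
    for b, split in enumerate(splits):
        model = fit_logistic(X[split.train], y[split.train], compute_se=False)
        p_val = model.predict_proba(X[split.val])
        if threshold == "youden":
            t = _youden_threshold(
                np.asarray(model.predict_proba(X[split.train])), y[split.train]
            )
        else:
            t = float(threshold)
        sens, spec, acc = metrics(confusion(p_val, y[split.val], t))
        per_iter[b] = (roc_auc(p_val, y[split.val]), sens, spec, acc)

    summaries = []
    for col in per_iter.T:
        mean = float(np.nanmean(col))
        if ci == "percentile":
            lo, hi = np.nanpercentile(col, [2.5, 97.5])
        else:
            sem = float(np.nanstd(col, ddof=1)) / np.sqrt(len(col)) if len(col) > 1 else 0.0
            lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
        summaries.append(
            MetricSummary(100 * mean, 100 * float(lo), 100 * float(hi))
        )
    return ModelPerformance(*summaries, ci_method=ci, B=len(splits))


def published_score(
    ph1: float,
    ph2: float,
    ph3: float,
    velocity_scale: float = 1.0,
    power_scale: float = 1.0,
    cv_scale: float = 1.0,
) -> float:
    """Frailty probability from the published three-feature logistic model.

    ``ph1`` = mean hip angular velocity range (deg/s), ``ph2`` = mean
    vertical power range (W), ``ph3`` = CV of vertical power range (%).
    Inputs on other scales can be converted via the multiplicative
    ``*_scale`` factors (e.g. ``velocity_scale=180/pi`` for rad/s input).
    """
    return predict_prob(
        PUBLISHED_MODEL,
        {
            "mean_hip_angular_velocity_range": ph1 * velocity_scale,
            "mean_vertical_power_range": ph2 * power_scale,
            "cv_vertical_power_range": ph3 * cv_scale,
        },
    )
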