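"""Model evaluation: penalised-LR baseline and the repeated-CV metric suite.

The baseline classifier is an L1-penalised, class-weighted logistic
regression on individual component log(ISU+1) values.  Both the baseline and
the pairwise density-ratio model are evaluated with stratified K-fold
cross-validation repeated R times; per-participant out-of-fold probabilities
are averaged over repetitions, and the metric suite (AUC, accuracy,
sensitivity, specificity, precision, F1) is computed from the averaged
probabilities at a fixed threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._l1 import L1LogisticFit, fit_l1_logistic_cv
from .cohort_io import CRDMatrix
from . import jdinac as _jdinac

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "precision", "f_measure")


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Scalar metrics from a confusion table (precision is 0, with a warning,
    when nothing is predicted positive)."""
    n = tp + fn + tn + fp
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    if tp + fp == 0:
        logger.warning("no predicted positives; precision set to 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f_measure": f1,
    }


@dataclass
class PerformanceReport:
    """Metric suite plus the ROC curve and the evaluation protocol."""

    metrics: dict[str, float]
    roc_points: np.ndarray               # (k, 2) of (FPR, TPR), (0,0) -> (1,1)
    confusion: dict[str, int]
    probabilities: np.ndarray
    y_true: np.ndarray
    protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "confusion": self.confusion,
            "protocol": self.protocol,
        }


def performance_report(
    y: np.ndarray, prob: np.ndarray, threshold: float = 0.5, protocol: dict | None = None
) -> PerformanceReport:
    y = np.asarray(y, dtype=int)
    prob = np.asarray(prob, dtype=float)
    pred = (prob > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    metrics = confusion_metrics(tp, fn, tn, fp)
    metrics["auc"] = float(roc_auc_score(y, prob)) if len(np.unique(y)) == 2 else float("nan")
    fpr, tpr, _ = roc_curve(y, prob)
    return PerformanceReport(
        metrics=metrics,
        roc_points=np.column_stack([fpr, tpr]),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        probabilities=prob,
        y_true=y,
        protocol=protocol or {},
    )


def trapezoid_auc(roc_points: np.ndarray) -> float:
    """Area under the ROC polygon; equals the rank-statistic AUC."""
    fpr, tpr = roc_points[:, 0], roc_points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def penalised_lr_fit(
    m: CRDMatrix,
    y: np.ndarray | pd.Series,
    seed: int = 0,
    log1: bool = True,
    inner_folds: int = 5,
    n_lambdas: int = 20,
    one_se: bool = True,
) -> L1LogisticFit:
    """Class-weighted L1 logistic regression on individual component values."""
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    y = np.asarray(y, dtype=int)
    x = m.to_numpy()
    if log1:
        x = np.log1p(x)
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("design matrix has no variance")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return fit_l1_logistic_cv(
        x, y, seed=seed, n_folds=inner_folds, n_lambdas=n_lambdas, one_se=one_se
    )


def repeated_cv_evaluate(
    model_spec: dict,
    m: CRDMatrix,
    y: np.ndarray | pd.Series,
    folds: int = 10,
    repetitions: int = 50,
    seed: int = 0,
    threshold: float = 0.5,
    max_retries: int = 20,
) -> PerformanceReport:
    """Repeated stratified K-fold CV with prediction averaging.

    ``model_spec`` selects the classifier: ``{"model": "penalised_lr", ...}``
    or ``{"model": "jdinac", "n_repetitions": T, ...}`` (extra keys are
    forwarded to the fitting routine).  Per-participant out-of-fold
    probabilities are averaged over repetitions before thresholding; the AUC
    is the rank statistic over the averaged probabilities.
    """
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    y = np.asarray(y, dtype=int)
    x_raw = m.to_numpy()
    n = len(y)
    if folds < 2 or n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    spec = dict(model_spec)
    kind = spec.pop("model")
    if kind not in ("penalised_lr", "jdinac"):
        raise ValueError(f"unknown model {kind!r}")
    log1 = spec.pop("log1", True)
    x = np.log1p(x_raw) if log1 else x_raw

    rng = np.random.default_rng(seed)
    prob_sum = np.zeros(n)
    prob_count = np.zeros(n)
    for rep in range(repetitions):
        for attempt in range(max_retries):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            splits = list(skf.split(x, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                break
        else:
            raise ValueError("could not build folds containing both classes")
        for tr, te in splits:
            if kind == "penalised_lr":
                fit = fit_l1_logistic_cv(
                    x[tr], y[tr], seed=int(rng.integers(2**31)),
                    n_folds=spec.get("inner_folds", 5),
                    n_lambdas=spec.get("n_lambdas", 20),
                    one_se=spec.get("one_se", True),
                )
                prob = fit.predict_proba(x[te])
            else:
                sub = CRDMatrix(m.data.iloc[tr])
                jfit = _jdinac.jdinac_fit(
                    sub, y[tr],
                    n_repetitions=spec.get("n_repetitions", 5),
                    seed=int(rng.integers(2**31)),
                    bandwidth_rule=spec.get("bandwidth_rule", "scott"),
                    log1=log1,
                )
                prob = _jdinac.predict(jfit, CRDMatrix(m.data.iloc[te]))
            prob_sum[te] += prob
            prob_count[te] += 1
    averaged = prob_sum / prob_count
    protocol = {
        "model": kind,
        "folds": folds,
        "repetitions": repetitions,
        "seed": seed,
        "threshold": threshold,
        "averaging": "per-participant probability averaging",
        **{k: v for k, v in spec.items()},
    }
    return performance_report(y, averaged, threshold=threshold, protocol=protocol)


def compare_models(report_a: PerformanceReport, report_b: PerformanceReport,
                   name_a: str = "model_a", name_b: str = "model_b") -> pd.DataFrame:
    """Side-by-side metric table; protocols (minus model identity) must match."""
    proto_a = {k: v for k, v in report_a.protocol.items() if k not in ("model", "seed", "n_repetitions")}
    proto_b = {k: v for k, v in report_b.protocol.items() if k not in ("model", "seed", "n_repetitions")}
    if proto_a != proto_b:
        raise ValueError(f"evaluation protocols differ: {proto_a} vs {proto_b}")
    rows = {
        metric: {
            name_a: report_a.metrics[metric],
            name_b: report_b.metrics[metric],
            "delta": report_b.metrics[metric] - report_a.metrics[metric],
        }
        for metric in METRIC_NAMES
    }
    return pd.DataFrame(rows).T
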