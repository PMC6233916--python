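"""Cross-validated L1-penalised, class-weighted logistic regression.

Shared by the pairwise density-ratio classifier and the individual-component
baseline.  The penalty level is chosen by K-fold cross-validated binomial
deviance over a data-driven log-spaced grid with the one-standard-error
rule (the sparsest model within one SE of the best mean deviance), the
convention popularised by glmnet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


def inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    """Class weights proportional to inverse class frequency, mean 1 over samples."""
    y = np.asarray(y)
    n = len(y)
    weights = {}
    for cls in (0, 1):
        n_cls = int((y == cls).sum())
        if n_cls == 0:
            raise ValueError(f"class {cls} absent")
        weights[cls] = n / (2.0 * n_cls)
    return weights


def _lambda_grid(x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                 n_lambdas: int, ratio: float = 1e-3) -> np.ndarray:
    """glmnet-style grid from the smallest lambda that zeroes all coefficients."""
    n = len(y)
    w = sample_weight / sample_weight.sum()
    p_bar = float((w * y).sum())
    resid = sample_weight * (y - p_bar)
    lam_max = np.abs(x.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _deviance(y: np.ndarray, prob: np.ndarray, sample_weight: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    ll = sample_weight * (y * np.log(prob) + (1 - y) * np.log(1 - prob))
    return float(-2.0 * ll.sum() / sample_weight.sum())


@dataclass
class L1LogisticFit:
    coef: np.ndarray
    intercept: float
    lam: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray      # mean deviance per lambda
    cv_deviance_se: np.ndarray

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        eta = x @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


def fit_l1_logistic_cv(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    n_lambdas: int = 20,
    one_se: bool = True,
    class_weight: dict[int, float] | None = None,
) -> L1LogisticFit:
    """L1 logistic regression with inner-CV penalty selection.

    ``class_weight=None`` uses inverse-frequency weights normalised to mean 1.
    With ``one_se`` the strongest penalty whose mean CV deviance is within one
    standard error of the minimum is selected; otherwise the minimiser.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if class_weight is None:
        class_weight = inverse_frequency_weights(y)
    sw = np.array([class_weight[int(v)] for v in y])
    lambdas = _lambda_grid(x, y, sw, n_lambdas)

    n_folds_eff = min(n_folds, int((y == 1).sum()), int((y == 0).sum()))
    if n_folds_eff < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True,
                          random_state=seed % (2**32))
    fold_dev = np.empty((n_folds_eff, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(x, y)):
        for li, lam in enumerate(lambdas):
            model = _liblinear(lam, len(tr), class_weight)
            model.fit(x[tr], y[tr])
            prob = model.predict_proba(x[te])[:, 1]
            fold_dev[f, li] = _deviance(y[te], prob, sw[te])
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds_eff)

    best = int(mean_dev.argmin())
    if one_se:
        threshold = mean_dev[best] + se_dev[best]
        # lambdas are in decreasing order: the first index within threshold
        # is the strongest acceptable penalty
        chosen = int(np.flatnonzero(mean_dev <= threshold)[0])
    else:
        chosen = best
    lam = float(lambdas[chosen])
    final = _liblinear(lam, n, class_weight)
    final.fit(x, y)
    return L1LogisticFit(
        coef=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        lam=lam,
        lambda_grid=lambdas,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
    )


def _liblinear(lam: float, n_train: int, class_weight: dict[int, float]) -> LogisticRegression:
    # glmnet objective (1/n) sum loss + lam * ||b||_1  <=>  sklearn C = 1/(n * lam)
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n_train * lam),
        solver="liblinear",
        class_weight=class_weight,
        max_iter=200,
        tol=1e-5,
        random_state=0,  # liblinear's internal shuffling must be fixed
    )
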