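"""Single-subject genotype-risk prediction from cluster-mean centrality.

Unpenalized maximum-likelihood logistic regression (explicit IRLS with a
quasi-separation guard), leave-one-out cross-validation, ROC/AUC with
Mann-Whitney tie handling, and a stratified percentile bootstrap for the
AUC confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "LogisticFit",
    "PredictionResult",
    "fit_logistic",
    "loocv_predict",
    "roc_and_auc",
    "auc_mann_whitney",
    "bootstrap_auc_ci",
    "evaluate_model",
    "compare_models",
]

_ETA_CLIP = 30.0       # logit beyond which probabilities saturate numerically
_BETA_DIVERGED = 1e3   # standardized-coefficient magnitude treated as runaway


@dataclass
class LogisticFit:
    coef: np.ndarray            # [intercept, slopes...]
    converged: bool
    separation: bool
    n_iter: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(len(x)), np.asarray(x, dtype=np.float64)])
        return expit(np.clip(design @ self.coef, -_ETA_CLIP, _ETA_CLIP))


def _as_design(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def fit_logistic(features: np.ndarray, labels: np.ndarray,
                 max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic coefficients by IRLS.

    Features are standardized internally (constant features are dropped, so
    a constant-only model reduces to the intercept and fits the class
    prevalence); coefficients are reported on the original scale.
    Convergence is declared when the largest standardized-coefficient
    update falls below ``tol``.  Quasi-separation (coefficients running
    away while the fit saturates) stops the iteration with ``separation``
    flagged; the returned coefficients still give saturated, usable
    predictions.
    """
    y = np.asarray(labels, dtype=np.float64)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    x_raw = np.asarray(features, dtype=np.float64)
    if x_raw.ndim == 1:
        x_raw = x_raw[:, None]
    if not np.all(np.isfinite(x_raw)):
        raise ValueError("features must be finite")
    mu = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)
    keep = sd > 0
    x = np.column_stack([np.ones(len(y)), (x_raw[:, keep] - mu[keep]) / sd[keep]])

    beta = np.zeros(x.shape[1])
    converged = separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(x @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        z = eta + (y - p) / w
        xtw = x.T * w
        beta_new = np.linalg.lstsq(xtw @ x, xtw @ z, rcond=None)[0]
        if not np.all(np.isfinite(beta_new)):
            separation = True
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        # on standardized features genuine ML coefficients are O(1-10);
        # runaway magnitudes mean the likelihood is saturating
        if np.max(np.abs(beta)) > _BETA_DIVERGED:
            separation = True
            break
        if step < tol:
            converged = True
            break
    if not converged and not separation and np.max(np.abs(beta)) > 15.0:
        separation = True
    coef = np.zeros(x_raw.shape[1] + 1)
    slopes = np.zeros(x_raw.shape[1])
    slopes[keep] = beta[1:] / sd[keep]
    coef[0] = beta[0] - float(slopes[keep] @ mu[keep])
    coef[1:] = slopes
    return LogisticFit(coef=coef, converged=converged, separation=separation,
                       n_iter=it)


def log_likelihood(coef: np.ndarray, features: np.ndarray, labels: np.ndarray) -> float:
    """Bernoulli log-likelihood of a coefficient vector (for checking fits)."""
    x = _as_design(features)
    y = np.asarray(labels, dtype=np.float64)
    eta = np.clip(x @ np.asarray(coef, dtype=np.float64), -_ETA_CLIP, _ETA_CLIP)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def loocv_predict(features: np.ndarray, labels: np.ndarray,
                  max_iter: int = 100, tol: float = 1e-10
                  ) -> tuple[np.ndarray, float, list[int]]:
    """Leave-one-out predicted probabilities, accuracy at 0.5, flagged folds.

    Each subject's probability comes from a model fit on the other n-1.  A
    fold whose training labels collapse to one class falls back to an
    intercept-only model (its index is returned in the flagged list).
    """
    y = np.asarray(labels, dtype=np.float64)
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    probs = np.empty(n)
    flagged: list[int] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if len(np.unique(y_tr)) < 2:
            probs[i] = y_tr.mean()
            flagged.append(i)
            continue
        fit = fit_logistic(x[keep], y_tr, max_iter=max_iter, tol=tol)
        probs[i] = fit.predict_proba(x[i: i + 1])[0]
    accuracy = float(np.mean((probs >= 0.5) == (y == 1)))
    return probs, accuracy, flagged


def roc_and_auc(probabilities: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr) over all unique score thresholds, plus AUC.

    Trapezoidal integration over the tie-grouped curve; equal to the
    Mann-Whitney statistic (concordant pairs + half ties) / (n1 * n0).
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bootstrap_auc_ci(probabilities: np.ndarray, labels: np.ndarray,
                     n_boot: int = 2000, seed: int = 0,
                     ) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the AUC.

    Subjects are resampled with replacement within each class (class counts
    preserved, so no degenerate single-class replicate can occur); the
    2.5/97.5 percentiles of the replicate AUCs are returned.  Reproducible
    by seed.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    y = np.asarray(labels).astype(bool)
    p = np.asarray(probabilities, dtype=np.float64)
    pos, neg = p[y], p[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(len(pos), dtype=bool), np.zeros(len(neg), dtype=bool)])
    for b in range(n_boot):
        sample = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        aucs[b] = auc_mann_whitney(sample, lab)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class PredictionResult:
    """LOOCV evaluation of one predictor set."""

    predictors: list[str]
    probabilities: np.ndarray
    labels: np.ndarray
    accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    flagged_folds: list[int] = field(default_factory=list)


def evaluate_model(features: np.ndarray, labels: np.ndarray,
                   predictors: list[str], n_boot: int = 2000,
                   seed: int = 0) -> PredictionResult:
    """LOOCV + ROC/AUC + bootstrap CI for one feature matrix."""
    probs, acc, flagged = loocv_predict(features, labels)
    fpr, tpr, auc = roc_and_auc(probs, labels)
    ci = bootstrap_auc_ci(probs, labels, n_boot=n_boot, seed=seed)
    return PredictionResult(
        predictors=list(predictors),
        probabilities=probs,
        labels=np.asarray(labels),
        accuracy=acc,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        ci95=ci,
        flagged_folds=flagged,
    )


def compare_models(base: PredictionResult, augmented: PredictionResult) -> dict:
    """Side-by-side accuracy/AUC of two models on the same subjects."""
    if len(base.labels) != len(augmented.labels) or not np.array_equal(
        np.sort(base.labels), np.sort(augmented.labels)
    ):
        raise ValueError("models were evaluated on different subjects")
    return {
        "base": {"predictors": base.predictors, "accuracy": base.accuracy,
                 "auc": base.auc, "ci95": list(base.ci95)},
        "augmented": {"predictors": augmented.predictors,
                      "accuracy": augmented.accuracy, "auc": augmented.auc,
                      "ci95": list(augmented.ci95)},
        "delta_accuracy": augmented.accuracy - base.accuracy,
        "delta_auc": augmented.auc - base.auc,
    }
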