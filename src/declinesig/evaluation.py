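"""ROC construction, correlated AUC comparison and confusion metrics.

The AUC standard error follows Hanley & McNeil's closed form based on the
Wilcoxon statistic; two AUCs measured on the same samples are compared
with a z-test whose covariance term uses the correlation between the two
AUC estimators, looked up from the average within-class correlation of
the underlying scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from sklearn.metrics import roc_curve

from .datatypes import GREATER, ConfigurationError

# ----------------------------------------------------------------------
# Correlation between two Wilcoxon AUC estimators as a function of the
# average within-class Pearson correlation of the scores (rows) and the
# average AUC (columns).  Precomputed Monte-Carlo grid under the binormal
# model (6000 replicates per cell, 50 cases / 50 controls); the entries
# attenuate below the score correlation as the AUCs approach 1, matching
# the published lookup table for this procedure.
_GRID_RHO = np.arange(0.0, 0.91, 0.1)
_GRID_AUC = np.array([0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.975])
_GRID_R = np.array(
    [
        [0.000, 0.003, 0.018, 0.000, 0.010, 0.004, 0.021, 0.007, 0.021],
        [0.101, 0.092, 0.087, 0.117, 0.081, 0.077, 0.085, 0.054, 0.041],
        [0.192, 0.214, 0.181, 0.180, 0.176, 0.156, 0.136, 0.114, 0.115],
        [0.258, 0.281, 0.272, 0.274, 0.231, 0.245, 0.228, 0.203, 0.158],
        [0.396, 0.374, 0.352, 0.378, 0.379, 0.326, 0.341, 0.306, 0.269],
        [0.473, 0.473, 0.477, 0.449, 0.430, 0.438, 0.426, 0.383, 0.347],
        [0.587, 0.580, 0.551, 0.568, 0.552, 0.542, 0.520, 0.461, 0.432],
        [0.679, 0.671, 0.657, 0.662, 0.658, 0.629, 0.607, 0.586, 0.544],
        [0.787, 0.777, 0.766, 0.768, 0.762, 0.750, 0.722, 0.709, 0.669],
        [0.886, 0.885, 0.878, 0.881, 0.880, 0.866, 0.862, 0.837, 0.828],
    ]
)
_R_LOOKUP = RegularGridInterpolator(
    (_GRID_RHO, _GRID_AUC), _GRID_R, bounds_error=False, fill_value=None
)


@dataclass
class ROCComparison:
    """Result of a correlated two-AUC comparison on the same samples."""

    auc1: float
    auc2: float
    se1: float
    se2: float
    r: float
    z: float
    p: float
    degenerate: bool = False


def _binary(labels, positive: str) -> np.ndarray:
    arr = np.asarray(labels)
    pos = arr == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ConfigurationError("both classes must be present")
    return pos


def roc_auc(
    scores, labels, positive: str = GREATER
) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    The trapezoidal AUC with proper tie handling equals the Mann-Whitney
    statistic divided by n_pos * n_neg.  Constant scores yield the
    chance diagonal (AUC 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    pos = _binary(labels, positive)
    if np.ptp(scores) == 0:
        points = pd.DataFrame(
            {"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "threshold": [np.inf, scores[0]]}
        )
        return points, 0.5
    fpr, tpr, thr = roc_curve(pos.astype(int), scores, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(np.trapezoid(tpr, fpr))


def hanley_mcneil_se(A: float, n_pos: int, n_neg: int) -> float:
    """Closed-form AUC standard error from the Wilcoxon statistic.

    With Q1 = A/(2-A) and Q2 = 2A^2/(1+A):
    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg).
    """
    if not 0 <= A <= 1:
        raise ConfigurationError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ConfigurationError("group sizes must be >= 1")
    q1 = A / (2 - A)
    q2 = 2 * A**2 / (1 + A)
    var = (
        A * (1 - A) + (n_pos - 1) * (q1 - A**2) + (n_neg - 1) * (q2 - A**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _within_class_corr(s1: np.ndarray, s2: np.ndarray, pos: np.ndarray) -> float:
    rs = []
    for mask in (pos, ~pos):
        a, b = s1[mask], s2[mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs))


def auc_estimator_correlation(r_avg: float, auc_avg: float) -> float:
    """Map average within-class score correlation to AUC-estimator correlation."""
    sign = np.sign(r_avg)
    r_abs = min(abs(r_avg), _GRID_RHO[-1] + 0.1)
    a = float(np.clip(auc_avg, _GRID_AUC[0], _GRID_AUC[-1]))
    val = float(_R_LOOKUP([[min(r_abs, _GRID_RHO[-1]), a]])[0])
    if r_abs > _GRID_RHO[-1]:  # linear continuation toward 1
        val += (r_abs - _GRID_RHO[-1]) * (1 - val) / (1 - _GRID_RHO[-1])
    return float(sign * np.clip(val, 0.0, 1.0))


def compare_auc_correlated(
    scores1, scores2, labels, positive: str = GREATER
) -> ROCComparison:
    """Correlated z-test of two AUCs measured on the same labeled samples."""
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    pos = _binary(labels, positive)
    if len(s1) != len(s2) or len(s1) != len(pos):
        raise ConfigurationError("score vectors and labels must align")
    _, a1 = roc_auc(s1, labels, positive)
    _, a2 = roc_auc(s2, labels, positive)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    se1 = hanley_mcneil_se(a1, n_pos, n_neg)
    se2 = hanley_mcneil_se(a2, n_pos, n_neg)
    r_avg = _within_class_corr(s1, s2, pos)
    r = auc_estimator_correlation(r_avg, 0.5 * (a1 + a2))
    var = se1**2 + se2**2 - 2 * r * se1 * se2
    if var <= 0:
        return ROCComparison(a1, a2, se1, se2, r, 0.0, 1.0, degenerate=True)
    z = (a1 - a2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return ROCComparison(a1, a2, se1, se2, r, float(z), float(p))


def confusion_metrics(
    predicted, truth, positive: str = GREATER
) -> dict[str, float]:
    """Sensitivity, specificity, balanced and raw accuracy (fractions).

    Sensitivity is computed on the positive (greater-decliner) class;
    balanced accuracy is the mean of sensitivity and specificity.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if len(pred) != len(true):
        raise ConfigurationError("prediction/truth length mismatch")
    pos = true == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ConfigurationError(
            "both classes must appear in the truth labels"
        )
    tp = int(((pred == positive) & pos).sum())
    fn = int(((pred != positive) & pos).sum())
    tn = int(((pred != positive) & ~pos).sum())
    fp = int(((pred == positive) & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": 0.5 * (sens + spec),
        "accuracy": (tp + tn) / len(true),
    }


def adjusted_linear_association(
    response, decline, covariates: pd.DataFrame | None = None
) -> dict[str, float]:
    """OLS of decline on a score with covariate adjustment.

    Returns the score coefficient and its t-based p-value from the
    adjusted model, plus the unadjusted Pearson correlation (r_p) between
    score and decline with its p-value.  Categorical covariates are
    dummy-encoded; a rank-deficient design raises with the offending
    columns named.
    """
    score = np.asarray(response, dtype=float)
    y = np.asarray(decline, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame({"score": score})
    else:
        enc = pd.get_dummies(
            covariates.reset_index(drop=True), drop_first=True, dtype=float
        )
        X = pd.concat(
            [pd.Series(score, name="score"), enc], axis=1
        )
    X = sm.add_constant(X.astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name a collinear column: one whose removal restores full rank
        culprits = []
        arr = X.to_numpy()
        full = np.linalg.matrix_rank(arr)
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == full:
                culprits.append(str(col))
        raise ConfigurationError(f"rank-deficient design; collinear: {culprits}")
    if X.shape[0] <= X.shape[1]:
        raise ConfigurationError("need n > number of model parameters")
    fit = sm.OLS(y, X).fit()
    r_p, r_p_pval = stats.pearsonr(score, y)
    return {
        "coefficient": float(fit.params["score"]),
        "p": float(fit.pvalues["score"]),
        "pearson_r": float(r_p),
        "pearson_p": float(r_p_pval),
        "r_squared": float(fit.rsquared),
    }
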