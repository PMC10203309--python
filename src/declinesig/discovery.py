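"""Signature discovery: balanced-resample elastic-net ranking feeding a
step-forward PLSDA search with cross-validated selection.

The procedure mirrors the discovery pipeline it implements end to end:

1. draw 2000 class-balanced subsets (every subset contains the full
   minority class plus an equal-sized random draw from the majority
   class, both without replacement);
2. fit an elastic net on each subset, with the penalty strength chosen
   per subset by internal cross-validation at minimum deviance, and record
   which analytes receive nonzero coefficients;
3. rank analytes by selection frequency;
4. feed the ranking step-forward into PLSDA, scoring each signature size
   by stratified k-fold (k = 6) cross-validation, and keep the size with
   the best cross-validated balanced accuracy (ties to the smaller size);
5. compare the winner against a null distribution of equally sized random
   signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold

from . import evaluation, plsda
from .datatypes import GREATER, ConfigurationError

logger = logging.getLogger(__name__)

MAX_SKIP_FRACTION = 0.10


@dataclass
class SelectionRanking:
    """Analytes ordered by elastic-net selection frequency (descending).

    ``table`` has one row per analyte with columns ``frequency`` (fraction
    of iterations with a nonzero coefficient), ``mean_abs_coef`` (mean
    |coefficient| across selecting iterations; first tie-break) and the
    final rank.  The second tie-break is the analyte id.
    """

    table: pd.DataFrame
    n_iterations: int
    n_skipped: int = 0

    @property
    def analytes(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])


@dataclass
class StepForwardCurve:
    """Per-size cross-validated performance of nested signatures."""

    table: pd.DataFrame  # size, cv/cal metrics
    features_by_size: dict[int, list[str]]


@dataclass
class SignatureEvaluation:
    """Calibration and cross-validated performance of one feature set."""

    features: list[str]
    calibration: dict[str, float]
    cv: dict[str, float]
    calibration_auc: float
    cv_auc: float
    calibration_roc: pd.DataFrame
    cv_roc: pd.DataFrame
    cv_scores: np.ndarray  # pooled out-of-fold predicted responses
    cv_labels: np.ndarray
    fold_accuracies: np.ndarray


@dataclass
class RandomSignatureNull:
    accuracies: np.ndarray
    observed: float
    empirical_p: float
    ttest_p: float
    signature_size: int


def balanced_resample(classes, rng) -> np.ndarray:
    """Positional indices of one class-balanced subset.

    From each class, min-class-size samples are drawn without replacement,
    so the subset has size 2 * n_min and the minority class is always
    fully included.
    """
    arr = np.asarray(classes)
    levels = pd.unique(arr)
    if len(levels) != 2:
        raise ConfigurationError("balanced resampling needs two classes")
    idx_by_class = [np.flatnonzero(arr == lv) for lv in levels]
    n_min = min(len(ix) for ix in idx_by_class)
    if n_min < 2:
        raise ConfigurationError("smallest class must have n >= 2")
    chosen = [rng.choice(ix, size=n_min, replace=False) for ix in idx_by_class]
    return np.sort(np.concatenate(chosen))


def _one_enet_iteration(
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    seed: int,
    alpha_mix: float,
    n_alphas: int,
    internal_cv: int,
) -> np.ndarray | None:
    rng = np.random.default_rng(seed)
    idx = balanced_resample(classes, rng)
    Xs, ys = X[idx], y[idx]
    if np.ptp(ys) == 0:
        return None
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xz = (Xs - mu) / sd
    cv = KFold(n_splits=internal_cv, shuffle=True, random_state=seed % (2**31))
    model = ElasticNetCV(
        l1_ratio=alpha_mix,
        alphas=n_alphas,  # length of the automatic penalty grid
        cv=cv,
        max_iter=3000,
        tol=1e-3,
        random_state=seed % (2**31),
    )
    model.fit(Xz, ys)
    return model.coef_


def enet_selection_frequencies(
    X,
    classes,
    n_iterations: int = 2000,
    alpha_mix: float = 0.5,
    seed: int = 0,
    n_alphas: int = 30,
    internal_cv: int = 5,
    n_jobs: int = 1,
) -> SelectionRanking:
    """Selection frequency of every analyte across balanced EN resamples.

    Per iteration a balanced subset is drawn, predictors are autoscaled
    within the subset, and an elastic net (mixing parameter ``alpha_mix``)
    is fit on the 0/1-encoded response with the penalty strength chosen by
    ``internal_cv``-fold cross-validation at minimum deviance.  An analyte
    counts as selected when its coefficient is nonzero at that penalty.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xm.shape[1])]
    arr = np.asarray(classes)
    y = (arr == (GREATER if GREATER in arr else pd.unique(arr)[0])).astype(float)

    seeds = np.random.SeedSequence(seed).generate_state(n_iterations) % (2**31)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_enet_iteration)(
            Xm, y, arr, int(s), alpha_mix, n_alphas, internal_cv
        )
        for s in seeds
    )
    counts = np.zeros(Xm.shape[1])
    coef_sums = np.zeros(Xm.shape[1])
    n_skipped = 0
    for coef in results:
        if coef is None:
            n_skipped += 1
            continue
        nz = coef != 0
        counts += nz
        coef_sums += np.abs(coef)
    n_used = n_iterations - n_skipped
    if n_skipped > MAX_SKIP_FRACTION * n_iterations:
        raise ConfigurationError(
            f"{n_skipped}/{n_iterations} degenerate resamples skipped"
        )
    if n_skipped:
        logger.warning("skipped %d degenerate resamples", n_skipped)
    freq = counts / max(n_used, 1)
    mean_abs = np.divide(
        coef_sums, counts, out=np.zeros_like(coef_sums), where=counts > 0
    )
    table = pd.DataFrame(
        {"frequency": freq, "mean_abs_coef": mean_abs},
        index=pd.Index(names, name="analyte"),
    )
    table = table.sort_values(
        by=["frequency", "mean_abs_coef", "analyte"],
        ascending=[False, False, True],
        kind="stable",
        key=lambda col: col if col.name != "analyte" else col.astype(str),
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return SelectionRanking(table=table, n_iterations=n_used, n_skipped=n_skipped)


def kfold_cv_evaluate(
    features: list[str],
    X: pd.DataFrame,
    classes,
    k: int = 6,
    seed: int = 0,
    n_lv: int = 2,
    positive: str = GREATER,
) -> SignatureEvaluation:
    """Stratified k-fold cross-validated PLSDA evaluation of a feature set.

    Autoscaling and model fitting happen on the training folds only;
    predictions are pooled across folds for the cross-validated confusion
    metrics and ROC.  Calibration metrics come from the full-data fit.
    """
    arr = np.asarray(classes)
    features = list(features)
    Xf = X[features] if isinstance(X, pd.DataFrame) else pd.DataFrame(X)[features]
    pos_n = int((arr == positive).sum())
    neg_n = len(arr) - pos_n
    loo = k == len(arr)  # leave-one-out: unstratified by necessity
    if not loo and min(pos_n, neg_n) < k:
        raise ConfigurationError(
            f"class of size {min(pos_n, neg_n)} cannot be stratified into "
            f"{k} folds; use a smaller k"
        )

    model = plsda.fit_plsda(Xf, arr, n_lv=n_lv, positive=positive)
    cal_yhat, cal_labels, _ = plsda.predict(model, Xf)
    cal_metrics = evaluation.confusion_metrics(cal_labels, arr, positive)
    cal_roc, cal_auc = evaluation.roc_auc(cal_yhat, arr, positive)

    if loo:
        splits = [
            (np.delete(np.arange(len(arr)), i), np.array([i]))
            for i in range(len(arr))
        ]
    else:
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=seed % (2**31)
        )
        splits = list(skf.split(Xf, arr))
    cv_yhat = np.empty(len(arr))
    cv_pred = np.empty(len(arr), dtype=object)
    fold_acc = []
    for train, test in splits:
        fold_model = plsda.fit_plsda(
            Xf.iloc[train], arr[train], n_lv=n_lv, positive=positive
        )
        yhat, labels, _ = plsda.predict(fold_model, Xf.iloc[test])
        cv_yhat[test] = yhat
        cv_pred[test] = labels
        fold_acc.append(float((labels == arr[test]).mean()))
    cv_metrics = evaluation.confusion_metrics(cv_pred, arr, positive)
    cv_roc, cv_auc = evaluation.roc_auc(cv_yhat, arr, positive)
    return SignatureEvaluation(
        features=features,
        calibration=cal_metrics,
        cv=cv_metrics,
        calibration_auc=cal_auc,
        cv_auc=cv_auc,
        calibration_roc=cal_roc,
        cv_roc=cv_roc,
        cv_scores=cv_yhat,
        cv_labels=cv_pred.astype(str),
        fold_accuracies=np.asarray(fold_acc),
    )


def step_forward_search(
    ranking: SelectionRanking,
    X: pd.DataFrame,
    classes,
    k: int = 6,
    max_size: int = 100,
    seed: int = 0,
    n_lv: int = 2,
    positive: str = GREATER,
) -> tuple[StepForwardCurve, SignatureEvaluation]:
    """Grow the signature one ranked analyte at a time, scoring by CV.

    The optimal signature is the size with the highest cross-validated
    balanced accuracy; ties go to the smallest size.
    """
    n_avail = len(ranking.analytes)
    if max_size > n_avail:
        logger.warning(
            "max_size %d clipped to %d available analytes", max_size, n_avail
        )
        max_size = n_avail
    rows = []
    features_by_size: dict[int, list[str]] = {}
    evaluations: dict[int, SignatureEvaluation] = {}
    for size in range(1, max_size + 1):
        feats = ranking.top(size)
        ev = kfold_cv_evaluate(
            feats, X, classes, k=k, seed=seed, n_lv=n_lv, positive=positive
        )
        features_by_size[size] = feats
        evaluations[size] = ev
        rows.append(
            {
                "size": size,
                "cv_balanced_accuracy": ev.cv["balanced_accuracy"],
                "cv_sensitivity": ev.cv["sensitivity"],
                "cv_specificity": ev.cv["specificity"],
                "cal_balanced_accuracy": ev.calibration["balanced_accuracy"],
                "cv_auc": ev.cv_auc,
            }
        )
    table = pd.DataFrame(rows).set_index("size", drop=False)
    best_acc = table["cv_balanced_accuracy"].max()
    best_size = int(table.index[table["cv_balanced_accuracy"] == best_acc][0])
    logger.info(
        "step-forward search: optimal size %d (CV balanced accuracy %.3f)",
        best_size,
        best_acc,
    )
    return (
        StepForwardCurve(table=table, features_by_size=features_by_size),
        evaluations[best_size],
    )


def minimal_signatures(
    curve: StepForwardCurve,
    max_size: int = 15,
    min_cv_accuracy: float = 0.80,
) -> pd.DataFrame:
    """Signatures with fewer than ``max_size`` features and CV balanced
    accuracy strictly above ``min_cv_accuracy``; local maxima of the curve
    are flagged."""
    t = curve.table
    acc = t["cv_balanced_accuracy"].to_numpy()
    local_max = np.zeros(len(t), dtype=bool)
    for i in range(len(t)):
        left = acc[i - 1] if i > 0 else -np.inf
        right = acc[i + 1] if i < len(t) - 1 else -np.inf
        local_max[i] = acc[i] >= left and acc[i] >= right
    out = t.copy()
    out["local_maximum"] = local_max
    keep = (out["size"] < max_size) & (out["cv_balanced_accuracy"] > min_cv_accuracy)
    return out.loc[keep]


def random_signature_null(
    X: pd.DataFrame,
    classes,
    signature_size: int,
    n_random: int = 2000,
    k: int = 6,
    seed: int = 0,
    observed_accuracy: float | None = None,
    n_lv: int = 2,
    positive: str = GREATER,
    n_jobs: int = 1,
) -> RandomSignatureNull:
    """Null distribution of CV balanced accuracy over random feature sets.

    The empirical p-value is (1 + #{null >= observed}) / (1 + n_random);
    a two-tailed one-sample comparison of the null accuracies against the
    observed value (the t-test used for the published comparison) is also
    reported.
    """
    if signature_size > X.shape[1]:
        raise ConfigurationError("signature_size exceeds analyte count")
    if n_random < 20:
        logger.warning("n_random < 20 gives an unstable null distribution")
    cols = np.asarray(X.columns)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_random) % (2**31)

    def one(s: int) -> float:
        rng = np.random.default_rng(s)
        feats = list(rng.choice(cols, size=signature_size, replace=False))
        ev = kfold_cv_evaluate(
            feats, X, classes, k=k, seed=int(s), n_lv=n_lv, positive=positive
        )
        return ev.cv["balanced_accuracy"]

    accs = np.asarray(
        Parallel(n_jobs=n_jobs)(delayed(one)(int(s)) for s in seeds)
    )
    if observed_accuracy is None:
        observed_accuracy = np.nan
        emp_p = np.nan
        t_p = np.nan
    else:
        emp_p = (1 + int((accs >= observed_accuracy).sum())) / (1 + n_random)
        t_p = float(stats.ttest_1samp(accs, observed_accuracy).pvalue)
    return RandomSignatureNull(
        accuracies=accs,
        observed=float(observed_accuracy),
        empirical_p=float(emp_p),
        ttest_p=t_p,
        signature_size=signature_size,
    )
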