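"""Partial least squares discriminant analysis (PLSDA).

A two-class PLS1 model: the class membership is encoded as a single 0/1
response, predictors are autoscaled with training statistics, latent
variables (LVs) are extracted by the classical iterative NIPALS algorithm
with deflation, and a sample is classified by thresholding its predicted
response at the midpoint of the calibration class means.

``orthogonalize`` rotates a fitted model's latent space so that all
response-predictive variation concentrates on LV1 while the remaining LVs
carry response-orthogonal variation — purely a change of basis within the
span of the original scores, so predictions are unchanged.  LV1 is
oriented so that the greater-decliner class mean score is negative
(proteins loading negatively are comparatively increased in greater
decliners).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GREATER, LESSER, ConfigurationError

logger = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class PLSDAModel:
    """A fitted two-class PLSDA model.

    Matrices follow the usual PLS conventions: ``x_weights`` (W) and
    ``x_loadings`` (P) are analytes x LVs, ``y_loadings`` (q) is the
    per-LV regression of the centered response on the scores,
    ``x_scores`` (T) is samples x LVs, and ``x_rotations``
    (R = W (P'W)^-1) maps autoscaled predictors directly to scores.
    """

    analytes: list[str]
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    x_rotations: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    n_lv: int
    class_encoding: dict
    decision_threshold: float
    x_variance_explained: np.ndarray
    orthogonalized: bool = False
    dropped_analytes: list[str] = field(default_factory=list)
    calibration_samples: list = field(default_factory=list)

    @property
    def positive_class(self) -> str:
        return next(k for k, v in self.class_encoding.items() if v == 1)

    @property
    def negative_class(self) -> str:
        return next(k for k, v in self.class_encoding.items() if v == 0)

    @property
    def coef(self) -> np.ndarray:
        """Regression vector on the autoscaled predictor scale."""
        return self.x_rotations @ self.y_loadings

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "analytes": self.analytes,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_rotations": self.x_rotations.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "n_lv": self.n_lv,
            "class_encoding": self.class_encoding,
            "decision_threshold": self.decision_threshold,
            "x_variance_explained": self.x_variance_explained.tolist(),
            "orthogonalized": self.orthogonalized,
            "dropped_analytes": self.dropped_analytes,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PLSDAModel":
        d = json.loads(text)
        return cls(
            analytes=d["analytes"],
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_scores=np.zeros((0, d["n_lv"])),
            x_rotations=np.asarray(d["x_rotations"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_std=np.asarray(d["x_std"], dtype=float),
            y_mean=d["y_mean"],
            n_lv=d["n_lv"],
            class_encoding={k: int(v) for k, v in d["class_encoding"].items()},
            decision_threshold=d["decision_threshold"],
            x_variance_explained=np.asarray(
                d["x_variance_explained"], dtype=float
            ),
            orthogonalized=d["orthogonalized"],
            dropped_analytes=d.get("dropped_analytes", []),
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str], list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], list(X.index)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])], list(range(arr.shape[0]))


def _encode(classes, positive: str | None) -> tuple[np.ndarray, dict]:
    arr = np.asarray(classes)
    levels = sorted(pd.unique(arr).tolist())
    if len(levels) != 2:
        raise ConfigurationError(
            f"PLSDA needs exactly two classes, got {levels}"
        )
    if positive is None:
        positive = GREATER if GREATER in levels else levels[0]
    if positive not in levels:
        raise ConfigurationError(f"positive class {positive!r} not in data")
    negative = next(l for l in levels if l != positive)
    encoding = {str(positive): 1, str(negative): 0}
    y = (arr == positive).astype(float)
    return y, encoding


def fit_plsda(
    X,
    classes,
    n_lv: int = 2,
    positive: str | None = None,
) -> PLSDAModel:
    """Fit a PLSDA model on autoscaled predictors.

    Predictors are centered and scaled to unit SD using the calibration
    data; the 0/1-encoded response is centered.  Constant analytes (zero
    training SD) are excluded with a warning.  ``n_lv`` is clipped to what
    the data can support.
    """
    Xm, names, sample_ids = _as_matrix(X)
    y, encoding = _encode(classes, positive)
    n, p = Xm.shape
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ConfigurationError("each class needs at least two samples")

    mean = Xm.mean(axis=0)
    std = Xm.std(axis=0, ddof=1)
    constant = std == 0
    dropped = [names[j] for j in np.flatnonzero(constant)]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} constant analyte(s): {dropped[:5]}",
            stacklevel=2,
        )
        keep = ~constant
        Xm, mean, std = Xm[:, keep], mean[keep], std[keep]
        names = [names[j] for j in np.flatnonzero(keep)]
        p = Xm.shape[1]
    if p == 0:
        raise ConfigurationError("no non-constant analytes to fit on")

    n_lv = int(min(n_lv, n - 1, p))
    if n_lv < 1:
        raise ConfigurationError("cannot extract any latent variable")

    Xs = (Xm - mean) / std
    y_mean = y.mean()
    yc = y - y_mean

    X_work = Xs.copy()
    ss_total = float((Xs**2).sum())
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    var_exp = np.zeros(n_lv)
    extracted = 0
    for a in range(n_lv):
        # iterative (power-method style) extraction; with a single
        # response column this converges in one pass but the loop keeps
        # the classical algorithm explicit
        u = yc.copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = X_work.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
            t = X_work @ w
            qa = float(yc @ t) / float(t @ t)
            u = yc * qa
        t = X_work @ w
        tt = float(t @ t)
        if tt <= 1e-300 or np.linalg.norm(w) == 0:
            break  # residual X exhausted
        pa = X_work.T @ t / tt
        qa = float(yc @ t) / tt
        X_work = X_work - np.outer(t, pa)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        var_exp[a] = float(np.outer(t, pa).ravel() @ np.outer(t, pa).ravel()) / ss_total
        extracted += 1
    if extracted == 0:
        raise ConfigurationError("no latent variable could be extracted")
    W, P, T, q, var_exp = (
        W[:, :extracted],
        P[:, :extracted],
        T[:, :extracted],
        q[:extracted],
        var_exp[:extracted],
    )
    n_lv = extracted

    R = W @ np.linalg.inv(P.T @ W)

    # orient each LV so the positive (greater) class mean score is negative
    pos = y == 1
    for a in range(n_lv):
        if T[pos, a].mean() > T[~pos, a].mean():
            W[:, a] *= -1
            P[:, a] *= -1
            T[:, a] *= -1
            R[:, a] *= -1
            q[a] *= -1

    yhat = y_mean + Xs @ (R @ q)
    threshold = 0.5 * (yhat[pos].mean() + yhat[~pos].mean())

    return PLSDAModel(
        analytes=names,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        x_rotations=R,
        x_mean=mean,
        x_std=std,
        y_mean=float(y_mean),
        n_lv=n_lv,
        class_encoding=encoding,
        decision_threshold=float(threshold),
        x_variance_explained=var_exp,
        dropped_analytes=dropped,
        calibration_samples=sample_ids,
    )


def predict(
    model: PLSDAModel, X_new
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict responses, class labels and LV scores for new samples.

    Autoscaling uses the training mean/SD only.  A sample is labeled
    ``greater`` (the positive class) iff its predicted response strictly
    exceeds the decision threshold; a tie goes to the negative class (the
    larger calibration class in the imbalanced design).
    """
    if isinstance(X_new, pd.DataFrame):
        by_name = {str(c): c for c in X_new.columns}
        missing = [a for a in model.analytes if a not in by_name]
        if missing:
            raise ConfigurationError(
                f"missing analytes in prediction input: {missing[:5]}"
            )
        Xm = X_new[[by_name[a] for a in model.analytes]].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[None, :]
        if Xm.shape[1] != len(model.analytes):
            raise ConfigurationError(
                f"expected {len(model.analytes)} analytes, got {Xm.shape[1]}"
            )
    Xs = (Xm - model.x_mean) / model.x_std
    scores = Xs @ model.x_rotations
    yhat = model.y_mean + scores @ model.y_loadings
    labels = np.where(
        yhat > model.decision_threshold,
        model.positive_class,
        model.negative_class,
    )
    return yhat, labels, scores


def orthogonalize(model: PLSDAModel) -> PLSDAModel:
    """Concentrate the response-predictive direction on LV1.

    Builds a new score basis by Gram-Schmidt on [T q, t_1, ..., t_k]: the
    first rotated score is the fitted centered response (so LV1 carries
    all predictive covariance) and subsequent scores are orthogonal to it,
    hence uncorrelated with the response.  Predictions are bit-identical
    because the basis spans the same space.  Idempotent; a single-LV model
    is returned unchanged.
    """
    if model.orthogonalized:
        return model
    k = model.n_lv
    if k == 1:
        out = _copy_model(model)
        out.orthogonalized = True
        return out
    T = model.x_scores
    if T.shape[0] == 0:
        raise ConfigurationError(
            "orthogonalization needs calibration scores (deserialized "
            "models cannot be rotated)"
        )
    q = model.y_loadings
    D = T.T @ T  # diagonal up to numerical noise

    # columns of G express the rotated scores in the old score basis
    candidates = [q] + [np.eye(k)[:, j] for j in range(k)]
    G_cols: list[np.ndarray] = []
    for c in candidates:
        g = c.astype(float).copy()
        for prev in G_cols:
            g -= prev * (prev @ D @ g) / (prev @ D @ prev)
        if np.sqrt(float(g @ D @ g)) > 1e-12 * np.sqrt(np.trace(D)):
            G_cols.append(g)
        if len(G_cols) == k:
            break
    if len(G_cols) < k:
        raise ConfigurationError("degenerate score space; cannot rotate")
    G = np.column_stack(G_cols)

    T_new = T @ G
    G_inv_T = np.linalg.inv(G).T
    P_new = model.x_loadings @ G_inv_T
    W_new = model.x_weights @ G
    R_new = model.x_rotations @ G
    # regression of the centered fitted response on the new scores: only
    # LV1 carries it by construction
    yhat_c = T @ q
    q_new = np.linalg.solve(T_new.T @ T_new, T_new.T @ yhat_c)

    # re-orient so the positive-class mean LV1 score is negative; the
    # fitted response is positive-class-high, so flip LV1
    for a in range(k):
        flip = False
        if a == 0:
            flip = True  # t1_new = +fitted response -> positive class high
        if flip:
            T_new[:, a] *= -1
            P_new[:, a] *= -1
            W_new[:, a] *= -1
            R_new[:, a] *= -1
            q_new[a] *= -1

    ss_total = float((model.x_scores @ model.x_loadings.T).ravel() @
                     (model.x_scores @ model.x_loadings.T).ravel())
    # total modeled X sum of squares is basis-invariant; recompute the
    # per-LV split in the rotated basis relative to the original total
    denom = ss_total / max(model.x_variance_explained.sum(), 1e-300)
    var_exp = np.array(
        [
            float((np.outer(T_new[:, a], P_new[:, a]) ** 2).sum()) / denom
            for a in range(k)
        ]
    )

    out = _copy_model(model)
    out.x_weights = W_new
    out.x_loadings = P_new
    out.y_loadings = q_new
    out.x_scores = T_new
    out.x_rotations = R_new
    out.x_variance_explained = var_exp
    out.orthogonalized = True
    return out


def _copy_model(model: PLSDAModel) -> PLSDAModel:
    return PLSDAModel(
        analytes=list(model.analytes),
        x_weights=model.x_weights.copy(),
        x_loadings=model.x_loadings.copy(),
        y_loadings=model.y_loadings.copy(),
        x_scores=model.x_scores.copy(),
        x_rotations=model.x_rotations.copy(),
        x_mean=model.x_mean.copy(),
        x_std=model.x_std.copy(),
        y_mean=model.y_mean,
        n_lv=model.n_lv,
        class_encoding=dict(model.class_encoding),
        decision_threshold=model.decision_threshold,
        x_variance_explained=model.x_variance_explained.copy(),
        orthogonalized=model.orthogonalized,
        dropped_analytes=list(model.dropped_analytes),
        calibration_samples=list(model.calibration_samples),
    )
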