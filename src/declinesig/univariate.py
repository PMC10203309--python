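"""Per-analyte screening: fold changes, t-tests, BH adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    GREATER,
    LESSER,
    LOG,
    ConfigurationError,
    ProteomicMatrix,
)

TINY_P = np.finfo(float).tiny  # reported instead of an underflowed 0


def two_sample_ttest(
    x, y, variant: str = "pooled"
) -> tuple[float, float]:
    """Two-tailed two-sample t-test.

    ``variant='pooled'`` is the classical Student test with pooled
    variance (the default throughout the pipeline); ``'welch'`` drops the
    equal-variance assumption.  Two zero-variance groups with equal means
    return (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each group needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigurationError("non-finite values in t-test input")
    if variant not in ("pooled", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def univariate_screen(
    matrix: ProteomicMatrix,
    classes,
    variant: str = "pooled",
    positive: str = GREATER,
) -> pd.DataFrame:
    """Volcano-style screen of every analyte between the two decline classes.

    The fold change is computed on the raw concentration scale — the mean
    concentration in greater decliners divided by the mean in lesser
    decliners, then log2 — while the t-test runs on the log-scale values.
    Returns a DataFrame with one row per analyte: ``fc``, ``t``,
    ``p_raw``, ``p_adj`` and significance flags at 0.05 / 0.01 (raw p).
    """
    if matrix.scale != LOG:
        raise ConfigurationError("screen expects a log-scale matrix")
    classes = np.asarray(classes)
    pos = classes == positive
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ConfigurationError("each class needs n >= 2")

    logvals = matrix.values.to_numpy()
    rawvals = np.exp2(logvals)
    fc = np.log2(rawvals[pos].mean(axis=0) / rawvals[~pos].mean(axis=0))

    t = np.empty(matrix.n_analytes)
    p = np.empty(matrix.n_analytes)
    for j in range(matrix.n_analytes):
        t[j], p[j] = two_sample_ttest(logvals[pos, j], logvals[~pos, j], variant)
    p = np.where(p == 0, TINY_P, p)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "analyte": matrix.analytes,
            "compartment": matrix.compartment.to_numpy(),
            "fc": fc,
            "t": t,
            "p_raw": p,
            "p_adj": padj,
            "sig_05": p < 0.05,
            "sig_01": p < 0.01,
        }
    ).set_index("analyte", drop=False)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test for 2x2 demographic tables (cohort summaries)."""
    odds, p = stats.fisher_exact(np.asarray(table))
    return float(odds), float(p)
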