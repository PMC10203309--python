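"""Unsupervised profiling: PCA with outlier handling, permutation tests
on component scores, group-score ANOVAs, and hierarchical clustering of a
signature with Spearman-correlation distance."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import ConfigurationError
from .evaluation import confusion_metrics
from .univariate import two_sample_ttest

logger = logging.getLogger(__name__)


@dataclass
class PCAProfile:
    """Autoscaled PCA of a samples x analytes table."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # analytes x components
    variance_explained: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_samples: int


def pca_fit(X: pd.DataFrame, n_components: int = 2) -> PCAProfile:
    """Mean-center, variance-scale and decompose.

    Constant columns (zero SD) are dropped with a warning before scaling.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if n < 3:
        raise ConfigurationError("PCA needs at least three samples")
    std = X.std(axis=0, ddof=1)
    constant = std == 0
    if constant.any():
        logger.warning(
            "dropping %d constant column(s) before PCA", int(constant.sum())
        )
        X = X.loc[:, ~constant]
        std = std[~constant]
        p = X.shape[1]
    if n_components > min(n - 1, p):
        raise ConfigurationError(
            f"n_components must be <= min(n-1, p) = {min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    Z = (X - mean) / std
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAProfile(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=X.columns, columns=comp_names
        ),
        variance_explained=pca.explained_variance_ratio_.copy(),
        eigenvalues=pca.explained_variance_.copy(),
        mean=mean.to_numpy(),
        std=std.to_numpy(),
        n_samples=n,
    )


def hotelling_t2_limit(n: int, k: int, conf: float = 0.95) -> float:
    """95% confidence limit of Hotelling's T^2 over k PCA components."""
    if n <= k:
        raise ConfigurationError("need more samples than components")
    return k * (n - 1) / (n - k) * stats.f.ppf(conf, k, n - k)


def hotelling_outliers(
    profile: PCAProfile, threshold: float = 2.0
) -> pd.Series:
    """Flag samples whose reduced Hotelling T^2 exceeds ``threshold``.

    T^2 sums the squared scores over the retained components, each scaled
    by its eigenvalue; the "reduced" statistic divides by the 95%
    confidence limit, so the conventional cut of 2 flags samples at twice
    the control limit.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    t2 = (profile.scores.to_numpy() ** 2 / profile.eigenvalues).sum(axis=1)
    limit = hotelling_t2_limit(profile.n_samples, profile.scores.shape[1])
    reduced = t2 / limit
    return pd.Series(reduced > threshold, index=profile.scores.index, name="outlier")


def reduced_t2(profile: PCAProfile) -> pd.Series:
    t2 = (profile.scores.to_numpy() ** 2 / profile.eigenvalues).sum(axis=1)
    limit = hotelling_t2_limit(profile.n_samples, profile.scores.shape[1])
    return pd.Series(t2 / limit, index=profile.scores.index, name="reduced_t2")


def permutation_group_test(
    scores: pd.DataFrame,
    groups,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Permutation p-value for group separation in the PC1-PC2 plane.

    The statistic is the Euclidean distance between the two group
    centroids; labels are permuted ``n_perm`` times and
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        logger.warning("n_perm < 100 gives a coarse permutation p-value")
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ConfigurationError("scores must have at least two components")
    S = S[:, :2]
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ConfigurationError("permutation test needs exactly two groups")
    mask = g == levels[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ConfigurationError("each group needs n >= 2")

    def centroid_distance(m: np.ndarray) -> float:
        return float(np.linalg.norm(S[m].mean(axis=0) - S[~m].mean(axis=0)))

    observed = centroid_distance(mask)
    rng = np.random.default_rng(seed)
    n1 = int(mask.sum())
    count = 0
    idx = np.arange(len(g))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        m = np.zeros(len(g), dtype=bool)
        m[perm[:n1]] = True
        if centroid_distance(m) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class ClusterEvaluation:
    newick: str
    assignments: pd.Series
    cluster_to_class: dict[int, str]
    sensitivity: float
    specificity: float
    misclassified: int
    distance: pd.DataFrame


def spearman_distance_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Sample-sample distance 1 - Spearman correlation across analytes."""
    vals = X.to_numpy(dtype=float)
    flat = np.ptp(vals, axis=1) == 0
    if flat.any():
        bad = list(X.index[flat][:5])
        raise ConfigurationError(
            f"constant sample profile(s), rank correlation undefined: {bad}"
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=X.index, columns=X.index)


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def hierarchical_cluster_eval(
    X_signature: pd.DataFrame,
    classes,
    positive: str = "greater",
) -> ClusterEvaluation:
    """Average-linkage clustering with Spearman-correlation distance.

    The dendrogram is cut into two clusters, clusters are mapped to
    decline classes by majority vote (ties toward the larger class) and
    the resulting confusion metrics are returned.
    """
    arr = np.asarray(classes)
    if X_signature.shape[1] < 2:
        raise ConfigurationError("need at least two analytes to cluster")
    dist = spearman_distance_matrix(X_signature)
    Z = average(squareform(dist.to_numpy(), checks=False))
    assign = fcluster(Z, t=2, criterion="maxclust")

    levels = pd.unique(arr)
    larger = max(levels, key=lambda lv: (arr == lv).sum())
    mapping: dict[int, str] = {}
    for c in np.unique(assign):
        members = arr[assign == c]
        counts = pd.Series(members).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        mapping[int(c)] = larger if larger in top else top[0]
    predicted = np.array([mapping[int(c)] for c in assign])
    metrics = confusion_metrics(predicted, arr, positive=positive)
    labels = [str(s) for s in X_signature.index]
    newick = _tree_to_newick(to_tree(Z), labels) + ";"
    return ClusterEvaluation(
        newick=newick,
        assignments=pd.Series(assign, index=X_signature.index, name="cluster"),
        cluster_to_class=mapping,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        misclassified=int((predicted != arr).sum()),
        distance=dist,
    )


POSTHOC_METHODS = ("tukey", "dunnett", "holm_sidak", "bonferroni")


def group_score_anova(
    scores,
    groups,
    posthoc: str = "tukey",
    control: str | None = None,
) -> dict:
    """One-way ANOVA of component scores across groups with a post-hoc family.

    ``dunnett`` compares every group to ``control``; the other families
    are all-pairs.  Returns the F statistic, ANOVA p, and a comparison
    table with adjusted p-values.
    """
    if posthoc not in POSTHOC_METHODS:
        raise ConfigurationError(
            f"unknown posthoc {posthoc!r}; choose from {POSTHOC_METHODS}"
        )
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ConfigurationError("need at least two groups")
    samples = [s[g == lv] for lv in levels]
    if any(len(x) < 2 for x in samples):
        raise ConfigurationError("each group needs n >= 2")
    f_stat, f_p = stats.f_oneway(*samples)

    rows = []
    if posthoc == "tukey":
        res = stats.tukey_hsd(*samples)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                rows.append(
                    {
                        "group1": levels[i],
                        "group2": levels[j],
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
    elif posthoc == "dunnett":
        if control is None or control not in levels:
            raise ConfigurationError("dunnett posthoc needs a valid control group")
        others = [lv for lv in levels if lv != control]
        res = stats.dunnett(
            *[s[g == lv] for lv in others], control=s[g == control]
        )
        for lv, p in zip(others, res.pvalue):
            rows.append({"group1": lv, "group2": control, "p_adj": float(p)})
    else:
        raw = []
        pairs = [
            (levels[i], levels[j])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
        for a, b in pairs:
            _, p = two_sample_ttest(s[g == a], s[g == b])
            raw.append(p)
        method = "holm-sidak" if posthoc == "holm_sidak" else "bonferroni"
        adj = multipletests(raw, method=method)[1]
        for (a, b), p in zip(pairs, adj):
            rows.append({"group1": a, "group2": b, "p_adj": float(p)})
    return {
        "f": float(f_stat),
        "p": float(f_p),
        "posthoc": posthoc,
        "comparisons": pd.DataFrame(rows),
    }
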