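import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from declinesig.datatypes import ConfigurationError
from declinesig import profiles as pf


class TestPCA:
    def test_rank_one_data(self):
        base = np.arange(6.0)
        X = pd.DataFrame(np.outer(base, [1.0, 2.0, -1.0]))
        prof = pf.pca_fit(X, n_components=2)
        assert prof.variance_explained[0] == pytest.approx(1.0)

    def test_scores_are_projections(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        prof = pf.pca_fit(X, n_components=3)
        Z = (X - X.mean()) / X.std(ddof=1)
        np.testing.assert_allclose(
            prof.scores.to_numpy(),
            Z.to_numpy() @ prof.loadings.to_numpy(),
            atol=1e-8,
        )

    def test_row_permutation_equivariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)))
        perm = rng.permutation(12)
        a = pf.pca_fit(X, 2).scores.to_numpy()
        b = pf.pca_fit(X.iloc[perm], 2).scores.to_numpy()
        np.testing.assert_allclose(a[perm], b, atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(ConfigurationError):
            pf.pca_fit(pd.DataFrame(np.ones((2, 3))), 1)


class TestHotelling:
    def test_centroid_sample_not_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        X.iloc[0] = X.mean()
        prof = pf.pca_fit(X, 2)
        out = pf.hotelling_outliers(prof)
        assert not out.iloc[0]

    def test_displaced_sample_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        X.iloc[0] += 10 * X.std()
        prof = pf.pca_fit(X, 2)
        assert pf.hotelling_outliers(prof).iloc[0]

    def test_spherical_flag_rate_below_5pct(self):
        """Reduced T^2 > 2 means twice the 95% control limit; on
        spherical Gaussian data the flagged fraction stays well under 5%
        and is stable across seeds."""
        rates = []
        for seed in range(8):
            X = pd.DataFrame(
                np.random.default_rng(seed).normal(size=(100, 10))
            )
            flags = pf.hotelling_outliers(pf.pca_fit(X, 2))
            rates.append(flags.mean())
        assert max(rates) < 0.05

    def test_bad_threshold(self, rng):
        prof = pf.pca_fit(pd.DataFrame(rng.normal(size=(10, 3))), 2)
        with pytest.raises(ConfigurationError):
            pf.hotelling_outliers(prof, threshold=0)


class TestPermutationTest:
    def test_separated_groups_minimal_p(self, rng):
        scores = rng.normal(size=(20, 2))
        scores[:10, 0] += 25.0
        groups = np.array(["a"] * 10 + ["b"] * 10)
        p = pf.permutation_group_test(pd.DataFrame(scores), groups, 999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_null_p_uniformish(self):
        """Identical group distributions: permutation p averages ~0.5."""
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=(16, 2))
            groups = np.array(["a"] * 8 + ["b"] * 8)
            ps.append(
                pf.permutation_group_test(pd.DataFrame(scores), groups, 200, seed)
            )
        assert 0.35 < np.mean(ps) < 0.65

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n = 8: the Monte-Carlo p agrees with exhaustive enumeration
        over all label assignments within 2 Monte-Carlo SEs."""
        rng = np.random.default_rng(5)
        S = rng.normal(size=(8, 2))
        S[:4] += 1.0
        groups = np.array(["a"] * 4 + ["b"] * 4)
        n_perm = 4000
        p_mc = pf.permutation_group_test(pd.DataFrame(S), groups, n_perm, seed=2)

        def stat(mask):
            return np.linalg.norm(S[mask].mean(0) - S[~mask].mean(0))

        obs = stat(np.array([True] * 4 + [False] * 4))
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if stat(mask) >= obs - 1e-12:
                count += 1
        p_exact = count / total
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 2 * se + 2 / n_perm

    def test_group_size_validation(self, rng):
        with pytest.raises(ConfigurationError):
            pf.permutation_group_test(
                pd.DataFrame(rng.normal(size=(4, 2))),
                np.array(["a", "b", "b", "b"]),
                200,
            )


class TestClustering:
    def test_well_separated_blobs_perfect(self, rng):
        # rank-based distance ignores level shifts, so the classes must
        # differ in profile shape, not overall level
        X = rng.normal(size=(20, 12))
        X[:8, :6] += 6.0
        X[8:, 6:] += 6.0
        Xdf = pd.DataFrame(X)
        classes = np.array(["greater"] * 8 + ["lesser"] * 12)
        out = pf.hierarchical_cluster_eval(Xdf, classes)
        assert out.misclassified == 0
        assert out.sensitivity == 1.0 and out.specificity == 1.0
        assert out.newick.endswith(";") and out.newick.count("(") == 19

    def test_distances_match_rank_correlation_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 15)))
        D = pf.spearman_distance_matrix(X)
        for i in range(10):
            for j in range(i + 1, 10):
                rho = stats.spearmanr(X.iloc[i], X.iloc[j]).statistic
                assert abs(D.iloc[i, j] - (1 - rho)) < 1e-12

    def test_constant_profile_named_in_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"))
        X.loc["c"] = 3.0
        with pytest.raises(ConfigurationError, match="c"):
            pf.hierarchical_cluster_eval(
                X, np.array(["greater"] * 2 + ["lesser"] * 3)
            )

    def test_two_misassigned_greater_gives_857(self, rng):
        """2 of 14 greater decliners landing in the lesser cluster yields
        the 85.7% clustering sensitivity."""
        X = rng.normal(size=(45, 10))
        X[:12, :5] += 8.0  # 12 greater show a distinct profile shape
        classes = np.array(["greater"] * 14 + ["lesser"] * 31)
        out = pf.hierarchical_cluster_eval(pd.DataFrame(X), classes)
        assert round(100 * out.sensitivity, 1) == 85.7


class TestANOVA:
    def test_identical_groups(self):
        s = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        out = pf.group_score_anova(s, g, posthoc="tukey")
        assert out["f"] == pytest.approx(0.0)
        assert (out["comparisons"]["p_adj"] > 0.99).all()

    def test_textbook_worked_example(self):
        """Three groups [3,4,5], [5,6,7], [8,9,10]: SSB = 38 (df 2),
        SSW = 6 (df 6), so F = 19 — computed by hand from the sums of
        squares."""
        s = np.array([3, 4, 5, 5, 6, 7, 8, 9, 10], dtype=float)
        g = np.repeat(["a", "b", "c"], 3)
        out = pf.group_score_anova(s, g, posthoc="tukey")
        assert out["f"] == pytest.approx(19.0)
        assert out["p"] < 0.01
        comp = out["comparisons"].set_index(["group1", "group2"])["p_adj"]
        assert comp[("a", "c")] < 0.05 and comp[("b", "c")] < 0.05
        assert comp[("a", "b")] > 0.05

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=10) + 0.5
        from declinesig.univariate import two_sample_ttest

        t, p_t = two_sample_ttest(x, y)
        out = pf.group_score_anova(
            np.r_[x, y], np.array(["a"] * 8 + ["b"] * 10), posthoc="bonferroni"
        )
        assert out["f"] == pytest.approx(t**2)
        assert out["p"] == pytest.approx(p_t)

    def test_dunnett_needs_control(self, rng):
        s = rng.normal(size=9)
        g = np.repeat(["a", "b", "c"], 3)
        with pytest.raises(ConfigurationError):
            pf.group_score_anova(s, g, posthoc="dunnett")
        out = pf.group_score_anova(s, g, posthoc="dunnett", control="a")
        assert set(out["comparisons"]["group2"]) == {"a"}

    def test_posthoc_families_agree_on_strong_effect(self, rng):
        s = np.r_[rng.normal(size=6), rng.normal(size=6) + 8.0]
        g = np.repeat(["a", "b"], 6)
        for ph in ("holm_sidak", "bonferroni"):
            out = pf.group_score_anova(s, g, posthoc=ph)
            assert (out["comparisons"]["p_adj"] < 0.001).all()

    def test_unknown_posthoc(self, rng):
        with pytest.raises(ConfigurationError):
            pf.group_score_anova(
                rng.normal(size=6), np.repeat(["a", "b"], 3), posthoc="scheffe"
            )


def test_signature_pca_separates_classes(small_analysis):
    """PCA restricted to the planted signature separates the decline
    classes on PC1 (ANOVA on PC1 scores)."""
    X = small_analysis["X"]
    planted = sorted(small_analysis["planted"])
    prof = pf.pca_fit(X[planted], n_components=2)
    out = pf.group_score_anova(
        prof.scores["PC1"].to_numpy(), small_analysis["classes"], "tukey"
    )
    assert out["p"] < 0.01
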