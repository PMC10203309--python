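import numpy as np
import pandas as pd
import pytest

from declinesig.datatypes import ConfigurationError
from declinesig import discovery, plsda
from declinesig.evaluation import confusion_metrics

from conftest import make_separated_panel


class TestBalancedResample:
    def test_minority_fully_included_subset_28(self, rng):
        classes = np.array(["greater"] * 14 + ["lesser"] * 31)
        idx = discovery.balanced_resample(classes, rng)
        assert len(idx) == 28
        assert set(idx[classes[idx] == "greater"]) == set(range(14))
        assert len(set(idx)) == 28  # without replacement

    def test_equal_classes_return_everything(self, rng):
        classes = np.array(["greater"] * 5 + ["lesser"] * 5)
        idx = discovery.balanced_resample(classes, rng)
        assert sorted(idx) == list(range(10))

    def test_majority_inclusion_frequency(self):
        """Each majority-class sample appears with probability 14/31
        (sampling without replacement) across many draws."""
        classes = np.array(["greater"] * 14 + ["lesser"] * 31)
        rng = np.random.default_rng(4)
        n_iter = 2000
        counts = np.zeros(45)
        for _ in range(n_iter):
            counts[discovery.balanced_resample(classes, rng)] += 1
        freq = counts[14:] / n_iter
        expected = 14 / 31
        se = np.sqrt(expected * (1 - expected) / n_iter)
        assert np.all(np.abs(freq - expected) < 4 * se)

    def test_tiny_class_errors(self, rng):
        with pytest.raises(ConfigurationError):
            discovery.balanced_resample(np.array(["a", "b", "b"]), rng)


class TestSelectionFrequencies:
    def test_planted_recovery_small_panel(self):
        """5 analytes planted at standardized effect 2.0 among 200 nulls
        (n = 45): every planted analyte ranks in the top 10."""
        X, classes, planted = make_separated_panel(seed=11)
        ranking = discovery.enet_selection_frequencies(
            X, classes, n_iterations=300, seed=5
        )
        assert set(planted) <= set(ranking.top(10))

    def test_duplicated_planted_analyte_grouping(self):
        """The elastic net's grouping behavior: a duplicated informative
        analyte is selected in both copies."""
        X, classes, planted = make_separated_panel(n_noise=60, seed=3)
        X = X.copy()
        X["sig0_copy"] = X["sig0"]
        ranking = discovery.enet_selection_frequencies(
            X, classes, n_iterations=150, seed=6
        )
        t = ranking.table
        assert t.loc["sig0", "frequency"] > 0
        assert t.loc["sig0_copy", "frequency"] > 0

    def test_frequencies_sorted_and_complete(self):
        X, classes, _ = make_separated_panel(n_noise=40, seed=2)
        ranking = discovery.enet_selection_frequencies(
            X, classes, n_iterations=50, seed=1
        )
        f = ranking.table["frequency"].to_numpy()
        assert (np.diff(f) <= 1e-12).all()
        assert sorted(ranking.analytes) == sorted(X.columns)

    def test_deterministic_given_seed(self):
        X, classes, _ = make_separated_panel(n_noise=30, seed=2)
        a = discovery.enet_selection_frequencies(X, classes, 40, seed=9)
        b = discovery.enet_selection_frequencies(X, classes, 40, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestKFoldEvaluate:
    def test_confusion_arithmetic_perfect_sensitivity(self):
        pred = np.array(["greater"] * 14 + ["greater"] + ["lesser"] * 30)
        true = np.array(["greater"] * 14 + ["lesser"] * 31)
        m = confusion_metrics(pred, true)
        assert m["sensitivity"] == 1.0
        assert round(100 * m["specificity"], 1) == 96.8
        assert round(100 * m["balanced_accuracy"], 1) == 98.4

    def test_permuted_labels_near_chance(self):
        """Label permutation on pure noise: CV balanced accuracy hovers
        around 0.5 across repeats."""
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(45, 8)))
        accs = []
        for seed in range(6):
            classes = np.array(["greater"] * 14 + ["lesser"] * 31)
            np.random.default_rng(seed).shuffle(classes)
            ev = discovery.kfold_cv_evaluate(
                list(X.columns), X, classes, k=6, seed=seed
            )
            accs.append(ev.cv["balanced_accuracy"])
        assert 0.3 < np.mean(accs) < 0.7

    def test_leave_one_out_matches_bruteforce_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        classes = np.array(["greater"] * 4 + ["lesser"] * 6)
        ev = discovery.kfold_cv_evaluate(list("abc"), X, classes, k=10, seed=0)
        preds = []
        for i in range(10):
            train = [j for j in range(10) if j != i]
            m = plsda.fit_plsda(X.iloc[train], classes[train], n_lv=2)
            _, label, _ = plsda.predict(m, X.iloc[[i]])
            preds.append(label[0])
        oracle = confusion_metrics(np.array(preds), classes)
        assert ev.cv["balanced_accuracy"] == oracle["balanced_accuracy"]
        assert ev.cv["sensitivity"] == oracle["sensitivity"]

    def test_fold_scaling_uses_training_rows_only(self):
        """Out-of-fold predictions equal those of a model fit and scaled
        on the training rows alone — no test-fold statistics enter, so
        rescaling the held-out rows transforms their predictions exactly
        as predicting transformed new data would."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(24, 5)))
        classes = np.array(["greater"] * 10 + ["lesser"] * 14)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=1)
        train0, test0 = next(iter(skf.split(X, classes)))
        for transform in (lambda v: v, lambda v: v * 3.0 + 1.0):
            X2 = X.copy()
            X2.iloc[test0] = transform(X2.iloc[test0])
            ev = discovery.kfold_cv_evaluate(
                list(X.columns), X2, classes, k=6, seed=1
            )
            direct = plsda.fit_plsda(X2.iloc[train0], classes[train0], n_lv=2)
            yhat, _, _ = plsda.predict(direct, X2.iloc[test0])
            np.testing.assert_allclose(ev.cv_scores[test0], yhat)

    def test_small_class_refuses_stratification(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 2)))
        classes = np.array(["greater"] * 3 + ["lesser"] * 5)
        with pytest.raises(ConfigurationError, match="smaller k"):
            discovery.kfold_cv_evaluate(list(X.columns), X, classes, k=6, seed=0)


class TestStepForward:
    def test_perfect_first_analyte_optimal_size_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {
                "perfect": np.r_[np.arange(14) + 50.0, np.arange(31)],
                "noise1": rng.normal(size=45),
                "noise2": rng.normal(size=45),
            }
        )
        classes = np.array(["greater"] * 14 + ["lesser"] * 31)
        table = pd.DataFrame(
            {"frequency": [1.0, 0.5, 0.2], "mean_abs_coef": [1, 1, 1]},
            index=pd.Index(["perfect", "noise1", "noise2"], name="analyte"),
        )
        ranking = discovery.SelectionRanking(table=table, n_iterations=10)
        curve, optimal = discovery.step_forward_search(
            ranking, X, classes, k=6, max_size=3, seed=0
        )
        assert curve.table.loc[1, "cv_balanced_accuracy"] == 1.0
        assert optimal.features == ["perfect"]

    def test_curve_reproducible_and_nested(self):
        X, classes, _ = make_separated_panel(n_noise=30, seed=7)
        ranking = discovery.enet_selection_frequencies(X, classes, 30, seed=2)
        c1, o1 = discovery.step_forward_search(ranking, X, classes, max_size=6, seed=4)
        c2, o2 = discovery.step_forward_search(ranking, X, classes, max_size=6, seed=4)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        assert o1.features == o2.features
        for s in range(2, 7):
            assert c1.features_by_size[s][:-1] == c1.features_by_size[s - 1]

    def test_max_size_clipped(self):
        X, classes, _ = make_separated_panel(n_noise=3, n_planted=2, seed=1)
        ranking = discovery.enet_selection_frequencies(X, classes, 20, seed=2)
        curve, _ = discovery.step_forward_search(
            ranking, X, classes, max_size=50, seed=0
        )
        assert curve.table["size"].max() == 5


class TestMinimalSignatures:
    def _curve(self, accs):
        table = pd.DataFrame(
            {
                "size": np.arange(1, len(accs) + 1),
                "cv_balanced_accuracy": accs,
                "cv_sensitivity": accs,
                "cv_specificity": accs,
                "cal_balanced_accuracy": accs,
                "cv_auc": accs,
            }
        ).set_index("size", drop=False)
        return discovery.StepForwardCurve(table=table, features_by_size={})

    def test_filter_application(self):
        out = discovery.minimal_signatures(self._curve([0.6, 0.82, 0.85]))
        assert list(out["size"]) == [2, 3]

    def test_all_below_threshold_empty(self):
        out = discovery.minimal_signatures(self._curve([0.5, 0.7, 0.80]))
        assert out.empty

    def test_boundaries_are_strict(self):
        accs = [0.80] * 14 + [0.9] * 2  # size 15 and 16 exceed accuracy
        out = discovery.minimal_signatures(self._curve(accs))
        assert list(out["size"]) == []  # 0.80 excluded; sizes 15,16 too big
        out2 = discovery.minimal_signatures(self._curve([0.801] * 16))
        assert list(out2["size"]) == list(range(1, 15))


class TestRandomNull:
    def test_strong_signature_beats_null(self):
        X, classes, planted = make_separated_panel(n_noise=120, seed=5)
        obs = discovery.kfold_cv_evaluate(planted, X, classes, k=6, seed=1)
        null = discovery.random_signature_null(
            X,
            classes,
            signature_size=5,
            n_random=60,
            seed=2,
            observed_accuracy=obs.cv["balanced_accuracy"],
        )
        assert null.empirical_p <= 5 / 61
        assert obs.cv["balanced_accuracy"] > np.quantile(null.accuracies, 0.9)

    def test_null_determinism(self):
        X, classes, _ = make_separated_panel(n_noise=40, seed=8)
        a = discovery.random_signature_null(
            X, classes, 5, n_random=25, seed=3, observed_accuracy=0.9
        )
        b = discovery.random_signature_null(
            X, classes, 5, n_random=25, seed=3, observed_accuracy=0.9
        )
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_oversized_signature_errors(self):
        X, classes, _ = make_separated_panel(n_noise=10, seed=8)
        with pytest.raises(ConfigurationError):
            discovery.random_signature_null(X, classes, 500, n_random=25, seed=3)
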