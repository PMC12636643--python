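import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from csfprognostics.panels import (attribute_features,
                                   combine_with_conventional,
                                   compare_predictor_sets, evaluate_panel,
                                   evaluate_nested_panel, roc_auc,
                                   stability_select, youden_threshold)


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == 1.0

    def test_hand_counted_pairs(self):
        auc, _ = roc_auc([0.9, 0.3, 0.8, 0.4], [1, 0, 0, 1])
        assert auc == 0.75

    def test_score_reversal_complements(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        a1, _ = roc_auc(s, y)
        a2, _ = roc_auc(-s, y)
        assert np.isclose(a1 + a2, 1.0)

    def test_matches_pairwise_count_on_random_instances(self):
        # ties included: scores drawn from a small discrete grid
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 15)
            y = rng.integers(0, 2, n)
            y[0], y[1] = 0, 1
            s = rng.integers(0, 5, n) / 4.0
            auc, _ = roc_auc(s, y)
            assert np.isclose(auc, brute_force_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestYouden:
    def test_separable_reaches_unit_j(self):
        _, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        _, j = youden_threshold(roc)
        assert j == 1.0

    def test_tie_broken_toward_sensitivity(self):
        _, roc = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        thr, j = youden_threshold(roc)
        assert np.isclose(j, 0.5)
        assert np.isclose(thr, 0.4)

    def test_j_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = rng.normal(size=20)
            y = rng.integers(0, 2, 20)
            y[0], y[1] = 0, 1
            _, roc = roc_auc(s, y)
            _, j = youden_threshold(roc)
            assert -1.0 <= j <= 1.0 and j >= 0.0


class TestStabilitySelect:
    def test_informative_feature_always_selected(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 10))
        X[:, 0] = y + rng.normal(0, 0.01, 100)
        sel = stability_select(X, y, n_boot=25, seed=3, cv_folds=3,
                               Cs=np.logspace(-2, 1, 5))
        assert sel.frequencies["f0"] == 1.0
        assert "f0" in sel.selected

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 40)
        for seed in range(3):
            X = rng.normal(size=(80, 15))
            sel = stability_select(X, y, n_boot=20, seed=seed, cv_folds=3,
                                   Cs=np.logspace(-2, 0.5, 5))
            assert sel.selected == []

    def test_selected_set_respects_threshold_definition(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 8))
        X[:, 0] = y + rng.normal(0, 0.05, 80)
        sel = stability_select(X, y, n_boot=20, seed=5, cv_folds=3,
                               Cs=np.logspace(-2, 1, 5))
        for f in sel.selected:
            assert sel.frequencies[f] >= sel.threshold

    def test_missing_values_rejected(self):
        X = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="knn_impute"):
            stability_select(X, np.repeat([0, 1], 5))


class TestEvaluatePanel:
    def test_separable_feature_gives_unit_auc(self):
        y = np.repeat([0, 1], 50)
        X = np.where(y, 10.0, 0.0)[:, None] + \
            np.random.default_rng(0).normal(0, 0.1, (100, 1))
        ev = evaluate_panel(X, y, n_runs=5,
                            grid={"n_estimators": [50], "max_depth": [None]},
                            seed=1)
        assert np.allclose(ev.aucs, 1.0)
        assert ev.median_auc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        y = rng.permutation(np.repeat([0, 1], 100))
        X = rng.normal(size=(200, 1))
        ev = evaluate_panel(X, y, n_runs=20,
                            grid={"n_estimators": [50], "max_depth": [3]},
                            seed=3)
        assert abs(ev.median_auc - 0.5) < 0.12

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 2)) + y[:, None]
        kw = dict(n_runs=4, grid={"n_estimators": [30], "max_depth": [3]}, seed=7)
        a = evaluate_panel(X, y, **kw)
        b = evaluate_panel(X, y, **kw)
        assert np.array_equal(a.aucs, b.aucs)
        assert all(np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])
                   for s1, s2 in zip(a.splits, b.splits))

    def test_grid_search_path_runs(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 2)) + 1.5 * y[:, None]
        ev = evaluate_panel(X, y, n_runs=2, cv_folds=3,
                            grid={"n_estimators": [20, 40], "max_depth": [2]},
                            seed=9)
        assert ev.aucs.min() > 0.7

    def test_nested_mode_not_optimistic_versus_fixed(self):
        rng = np.random.default_rng(5)
        n = 150
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 12))
        X[:, 0] += 1.2 * y
        X[:, 1] += 0.8 * y
        select_kwargs = dict(n_boot=15, cv_folds=3, Cs=np.logspace(-2, 1, 4))
        grid = {"n_estimators": [50], "max_depth": [3]}
        fixed_sel = stability_select(X, y, seed=1, **select_kwargs)
        panel = fixed_sel.selected or [fixed_sel.frequencies.idxmax()]
        Xf = pd.DataFrame(X, columns=[f"f{j}" for j in range(12)])
        fixed = evaluate_panel(Xf[panel], y, n_runs=8, grid=grid, seed=2)
        nested, panels = evaluate_nested_panel(
            Xf, y, n_runs=8, grid=grid, seed=2, select_kwargs=select_kwargs)
        assert len(panels) == 8
        # re-selecting inside the training split cannot be meaningfully better
        assert nested.median_auc <= fixed.median_auc + 0.05


class TestAttribution:
    def test_constant_model_gives_zero_attributions(self):
        class Const:
            def predict(self, X):
                return np.full(len(X), 0.7)
        X = np.random.default_rng(0).normal(size=(8, 3))
        att = attribute_features(Const(), X, seed=0)
        assert np.allclose(att.values, 0.0, atol=1e-12)
        assert np.isclose(att.base_value, 0.7)

    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        w = np.array([1.5, -2.0])

        class Lin:
            def predict(self, Z):
                return Z @ w
        att = attribute_features(Lin(), X[:10], background=X,
                                 max_background=60, seed=0)
        expected = w[None, :] * (X[:10] - X.mean(axis=0))
        assert np.allclose(att.values, expected, atol=1e-10)

    def test_sampled_matches_exact_enumeration_two_features(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))

        class Interact:
            def predict(self, Z):
                return Z[:, 0] * Z[:, 1] + Z[:, 0]
        exact = attribute_features(Interact(), X[:5], background=X[:20],
                                   max_background=20, seed=0, exact_limit=2)
        sampled = attribute_features(Interact(), X[:5], background=X[:20],
                                     max_background=20, seed=0, exact_limit=0,
                                     n_permutations=400)
        assert np.allclose(exact.values, sampled.values, atol=0.05)

    def test_local_accuracy_for_random_forest(self):
        from sklearn.ensemble import RandomForestClassifier
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 3)) + y[:, None]
        clf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        att = attribute_features(clf, X[:6], background=X, max_background=16,
                                 seed=1)
        scores = clf.predict_proba(X[:6])[:, 1]
        assert np.allclose(att.base_value + att.values.sum(axis=1), scores,
                           atol=1e-6)


class TestComparePredictorSets:
    def test_identical_blocks_give_zero_delta_p_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 2)) + y[:, None]
        lr = lambda s: LogisticRegression()
        d, p = compare_predictor_sets(X, X, y, n_runs=4, B=9,
                                      estimator_factory=lr, seed=1)
        assert d == 0.0
        assert p == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        Xa = rng.normal(size=(60, 2)) + 2 * y[:, None]
        Xb = rng.normal(size=(60, 2))
        lr = lambda s: LogisticRegression()
        d1, p1 = compare_predictor_sets(Xa, Xb, y, n_runs=4, B=9,
                                        estimator_factory=lr, seed=2)
        d2, p2 = compare_predictor_sets(Xb, Xa, y, n_runs=4, B=9,
                                        estimator_factory=lr, seed=2)
        assert np.isclose(d1, -d2)
        assert p1 == p2

    def test_misaligned_rows_rejected(self):
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            compare_predictor_sets(np.ones((10, 1)), np.ones((8, 1)), y)


class TestCombineWithConventional:
    def test_column_counts_and_order(self):
        panel = pd.DataFrame(np.ones((5, 3)), columns=["P1", "P2", "P3"])
        conv = pd.DataFrame(np.zeros((5, 2)), columns=["abeta42", "ptau181"])
        out = combine_with_conventional(panel, conv)
        assert list(out.columns) == ["P1", "P2", "P3", "abeta42", "ptau181"]
        assert out.attrs["provenance"]["abeta42"] == "conventional"

    def test_empty_conventional_is_identity(self):
        panel = pd.DataFrame(np.ones((4, 2)), columns=["P1", "P2"])
        out = combine_with_conventional(panel, pd.DataFrame(index=panel.index))
        assert list(out.columns) == ["P1", "P2"]

    def test_duplicate_names_rejected(self):
        panel = pd.DataFrame(np.ones((4, 1)), columns=["P1"])
        with pytest.raises(ValueError, match="duplicate"):
            combine_with_conventional(panel, panel)
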