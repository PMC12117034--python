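"""Classifiers: forced examples, sklearn cross-checks, determinism, serialization."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from rilipred.models import (
    DistanceWeightedKNNClassifier,
    GiniTreeClassifier,
    RandomFeatureKernelLogistic,
    gini_impurity,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
    standardize_apply,
    standardize_fit,
)

XOR_X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
XOR_Y = np.array([0, 0, 1, 1])


class TestStandardization:
    def test_two_point_column(self):
        params = standardize_fit(np.array([[1.0], [3.0]]))
        out = standardize_apply(params, np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert params.scale[0] == pytest.approx(np.sqrt(2))

    def test_constant_column_warns_scale_one(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            params = standardize_fit(X)
        out = standardize_apply(params, X)
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_training_columns_centered(self, rng):
        X = rng.normal(5, 3, (30, 4))
        out = standardize_apply(standardize_fit(X), X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestGiniTree:
    def test_impurity_values(self):
        assert gini_impurity([5, 5]) == 0.5
        assert gini_impurity([10, 0]) == 0.0

    def test_single_class_stump(self):
        tree = GiniTreeClassifier().fit(np.arange(6).reshape(-1, 1), np.ones(6, int))
        assert tree.n_splits_ == 0
        assert (tree.predict(np.array([[0.0], [100.0]])) == 1).all()

    def test_xor_shattered_with_three_splits(self):
        """Parity needs a zero-gain first split; budget 3 reaches 100%."""
        tree = GiniTreeClassifier(max_splits=3).fit(XOR_X, XOR_Y)
        assert tree.n_splits_ == 3
        np.testing.assert_array_equal(tree.predict(XOR_X), XOR_Y)

    def test_budget_monotone_resubstitution(self, small_cohort):
        from rilipred.evaluate import design_matrix

        X = design_matrix(small_cohort, "tree")
        y = small_cohort["rili"].to_numpy(int)
        prev = -1.0
        for budget in (0, 1, 3, 10, 100):
            tree = GiniTreeClassifier(max_splits=budget).fit(X, y)
            acc = (tree.predict(X) == y).mean()
            assert acc >= prev - 1e-12
            assert tree.n_splits_ <= budget
            prev = acc
        assert prev == 1.0  # unlimited-enough budget, consistent labels

    def test_matches_sklearn_on_separable_data(self, rng):
        """Cross-check: on cleanly separable blobs both trees are perfect."""
        X = np.vstack([rng.normal(-2, 0.4, (40, 3)), rng.normal(2, 0.4, (40, 3))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        ours = GiniTreeClassifier(max_splits=5).fit(X, y)
        ref = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
        X_new = np.vstack([rng.normal(-2, 0.4, (20, 3)), rng.normal(2, 0.4, (20, 3))])
        y_new = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert (ours.predict(X_new) == y_new).all()
        assert (ours.predict(X_new) == ref.predict(X_new)).all()

    def test_deterministic(self, small_cohort):
        from rilipred.evaluate import design_matrix

        X = design_matrix(small_cohort, "tree")
        y = small_cohort["rili"].to_numpy(int)
        a = model_to_dict(GiniTreeClassifier().fit(X, y))
        b = model_to_dict(GiniTreeClassifier().fit(X, y))
        assert a == b

    def test_rejects_missing_values(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError):
            GiniTreeClassifier().fit(X, [0, 1])


class TestKnn:
    def test_resubstitution_is_perfect_on_distinct_rows(self, train_cohort_159):
        """Zero-distance dominance: 100% on any distinct-row training set."""
        from rilipred.evaluate import design_matrix

        X = design_matrix(train_cohort_159, "knn")
        y = train_cohort_159["rili"].to_numpy(int)
        model = DistanceWeightedKNNClassifier(k=84).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_k1_nearest_label(self):
        X = np.array([[0.0], [10.0]])
        model = DistanceWeightedKNNClassifier(k=1, standardize=False).fit(X, [0, 1])
        assert model.predict([[1.0]])[0] == 0
        assert model.predict([[9.0]])[0] == 1

    def test_squared_inverse_weights_forced(self):
        """Distances 1 and 2, opposite labels: weights 1 vs 0.25."""
        X = np.array([[1.0], [-2.0]])
        model = DistanceWeightedKNNClassifier(k=2, standardize=False).fit(X, [1, 0])
        proba = model.predict_proba([[0.0]])[0]
        assert proba[1] == pytest.approx(1.0 / 1.25)
        assert model.predict([[0.0]])[0] == 1

    def test_boundary_ties_included(self):
        """Neighbours tied with the k-th distance are all admitted to the vote."""
        X = np.array([[0.0], [1.0], [1.0]])
        y = np.array([0, 1, 1])
        model = DistanceWeightedKNNClassifier(k=2, standardize=False).fit(X, y)
        proba = model.predict_proba([[0.5]])[0]
        # all three rows sit at distance 0.5; weights 4 each -> P(1) = 8/12
        assert proba[1] == pytest.approx(2.0 / 3.0)

    def test_zero_distance_majority_dominates(self):
        X = np.array([[0.0], [0.0], [0.0], [5.0]])
        y = np.array([1, 1, 0, 0])
        model = DistanceWeightedKNNClassifier(k=4, standardize=False).fit(X, y)
        assert model.predict([[0.0]])[0] == 1  # majority among zero-distance rows

    def test_dimension_mismatch(self, train_cohort_159):
        from rilipred.evaluate import design_matrix

        X = design_matrix(train_cohort_159, "knn")
        model = DistanceWeightedKNNClassifier().fit(X, train_cohort_159["rili"])
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(np.zeros((2, 3)))

    def test_matches_sklearn_inverse_square_weights(self, rng):
        """Cross-check against KNeighborsClassifier with 1/d^2 weights on
        queries that do not coincide with training points."""
        X = rng.normal(0, 1, (60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        queries = rng.normal(0, 1, (25, 4))
        ours = DistanceWeightedKNNClassifier(k=7, standardize=False).fit(X, y)
        ref = KNeighborsClassifier(
            n_neighbors=7, weights=lambda d: 1.0 / d**2, metric="euclidean"
        ).fit(X, y)
        np.testing.assert_array_equal(ours.predict(queries), ref.predict(queries))


class TestKernelLogistic:
    def test_map_dimension_is_115_by_default(self, small_cohort):
        from rilipred.evaluate import design_matrix

        X = design_matrix(small_cohort, "kernel")
        y = small_cohort["rili"].to_numpy(int)
        model = RandomFeatureKernelLogistic().fit(X, y)
        assert model.transform(X).shape == (len(small_cohort), 115)
        assert model.coef_.shape == (115,)
        assert model.get_params()["reg_lambda"] == 0.55035
        assert model.get_params()["max_iter"] == 1000

    def test_separable_blobs_holdout(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (100, 2)), rng.normal(2, 0.5, (100, 2))])
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        perm = rng.permutation(200)
        train, test = perm[:140], perm[140:]
        model = RandomFeatureKernelLogistic(random_state=3).fit(X[train], y[train])
        acc = (model.predict(X[test]) == y[test]).mean()
        assert acc >= 0.95

    def test_ridge_limit_shrinks_to_majority(self, small_cohort):
        from rilipred.evaluate import design_matrix

        X = design_matrix(small_cohort, "kernel")
        y = small_cohort["rili"].to_numpy(int)
        model = RandomFeatureKernelLogistic(reg_lambda=1e6, random_state=0).fit(X, y)
        assert np.linalg.norm(model.coef_) < 1e-3
        majority = int(np.bincount(y).argmax())
        assert (model.predict(X) == majority).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            RandomFeatureKernelLogistic().fit(np.zeros((5, 2)), np.ones(5, int))

    def test_random_map_approximates_gaussian_kernel(self, rng):
        """At D = 10^4 the cosine feature inner product is within 0.05 of
        exp(-||x-x'||^2 / (2 sigma^2)) on random pairs."""
        X = rng.normal(0, 1, (12, 5))
        model = RandomFeatureKernelLogistic(
            n_components=10_000, random_state=9, standardize=False, max_iter=0
        )
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        model.fit(X, y)
        Z = model.transform(X)
        sigma = model.kernel_scale_
        G = Z @ Z.T
        for i in range(12):
            for j in range(12):
                exact = np.exp(-np.sum((X[i] - X[j]) ** 2) / (2 * sigma**2))
                assert abs(G[i, j] - exact) < 0.05

    def test_deterministic_given_seed(self, small_cohort):
        from rilipred.evaluate import design_matrix

        X = design_matrix(small_cohort, "kernel")
        y = small_cohort["rili"].to_numpy(int)
        a = RandomFeatureKernelLogistic(random_state=5).fit(X, y)
        b = RandomFeatureKernelLogistic(random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    def test_newton_matches_sklearn_unregularized_logistic(self, rng):
        """With an identity 'map' surrogate (tiny lambda), the Newton solver
        agrees with sklearn LogisticRegression on the same design."""
        X = rng.normal(0, 1, (80, 3))
        y = (X @ np.array([1.0, -2.0, 0.5]) + 0.3 * rng.normal(size=80) > 0).astype(int)
        lam = 1e-4
        model = RandomFeatureKernelLogistic(
            n_components=50, reg_lambda=lam, random_state=2
        ).fit(X, y)
        Z = model.transform(X)
        # mean-loss + lam/2 ||w||^2 is sklearn's objective with C = 1/(n*lam)
        ref = LogisticRegression(C=1.0 / (80 * lam), max_iter=5000, tol=1e-10).fit(Z, y)
        ours_p = model.predict_proba(X)[:, 1]
        ref_p = ref.predict_proba(Z)[:, 1]
        np.testing.assert_allclose(ours_p, ref_p, atol=5e-3)


class TestSerialization:
    @pytest.mark.parametrize("name", ["tree", "knn", "kernel", "hpf"])
    def test_round_trip_preserves_predictions(self, name, small_cohort, tmp_path):
        from rilipred.evaluate import design_matrix, make_model

        X = design_matrix(small_cohort, name)
        y = small_cohort["rili"].to_numpy(int)
        model = make_model(name).fit(X, y)
        path = tmp_path / f"{name}.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown model type"):
            model_from_dict({"type": "mystery"})
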