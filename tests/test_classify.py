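"""Split, PCA, classifiers, LOO-CV grid search and external validation."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from vigorspec.classify import (
    GridSpec,
    SplitSpec,
    default_grid,
    external_validate,
    fit_classifier,
    fit_pca,
    grid_search,
    loo_cv_accuracy,
    predict,
    project,
    sample_matrix,
    split_dataset,
    train_classifier,
    _KNN,
    _QDA,
)
from vigorspec.preprocess import AveragedSample


def make_samples(X, labels, band="UV", prefix="s"):
    grid = np.arange(X.shape[1], dtype=float)
    return [
        AveragedSample(f"{prefix}{i:03d}", "Marandu", label, band, grid, row)
        for i, (row, label) in enumerate(zip(X, labels))
    ]


def gaussian_classes(n_per_class=60, dim=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 1.0, (n_per_class, dim)),
        rng.normal(sep, 1.0, (n_per_class, dim)),
    ])
    y = np.array(["HV"] * n_per_class + ["LV"] * n_per_class)
    return X, y


class TestSplit:
    def test_default_split_is_90_45_45_plus_30_15_15(self):
        X, y = gaussian_classes(60, dim=3)
        samples = make_samples(X, y)
        train, val = split_dataset(samples, SplitSpec(seed=4))
        assert len(train) == 90 and len(val) == 30
        assert sum(s.vigor == "HV" for s in train) == 45
        assert sum(s.vigor == "HV" for s in val) == 15

    def test_partition_and_determinism(self):
        X, y = gaussian_classes(40, dim=2)
        samples = make_samples(X, y)
        spec = SplitSpec(seed=8)
        train1, val1 = split_dataset(samples, spec)
        train2, val2 = split_dataset(samples, spec)
        ids = lambda group: [s.sample_id for s in group]
        assert ids(train1) == ids(train2) and ids(val1) == ids(val2)
        assert set(ids(train1)) | set(ids(val1)) == set(ids(samples))
        assert set(ids(train1)) & set(ids(val1)) == set()

    def test_insufficient_class_counts_rejected(self):
        X, y = gaussian_classes(10, dim=2)
        with pytest.raises(ValueError, match="needs"):
            split_dataset(make_samples(X, y), SplitSpec())

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(n_validation=30, n_hv=10, n_lv=15)


class TestPCA:
    def test_rank_one_two_samples(self):
        model = fit_pca(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]]))
        assert model.n_components == 1
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_reconstruction(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 8))
        model = fit_pca(X)
        np.testing.assert_allclose(model.components_ @ model.components_.T,
                                   np.eye(model.n_components), atol=1e-10)
        Z = project(model, X, model.n_components)
        np.testing.assert_allclose(Z @ model.components_ + model.mean_, X, atol=1e-8)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5, 0.2])
        model = fit_pca(X)
        eigvals, eigvecs = np.linalg.eigh(np.cov(X, rowvar=False, ddof=1))
        eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
        np.testing.assert_allclose(model.explained_variance_, eigvals[:model.n_components],
                                   rtol=1e-8)
        np.testing.assert_allclose(model.explained_variance_ratio_,
                                   eigvals[:model.n_components] / eigvals.sum(), rtol=1e-8)
        for k in range(model.n_components):
            cosine = abs(model.components_[k] @ eigvecs[:, k])
            assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(7)
        model = fit_pca(rng.normal(size=(12, 5)))
        for row in model.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_variance_ratios_non_increasing_and_bounded(self):
        rng = np.random.default_rng(9)
        model = fit_pca(rng.normal(size=(20, 10)))
        ratios = model.explained_variance_ratio_
        assert np.all(np.diff(ratios) <= 1e-12)
        assert np.all((ratios >= 0) & (ratios <= 1)) and ratios.sum() <= 1 + 1e-9

    def test_projecting_the_mean_gives_zero_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 5))
        model = fit_pca(X)
        np.testing.assert_allclose(project(model, X.mean(axis=0), 3), 0.0, atol=1e-10)

    def test_projection_is_an_isometry_on_all_components(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 6))
        model = fit_pca(X)
        Z = project(model, X, model.n_components)
        np.testing.assert_allclose(np.linalg.norm(Z, axis=1),
                                   np.linalg.norm(X - model.mean_, axis=1), rtol=1e-8)

    def test_score_variances_equal_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        model = fit_pca(X)
        Z = project(model, X, model.n_components)
        np.testing.assert_allclose(Z.var(axis=0, ddof=1), model.explained_variance_,
                                   rtol=1e-8)

    def test_grid_mismatch_rejected(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            project(model, np.zeros((2, 7)), 1)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_pca(np.ones((5, 3)))


class TestClassifiers:
    def test_knn_k1_reproduces_training_labels(self):
        X, y = gaussian_classes(10, dim=3, seed=1)
        est = fit_classifier("knn", X, y, 1)
        assert np.array_equal(predict(est, X), y)

    def test_knn_vote_tie_goes_to_nearest_neighbour(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["HV", "LV"])
        est = _KNN(2).fit(X, y)
        assert predict(est, np.array([[0.1]]))[0] == "HV"
        assert predict(est, np.array([[0.9]]))[0] == "LV"

    def test_knn_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            _KNN(5).fit(np.zeros((3, 2)), np.array(["HV", "LV", "HV"]))

    def test_qda_r0_matches_sklearn(self):
        X, y = gaussian_classes(25, dim=4, sep=2.0, seed=6)
        ours = _QDA(0.0).fit(X, y)
        theirs = QuadraticDiscriminantAnalysis(reg_param=0.0).fit(X, y)
        rng = np.random.default_rng(10)
        queries = rng.normal(1.0, 2.0, size=(50, 4))
        assert np.array_equal(predict(ours, queries), theirs.predict(queries))

    def test_qda_singular_covariance_needs_regularization(self):
        # rank-deficient class covariance: 3 samples in 4 dimensions
        X = np.vstack([np.eye(4)[:3], 5.0 + np.eye(4)[:3]])
        y = np.array(["HV"] * 3 + ["LV"] * 3)
        with pytest.raises(ValueError, match="regularization"):
            _QDA(0.0).fit(X, y)
        est = _QDA(0.1).fit(X, y)  # shrinkage restores positive-definiteness
        assert set(predict(est, X)) <= {"HV", "LV"}

    def test_lda_matches_closed_form_pooled_discriminant(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                      [4.0, 4.0], [5.0, 4.0], [4.0, 5.0]])
        y = np.array(["HV", "HV", "HV", "LV", "LV", "LV"])
        est = fit_classifier("lda", X, y, "svd")
        mu0, mu1 = X[:3].mean(axis=0), X[3:].mean(axis=0)
        pooled = (np.cov(X[:3], rowvar=False, ddof=1) * 2 +
                  np.cov(X[3:], rowvar=False, ddof=1) * 2) / 4
        w = np.linalg.solve(pooled, mu1 - mu0)
        b = -0.5 * (mu0 + mu1) @ w  # equal priors
        queries = np.array([[0.5, 0.5], [2.0, 2.0], [4.5, 4.5], [2.3, 2.2], [1.9, 2.0]])
        expected = np.where(queries @ w + b > 0, "LV", "HV")
        assert np.array_equal(predict(est, queries), expected)

    def test_lda_solvers_agree(self):
        X, y = gaussian_classes(20, dim=5, sep=1.5, seed=11)
        rng = np.random.default_rng(1)
        queries = rng.normal(0.75, 1.5, size=(40, 5))
        preds = [predict(fit_classifier("lda", X, y, solver), queries)
                 for solver in ("svd", "lsqr", "eigen")]
        assert np.array_equal(preds[0], preds[1])
        assert np.array_equal(preds[0], preds[2])

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_classifier("knn", np.zeros((3, 2)), np.array(["HV"] * 3), 1)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_classifier("forest", np.zeros((4, 2)),
                           np.array(["HV", "LV", "HV", "LV"]), 1)


class TestLOOCV:
    def test_separated_clusters_are_perfect_with_knn1(self):
        X, y = gaussian_classes(10, dim=3, sep=20.0, seed=13)
        assert loo_cv_accuracy(X, y, "knn", 1) == 1.0

    @pytest.mark.parametrize("algorithm,hyper", [
        ("knn", 3), ("lda", "svd"), ("qda", 0.1), ("svm", 1.0),
    ])
    def test_equals_independent_explicit_loop(self, algorithm, hyper):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(12, 3))
        X[6:] += 1.0  # moderate overlap so accuracy is non-trivial
        y = np.array(["HV"] * 6 + ["LV"] * 6)
        # independently coded hold-one-out loop
        correct = 0
        for i in range(12):
            keep = [j for j in range(12) if j != i]
            est = fit_classifier(algorithm, X[keep], y[keep], hyper)
            correct += int(predict(est, X[i])[0] == y[i])
        assert loo_cv_accuracy(X, y, algorithm, hyper) == correct / 12


class TestGridSearch:
    def test_map_shapes_match_default_grids(self):
        assert default_grid("knn").hyper_grid == tuple(range(1, 46))
        assert default_grid("lda").hyper_grid == ("svd", "lsqr", "eigen")
        assert default_grid("qda").hyper_grid == (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
        assert default_grid("svm").hyper_grid == (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)
        for alg in ("knn", "lda", "qda", "svm"):
            assert default_grid(alg).pc_grid == tuple(range(1, 21))

    def test_ties_break_to_fewest_pcs_then_first_hyperparameter(self):
        X, y = gaussian_classes(12, dim=6, sep=25.0, seed=14)
        spec = GridSpec("knn", pc_grid=(1, 2, 3), hyper_grid=(1, 3, 5))
        gsmap = grid_search(X, y, spec)
        assert np.all(gsmap.accuracy == 1.0)
        assert gsmap.chosen == (1, 1)

    def test_chosen_cell_attains_the_maximum(self):
        X, y = gaussian_classes(15, dim=5, sep=1.0, seed=15)
        spec = GridSpec("qda", pc_grid=(1, 2, 4), hyper_grid=(0.0, 0.2))
        gsmap = grid_search(X, y, spec)
        a = gsmap.pc_grid.index(gsmap.chosen[0])
        b = gsmap.hyper_grid.index(gsmap.chosen[1])
        assert gsmap.accuracy[a, b] == gsmap.best_accuracy
        assert np.all(gsmap.accuracy <= gsmap.best_accuracy)

    def test_lda_solver_columns_identical(self):
        X, y = gaussian_classes(15, dim=6, sep=1.2, seed=16)
        gsmap = grid_search(X, y, GridSpec("lda", pc_grid=(1, 3, 5)))
        assert gsmap.accuracy.shape == (3, 3)
        np.testing.assert_allclose(gsmap.accuracy[:, 1], gsmap.accuracy[:, 0])
        np.testing.assert_allclose(gsmap.accuracy[:, 2], gsmap.accuracy[:, 0])

    def test_pca_in_fold_variant_runs_and_stays_close(self):
        X, y = gaussian_classes(12, dim=8, sep=6.0, seed=17)
        spec = GridSpec("lda", pc_grid=(1, 2), hyper_grid=("svd",))
        fast = grid_search(X, y, spec, pca_in_fold=False)
        strict = grid_search(X, y, spec, pca_in_fold=True)
        assert np.all(np.abs(fast.accuracy - strict.accuracy) <= 0.25)

    def test_excessive_pc_request_rejected(self):
        X, y = gaussian_classes(4, dim=3, seed=18)
        with pytest.raises(ValueError, match="PCs"):
            grid_search(X, y, GridSpec("knn", pc_grid=(10,), hyper_grid=(1,)))


class TestExternalValidation:
    def build(self, seed=19):
        X, y = gaussian_classes(25, dim=4, sep=6.0, seed=seed)
        samples = make_samples(X, y)
        train, val = split_dataset(samples, SplitSpec(20, 10, 10, seed=1))
        model = train_classifier(train, "lda", 2, "svd")
        return model, train, val

    def test_confusion_counts_sum_to_validation_size(self):
        model, _, val = self.build()
        report = external_validate(model, val)
        assert report.confusion.sum() == len(val) == 20
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum())

    def test_leakage_is_detected(self):
        model, train, _ = self.build()
        with pytest.raises(ValueError, match="leakage"):
            external_validate(model, train[:5])

    def test_flipped_labels_score_zero(self):
        model, _, val = self.build()
        flipped = [
            AveragedSample(s.sample_id, s.cultivar,
                           "HV" if s.vigor == "LV" else "LV",
                           s.band, s.wavelengths, s.intensities)
            for s in val
        ]
        base = external_validate(model, val)
        inverse = external_validate(model, flipped)
        assert base.accuracy + inverse.accuracy == pytest.approx(1.0)
        if base.accuracy == 1.0:
            assert inverse.accuracy == 0.0

    def test_model_independent_of_validation_permutation(self):
        model, _, val = self.build()
        forward = external_validate(model, val)
        backward = external_validate(model, list(reversed(val)))
        assert forward.accuracy == backward.accuracy
        assert forward.confusion.tolist() == backward.confusion.tolist()
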