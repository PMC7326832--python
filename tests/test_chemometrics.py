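"""PCA, the OPLS-DA recursion and Mahalanobis classification."""

import numpy as np
import pytest

from reims.chemometrics import (
    classify_mahalanobis,
    fit_oplsda,
    fit_pca,
    load_model,
    project,
    save_model,
)
from reims.spectra import BinAxis, FeatureMatrix

from .conftest import random_logged_matrix


def logged_matrix(X, labels, patient_ids=None):
    n, p = X.shape
    return FeatureMatrix(
        axis=BinAxis(600.0, 600.0 + p, 1.0),
        X=X,
        spectrum_ids=[f"s{i}" for i in range(n)],
        patient_ids=patient_ids or [f"p{i}" for i in range(n)],
        sample_ids=[f"p{i}-a" for i in range(n)],
        tissue_labels=list(labels),
        stage="logged",
    )


def one_hot_centered(labels):
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y - Y.mean(axis=0)


class TestPca:
    def test_collinear_data_explained_by_one_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, [1.0, 2.0, -0.5, 0.0]) + 3.0
        m = logged_matrix(np.abs(X), ["normal", "tumour"] * 5)
        model = fit_pca(m, k=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.exponential(1.0, size=(10, 6))
        m = logged_matrix(X, ["normal", "tumour"] * 5)
        model = fit_pca(m, k=6)
        Xc = X - model.mean
        recon = model.transform(X) @ model.loadings
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        """Dense eigensolver oracle on the covariance matrix."""
        rng = np.random.default_rng(1)
        X = rng.exponential(1.0, size=(10, 6))
        m = logged_matrix(X, ["normal", "tumour"] * 5)
        model = fit_pca(m, k=4)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio, eig[:4] / eig.sum(), atol=1e-10
        )

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        m = logged_matrix(rng.exponential(1.0, size=(12, 7)), ["normal", "tumour"] * 6)
        model = fit_pca(m, k=5)
        np.testing.assert_allclose(
            model.loadings @ model.loadings.T, np.eye(5), atol=1e-8
        )

    def test_k_out_of_range(self):
        rng = np.random.default_rng(3)
        m = logged_matrix(rng.exponential(1.0, size=(5, 4)), ["normal", "tumour", "normal", "tumour", "normal"])
        with pytest.raises(ValueError, match="out of range"):
            fit_pca(m, k=5)


class TestOplsdaAgainstPlsOracle:
    def test_no_orth_components_match_nipals_pls(self):
        """With n_orth=0 the predictive scores equal those of an independent
        NIPALS PLS-DA reference, up to component sign."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(123)
        for trial in range(20):
            n = int(rng.integers(12, 30))
            X = rng.normal(size=(n, 8)) ** 2
            labels = [["adenoma", "normal", "tumour"][i % 3] for i in range(n)]
            m = logged_matrix(X, labels)
            model = fit_oplsda(m, n_pred=2, n_orth=0)
            Y = np.zeros((n, 3))
            for i, lab in enumerate(labels):
                Y[i, sorted(set(labels)).index(lab)] = 1.0
            ref = PLSRegression(n_components=2, scale=False, tol=1e-18, max_iter=5000).fit(X, Y)
            for a in range(2):
                t, t_ref = model.training_scores[:, a], ref.x_scores_[:, a]
                assert min(np.abs(t - t_ref).max(), np.abs(t + t_ref).max()) < 1e-6


class TestOplsdaProperties:
    def test_orthogonal_scores_decorrelated_from_class_indicators(self):
        rng = np.random.default_rng(7)
        m = random_logged_matrix(rng, n=30, p=20)
        model = fit_oplsda(m, n_pred=2, n_orth=2)
        Yc = one_hot_centered(m.tissue_labels)
        for j in range(model.n_orth):
            t = model.orth_scores[:, j]
            for k in range(Yc.shape[1]):
                assert abs(np.corrcoef(t, Yc[:, k])[0, 1]) < 1e-6

    def test_separated_gaussian_classes_classified_perfectly(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 10))
        X[20:, 0] += 10.0  # 10 SD separation on one coordinate
        X = X - X.min() + 0.1
        labels = ["normal"] * 20 + ["tumour"] * 20
        m = logged_matrix(X, labels)
        model = fit_oplsda(m, n_pred=1, n_orth=1)
        preds = [
            classify_mahalanobis(model, m.X[i]).predicted_label for i in range(40)
        ]
        assert preds == labels

    def test_variance_decomposition_is_complete(self):
        """Total centred X variance = orthogonal + predictive + residual."""
        rng = np.random.default_rng(13)
        m = random_logged_matrix(rng, n=24, p=12)
        model = fit_oplsda(m, n_pred=2, n_orth=1)
        Xc = m.X - model.x_mean
        total = (Xc**2).sum()
        explained = 0.0
        X_work = Xc.copy()
        for j in range(model.n_orth):
            t = X_work @ model.W_orth[j]
            X_work = X_work - np.outer(t, model.P_orth[j])
            explained += (np.outer(t, model.P_orth[j]) ** 2).sum()
        for a in range(model.n_pred):
            t = X_work @ model.W_pred[a]
            X_work = X_work - np.outer(t, model.P_pred[a])
            explained += (np.outer(t, model.P_pred[a]) ** 2).sum()
        residual = (X_work**2).sum()
        # score vectors are mutually orthogonal, so Pythagoras applies
        assert total == pytest.approx(explained + residual, rel=1e-6)

    def test_class_with_single_row_rejected(self):
        rng = np.random.default_rng(17)
        X = rng.exponential(1.0, size=(5, 4))
        m = logged_matrix(X, ["normal", "normal", "tumour", "tumour", "adenoma"])
        with pytest.raises(ValueError, match="< 2 rows"):
            fit_oplsda(m)

    def test_refit_is_bit_for_bit_identical(self):
        rng = np.random.default_rng(19)
        m = random_logged_matrix(rng, n=21, p=9)
        a = fit_oplsda(m, n_orth=1)
        b = fit_oplsda(m, n_orth=1)
        np.testing.assert_array_equal(a.training_scores, b.training_scores)
        np.testing.assert_array_equal(a.W_pred, b.W_pred)


class TestProjection:
    def test_training_rows_reproduce_training_scores(self):
        rng = np.random.default_rng(23)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=1)
        np.testing.assert_allclose(
            project(model, m.X), model.training_scores, atol=1e-8
        )

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(29)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=1)
        np.testing.assert_allclose(project(model, model.x_mean), 0.0, atol=1e-12)

    def test_projection_is_affine(self):
        rng = np.random.default_rng(31)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=1)
        x1, x2 = m.X[0], m.X[1]
        for alpha in (0.25, 0.5, 0.9):
            lhs = project(model, alpha * x1 + (1 - alpha) * x2)
            rhs = alpha * project(model, x1) + (1 - alpha) * project(model, x2)
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(37)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m)
        with pytest.raises(ValueError, match="training bins"):
            project(model, np.ones(9))


class TestMahalanobis:
    def test_point_at_centroid_has_zero_distance(self):
        rng = np.random.default_rng(41)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=0)
        # invert the projection at a centroid via least squares on W_pred
        c = model.class_centroids["normal"]
        pred = classify_mahalanobis(model, model.x_mean + np.linalg.lstsq(
            _projection_matrix(model).T, c, rcond=None
        )[0])
        assert pred.distances["normal"] == pytest.approx(0.0, abs=1e-6)
        assert pred.predicted_label == "normal"

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(43)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=0)
        model.pooled_cov = np.eye(2)
        x = m.X[3]
        pred = classify_mahalanobis(model, x)
        t = project(model, x)
        for c, cent in model.class_centroids.items():
            assert pred.distances[c] == pytest.approx(
                float(np.linalg.norm(t - cent)), rel=1e-10
            )

    def test_exact_tie_broken_lexicographically(self):
        rng = np.random.default_rng(47)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=0)
        model.pooled_cov = np.eye(2)
        # place centroids symmetrically about the origin score
        model.class_centroids = {
            "adenoma": np.array([1.0, 0.0]),
            "tumour": np.array([-1.0, 0.0]),
        }
        model.class_labels = ["adenoma", "tumour"]
        pred = classify_mahalanobis(model, model.x_mean)  # scores (0, 0)
        assert pred.predicted_label == "adenoma"


def _projection_matrix(model):
    """Matrix M with project(x) = (x - mean) @ M, for n_orth = 0 models."""
    p = model.x_mean.size
    M = np.zeros((p, model.n_pred))
    I = np.eye(p)
    X = I.copy()
    for a in range(model.n_pred):
        t = X @ model.W_pred[a]
        M[:, a] = t
        X = X - np.outer(t, model.P_pred[a])
    return M


class TestModelArchive:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(53)
        m = random_logged_matrix(rng, n=18, p=8)
        model = fit_oplsda(m, n_pred=2, n_orth=1)
        path = tmp_path / "model.json"
        save_model(model, path, config_hash="abc")
        loaded = load_model(path)
        x = m.X[5]
        a, b = classify_mahalanobis(model, x), classify_mahalanobis(loaded, x)
        assert a.predicted_label == b.predicted_label
        for c in a.distances:
            assert a.distances[c] == pytest.approx(b.distances[c], rel=1e-12)

    def test_rejects_non_archive(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{}")
        with pytest.raises(ValueError, match="not a model archive"):
            load_model(path)
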