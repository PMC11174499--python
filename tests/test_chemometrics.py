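"""PCA, NIPALS PLS, Venetian-blinds CV, and the two-donor TSD study."""

import numpy as np
import pytest

from ramantsd import chemometrics as cm
from ramantsd.spectra import SpectraDataset


def subspace_angle(A, B):
    """Sine of the largest principal angle between column spaces,
    via the spectral norm of the projector difference."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    return np.linalg.norm(Qa @ Qa.T - Qb @ Qb.T, 2)


class TestPCA:
    def test_collinear_data_one_component(self, rng):
        t = rng.normal(0, 1, 30)
        X = np.column_stack([t, -2.0 * t])
        model = cm.pca_fit(X, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(0, 1, (12, 7))
        model = cm.pca_fit(X, 7)
        recon = model.scores @ model.loadings.T + model.train_mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(0, 1, (20, 10))
        model = cm.pca_fit(X, 4)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(4), atol=1e-8)

    def test_matches_covariance_eigensolver_oracle(self, rng):
        X = rng.normal(0, 1, (25, 6))
        model = cm.pca_fit(X, 3)
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        oracle = evecs[:, np.argsort(evals)[::-1][:3]]
        assert subspace_angle(model.loadings, oracle) < 1e-8

    def test_rank_overflow_warns(self, rng):
        X = rng.normal(0, 1, (4, 10))
        with pytest.warns(RuntimeWarning, match="rank"):
            model = cm.pca_fit(X, 8)
        assert model.n_components <= 3


class TestPLS:
    def test_single_channel_response_one_lv(self, rng):
        # orthogonal zero-mean channels: one latent variable isolates the
        # response channel (QR of a centered matrix keeps columns
        # orthogonal to the ones-vector, hence zero-mean)
        G = rng.normal(0, 1, (20, 6))
        X, _ = np.linalg.qr(G - G.mean(axis=0))
        y = 3.0 * X[:, 2]
        model = cm.pls_fit(X, y, 1)
        np.testing.assert_allclose(cm.pls_predict(model, X), y, atol=1e-8)

    def test_full_rank_equals_least_squares_oracle(self, rng):
        X = rng.normal(0, 1, (8, 5))
        y = rng.normal(0, 1, 8)
        model = cm.pls_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.regression_coefficients, beta, atol=1e-8)
        np.testing.assert_allclose(cm.pls_predict(model, X), Xc @ beta + y.mean(), atol=1e-8)

    def test_sample_duplication_invariance(self, rng):
        X = rng.normal(0, 1, (15, 9))
        y = rng.normal(0, 1, 15)
        a = cm.pls_fit(X, y, 3)
        b = cm.pls_fit(np.vstack([X, X]), np.concatenate([y, y]), 3)
        np.testing.assert_allclose(
            a.regression_coefficients, b.regression_coefficients, atol=1e-10
        )

    def test_score_orthogonality(self, rng):
        X = rng.normal(0, 1, (30, 12))
        y = X @ rng.normal(0, 1, 12) + rng.normal(0, 0.1, 30)
        model = cm.pls_fit(X, y, 4)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(G))

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(0, 1, (40, 20))
        y = X @ rng.normal(0, 1, 20) + rng.normal(0, 0.5, 40)
        mine = cm.pls_fit(X, y, 5)
        ref = sklearn_pls.PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(
            cm.pls_predict(mine, X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_predict_contracts(self, rng):
        X = rng.normal(0, 1, (10, 4))
        y = rng.normal(0, 1, 10)
        model = cm.pls_fit(X, y, 2)
        assert cm.pls_predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())
        with pytest.raises(ValueError, match="channel"):
            cm.pls_predict(model, np.zeros((2, 5)))
        with pytest.raises(ValueError, match="variance"):
            cm.pls_fit(X, np.ones(10), 2)

    def test_two_path_prediction_equivalence(self, rng):
        """Coefficient-vector prediction equals the explicit NIPALS path
        (sequential deflation scores times y-loadings)."""
        X = rng.normal(0, 1, (25, 8))
        y = rng.normal(0, 1, 25)
        model = cm.pls_fit(X, y, 3)
        Xnew = rng.normal(0, 1, (6, 8))
        Xd = Xnew - model.train_mean_x
        pred = np.full(6, model.train_mean_y)
        for a in range(model.n_lv):
            t = Xd @ model.x_weights[:, a]
            pred += t * model.y_loadings[0, a]
            Xd = Xd - np.outer(t, model.x_loadings[:, a])
        np.testing.assert_allclose(pred, cm.pls_predict(model, Xnew), atol=1e-9)


class TestClassRule:
    def test_threshold_and_tie(self):
        # identity model: response equals the single input channel
        model = cm.LatentModel(
            n_lv=1,
            x_weights=np.ones((1, 1)),
            x_loadings=np.ones((1, 1)),
            y_loadings=np.ones((1, 1)),
            x_scores=np.zeros((1, 1)),
            regression_coefficients=np.array([1.0]),
            train_mean_x=np.zeros(1),
            train_mean_y=0.0,
        )
        labels, resp = cm.plsda_classify(model, [[0.49], [0.51], [0.5]])
        assert list(labels) == ["fresh", "old", "fresh"]
        np.testing.assert_allclose(resp, [0.49, 0.51, 0.5])

    def test_classifier_never_unassigned(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = (X[:, 0] > 0).astype(float)
        model = cm.pls_fit(X, y, 2)
        labels, resp = cm.plsda_classify(model, rng.normal(0, 5, (100, 5)))
        assert set(labels) <= {"fresh", "old"}
        assert resp.shape == (100,)


class TestVenetianBlinds:
    def test_closed_form_folds(self):
        folds = cm.venetian_blinds(6, 2)
        np.testing.assert_array_equal(folds[0], [0, 2, 4])
        np.testing.assert_array_equal(folds[1], [1, 3, 5])

    @pytest.mark.parametrize("n,splits", [(10, 3), (144, 10), (7, 7)])
    def test_partition_properties(self, n, splits):
        folds = cm.venetian_blinds(n, splits)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(n))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_errors(self):
        with pytest.raises(ValueError):
            cm.venetian_blinds(3, 5)
        with pytest.raises(ValueError):
            cm.venetian_blinds(10, 1)


class TestCrossValidate:
    def test_noiseless_linear_response_recovered(self, rng):
        X = rng.normal(0, 1, (40, 5))
        y = X @ rng.normal(0, 1, 5) + 2.0
        preds = cm.cross_validate(X, y, 5, n_splits=8)
        np.testing.assert_allclose(preds, y, atol=1e-6)

    def test_cv_r2_not_above_calibration_r2(self, rng):
        """Held-out R^2 may not beat the resubstitution R^2, save rare
        noise flukes (<= 2 of 100 random datasets)."""
        violations = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (30, 8))
            y = X @ r.normal(0, 1, 8) + r.normal(0, 1.0, 30)
            model = cm.pls_fit(X, y, 3)
            cal = cm.pls_predict(model, X)
            cv = cm.cross_validate(X, y, 3, n_splits=10)
            sst = np.sum((y - y.mean()) ** 2)
            r2_cal = 1 - np.sum((y - cal) ** 2) / sst
            r2_cv = 1 - np.sum((y - cv) ** 2) / sst
            violations += r2_cv > r2_cal
        assert violations <= 2


class TestTSDStudy:
    def test_default_run_has_stated_lv_counts(self, default_study):
        _, _, results = default_study
        assert results.plsda.n_lv == 3
        assert results.plsr.n_lv == 5

    def test_calibration_beats_cv_beats_zero(self, default_study):
        _, _, results = default_study
        assert results.r_squared("calibration") >= results.r_squared("cv") >= 0.0

    def test_boundary_hours_rejected(self, default_study):
        _, _, results = default_study
        train = results.study.train
        bad = SpectraDataset([s.copy() for s in train.spectra[:5]])
        for s in bad.spectra:
            s.meta.hour = 80.0  # strictly inside (72, 96)
        with pytest.raises(ValueError, match="boundary"):
            cm.TSDStudy(bad, results.study.test)

    def test_pca_hour_structure_early_hours_separate_more(self, default_study):
        """Donor-1 PCA scores: early-hour class centroids are mutually
        farther apart than late-hour centroids."""
        _, _, results = default_study
        train = results.study.train
        model = cm.pca_fit(train.matrix, 4)
        hours = train.hours

        def mean_pairwise_centroid_distance(hour_set):
            cents = [model.scores[hours == h].mean(axis=0) for h in hour_set]
            d = [
                np.linalg.norm(a - b)
                for i, a in enumerate(cents)
                for b in cents[i + 1:]
            ]
            return np.mean(d)

        early = mean_pairwise_centroid_distance([1.0, 5.0, 9.0, 24.0, 48.0])
        late = mean_pairwise_centroid_distance([96.0, 120.0, 144.0, 168.0, 236.0, 336.0])
        assert early > late

    def test_label_permutation_destroys_external_accuracy(self, default_study):
        """Permuting calibration hours leaves external classification at
        chance level (mean accuracy within 0.35-0.65 over 50 permutations)."""
        _, _, results = default_study
        train, test = results.study.train, results.study.test
        X, Xt = train.matrix, test.matrix
        true_test = (test.hours >= 96.0).astype(float)
        rng_perm = np.random.default_rng(2024)
        accs = []
        for _ in range(50):
            c = rng_perm.permutation((train.hours >= 96.0).astype(float))
            model = cm.pls_fit(X, c, 3)
            resp = cm.pls_predict(model, Xt)
            accs.append(np.mean((resp > 0.5) == (true_test == 1.0)))
        assert 0.35 < np.mean(accs) < 0.65
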