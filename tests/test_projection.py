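import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from mycometab.projection import (
    classical_mds,
    compute_vip,
    cross_validate_q2,
    encode_classes,
    fit_opls,
    fit_oplsda,
    fit_pca,
    fit_pls,
    fit_plsda,
    permutation_significance,
)


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.arange(5.0)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        model = fit_pca(u @ v, n_comp=2)
        assert model.r2x[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 8))
        model = fit_pca(X, n_comp=5)
        Xc = X - X.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(5):
            v = Vt[a]
            sign = np.sign(v @ model.P[:, a])
            assert np.max(np.abs(model.P[:, a] - sign * v)) <= 1e-8
        assert np.allclose(model.r2x, s[:5] ** 2 / np.sum(s**2), atol=1e-10)

    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        X2 = np.vstack([X, X[2]])
        model = fit_pca(X2, n_comp=2)
        assert np.allclose(model.T[2], model.T[-1], atol=1e-10)

    def test_ncomp_bounds(self):
        with pytest.raises(ValueError):
            fit_pca(np.eye(4), n_comp=4)


class TestMds:
    def test_euclidean_configuration_matches_pca(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        emb = classical_mds(X=X, n_dim=3, distance_kind="euclidean")
        pca = fit_pca(X, n_comp=3)
        _, residual = orthogonal_procrustes(emb.coordinates, pca.T)
        diff = emb.coordinates @ orthogonal_procrustes(emb.coordinates, pca.T)[0] - pca.T
        assert np.sqrt(np.sum(diff**2)) <= 1e-6

    def test_identical_samples_coincide(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0]])
        emb = classical_mds(X=X, n_dim=2)
        assert np.allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-10)

    def test_right_triangle_distances_reproduced(self):
        D = np.array([[0.0, 3.0, 5.0], [3.0, 0.0, 4.0], [5.0, 4.0, 0.0]])
        emb = classical_mds(D=D, n_dim=2)
        rec = squareform(pdist(emb.coordinates))
        assert np.allclose(rec, D, atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(D=np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_eigenvalues_nonincreasing(self):
        rng = np.random.default_rng(3)
        emb = classical_mds(X=rng.normal(size=(8, 5)), n_dim=2)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-10)


class TestPls:
    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls(X, y, n_comp=1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        ref = Xc.T @ yc
        ref /= np.linalg.norm(ref)
        cos = abs(float(ref @ model.W[:, 0]))
        assert cos >= 1 - 1e-10

    def test_noise_free_response_fully_explained(self):
        # with orthogonal columns the first component is exactly the response
        rng = np.random.default_rng(5)
        G = rng.normal(size=(15, 6))
        X, _ = np.linalg.qr(G - G.mean(axis=0))  # centered orthonormal columns
        model = fit_pls(X, X[:, 2], n_comp=1)
        assert model.r2y == pytest.approx(1.0, abs=1e-10)

    def test_r2y_nondecreasing_in_components(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=20)
        r2 = [fit_pls(X, y, n_comp=a).r2y for a in (1, 2, 3, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_permuted_response_fits_worse(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10)
        r_true = fit_pls(X, y, n_comp=1).r2y
        r_perm = fit_pls(X, y[rng.permutation(30)], n_comp=1).r2y
        assert r_perm < r_true

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.random.default_rng(8).normal(size=(5, 3)), np.ones(5), 1)

    def test_prediction_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 7))
        y = X @ rng.normal(size=7) + 0.1 * rng.normal(size=15)
        perm = rng.permutation(7)
        a = fit_pls(X, y, n_comp=2).predict(X)
        b = fit_pls(X[:, perm], y, n_comp=2).predict(X[:, perm])
        assert np.allclose(a, b, atol=1e-8)


class TestOpls:
    def test_orthogonal_scores_uncorrelated_with_response(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=25)
        model = fit_opls(X, y, n_orth=2)
        yc = y - y.mean()
        for a in range(model.n_orth):
            t_o = model.T_o[:, a]
            assert abs(t_o @ yc) <= 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)

    def test_separable_construction(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=40)
        z = rng.normal(size=40)
        z -= z @ y / (y @ y) * y  # exactly orthogonal to y
        X = np.column_stack([y, z])
        model = fit_opls(X, y, n_orth=1)
        w = np.abs(model.W[:, 0])
        w_o = np.abs(model.W_o[:, 0])
        assert w[0] > w[1] and w_o[1] > w_o[0]

    def test_zero_orth_equals_single_component_pls(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(18, 9))
        y = rng.normal(size=18)
        opls = fit_opls(X, y, n_orth=0)
        pls = fit_pls(X, y, n_comp=1)
        assert np.allclose(opls.W[:, 0], pls.W[:, 0], atol=1e-10)
        assert opls.r2y == pytest.approx(pls.r2y, abs=1e-10)

    def test_planted_direction_recovered_under_structured_noise(self):
        rng = np.random.default_rng(13)
        n, j = 300, 30
        beta = np.zeros(j)
        beta[:5] = 1.0
        beta /= np.linalg.norm(beta)
        t_y = rng.normal(size=n)
        orth_dir = np.zeros(j)
        orth_dir[5:10] = 1.0
        orth_dir /= np.linalg.norm(orth_dir)
        X = np.outer(t_y, beta) + 3.0 * np.outer(rng.normal(size=n), orth_dir)
        X += 0.05 * rng.normal(size=(n, j))
        model = fit_opls(X, t_y, n_orth=1)
        cos = abs(float(model.W[:, 0] @ beta))
        assert cos >= 0.95

    def test_multicolumn_response_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="single-column"):
            fit_opls(rng.normal(size=(8, 4)), rng.normal(size=(8, 2)))


def test_encode_classes_examples():
    Y = encode_classes(["a", "b", "a"])
    assert Y.to_numpy().tolist() == [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
    assert list(Y.columns) == ["a", "b"]
    assert encode_classes(["x", "y", "z"]).shape[1] == 3
    with pytest.raises(ValueError):
        encode_classes(["only"])


def test_oplsda_sign_convention_points_to_positive_class():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(12, 6))
    labels = ["ctrl"] * 6 + ["treat"] * 6
    X[6:, 0] += 3.0  # feature 0 higher in 'treat'
    model = fit_oplsda(X, labels, positive_class="treat", n_orth=0)
    assert model.P[0, 0] > 0


class TestQ2:
    def test_noise_free_linear_relation(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5)
        q2 = cross_validate_q2(X, y, {"kind": "PLS", "n_comp": 3}, n_folds=7, seed=0)
        assert q2 >= 0.99

    def test_null_relation_not_predictive(self):
        rng = np.random.default_rng(17)
        q2s = []
        for _ in range(30):
            X = rng.normal(size=(15, 10))
            y = rng.normal(size=15)
            q2s.append(cross_validate_q2(X, y, {"kind": "PLS", "n_comp": 1}, 5, seed=1))
        assert np.mean(q2s) <= 0.0

    def test_leave_one_out_path_is_deterministic(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        a = cross_validate_q2(X, y, {"kind": "PLS", "n_comp": 1}, n_folds=9, seed=5)
        b = cross_validate_q2(X, y, {"kind": "PLS", "n_comp": 1}, n_folds=9, seed=99)
        # LOO folds are identical whatever the shuffle seed (up to fold order)
        assert a == pytest.approx(b, rel=1e-10)


class TestPermutation:
    def test_strong_signal_reaches_floor_p(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(30, 5))
        y = X[:, 0]
        p_r2, p_q2 = permutation_significance(X, y, {"kind": "PLS", "n_comp": 1}, n_perm=19, seed=0)
        assert p_r2 == pytest.approx(1 / 20)
        assert p_q2 == pytest.approx(1 / 20)

    def test_p_values_are_valid_probabilities(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        p_r2, p_q2 = permutation_significance(X, y, {"kind": "PLS", "n_comp": 1}, n_perm=19, seed=0)
        for p in (p_r2, p_q2):
            assert 1 / 20 <= p <= 1.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_significance(np.eye(5), np.arange(5.0), {}, n_perm=5)


class TestVip:
    def test_mean_square_is_one(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            X = rng.normal(size=(15, 11))
            y = rng.normal(size=15)
            model = fit_pls(X, y, n_comp=3)
            assert float(np.mean(model.vip**2)) == pytest.approx(1.0, abs=1e-8)
            om = fit_opls(X, y, n_orth=1)
            assert float(np.mean(om.vip**2)) == pytest.approx(1.0, abs=1e-8)

    def test_identical_features_share_unit_vip(self):
        rng = np.random.default_rng(22)
        col = rng.normal(size=12)
        X = np.tile(col[:, None], (1, 6))
        y = col + 0.01 * rng.normal(size=12)
        model = fit_pls(X, y, n_comp=1)
        assert np.allclose(model.vip, 1.0, atol=1e-8)

    def test_informative_feature_has_top_vip_above_one(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(24, 20))
        y = X[:, 7] + 0.1 * rng.normal(size=24)
        model = fit_opls(X, y, n_orth=0)
        assert int(np.argmax(model.vip)) == 7
        assert model.vip[7] > 1.0

    def test_pca_has_no_vip(self):
        model = fit_pca(np.random.default_rng(24).normal(size=(6, 4)), 2)
        with pytest.raises(ValueError):
            compute_vip(model)


def test_plsda_multiclass_shapes():
    rng = np.random.default_rng(25)
    X = rng.normal(size=(12, 7))
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    model = fit_plsda(X, labels, n_comp=2)
    assert model.T.shape == (12, 2)
    assert model.C.shape == (3, 2)
    assert model.classes == ["a", "b", "c"]
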