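import numpy as np
import pytest

from risyng.cluster import RISynG, risyng_run
from risyng.evaluation import adjusted_rand
from risyng.integration import (
    canonicalize_labels,
    cluster_accretive,
    gram_schmidt,
    integrate,
    orthonorm_weight,
    project_basis,
    residual,
)
from risyng.representations import build_representations
from risyng.simulate import SyntheticSpec, ViewSpec, make_multiview
from risyng.synergy import SynergyView, embed


def _orthobasis(rng, n, k):
    Q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return Q


def _sv(name, U):
    n, k = U.shape
    return SynergyView(name, np.eye(n), 0.5, U, 0.5, np.zeros(n, dtype=int))


class TestProjectBasis:
    def test_orthogonal_input_projects_to_zero(self, rng):
        Q = _orthobasis(rng, 8, 4)
        b, U = Q[:, :2], Q[:, 2:]
        np.testing.assert_allclose(project_basis(b, U), 0.0, atol=1e-12)

    def test_projecting_basis_onto_itself_is_identity(self, rng):
        b = _orthobasis(rng, 6, 2)
        np.testing.assert_allclose(project_basis(b, b), b, atol=1e-12)

    def test_matches_triple_product_loop_oracle(self, rng):
        b = _orthobasis(rng, 6, 2)
        U = rng.normal(size=(6, 2))
        P = project_basis(b, U)
        expected = np.zeros((6, 2))
        for i in range(6):
            for j in range(2):
                expected[i, j] = sum(
                    b[i, a] * b[l, a] * U[l, j]
                    for a in range(2)
                    for l in range(6)
                )
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            project_basis(np.zeros((4, 2)), np.zeros((5, 2)))


class TestResidual:
    def test_self_projection_leaves_nothing(self, rng):
        b = _orthobasis(rng, 7, 3)
        np.testing.assert_allclose(residual(b, project_basis(b, b)), 0.0, atol=1e-12)

    def test_orthogonal_input_passes_through(self, rng):
        Q = _orthobasis(rng, 8, 4)
        b, U = Q[:, :2], Q[:, 2:]
        np.testing.assert_allclose(residual(U, project_basis(b, U)), U, atol=1e-12)

    def test_residual_orthogonal_to_basis(self, rng):
        b = _orthobasis(rng, 10, 3)
        U = _orthobasis(rng, 10, 3)
        Q = residual(U, project_basis(b, U))
        assert np.abs(b.T @ Q).max() < 1e-10


class TestGramSchmidt:
    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(gram_schmidt(np.zeros((5, 3))), np.zeros((5, 3)))

    def test_independent_columns_become_orthonormal(self, rng):
        Q = rng.normal(size=(6, 2))
        R = gram_schmidt(Q)
        np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-10)

    def test_duplicated_column_dropped_to_zero(self, rng):
        v = rng.normal(size=6)
        Q = np.column_stack([v, v])
        R = gram_schmidt(Q)
        np.testing.assert_allclose(R[:, 1], 0.0, atol=1e-12)
        assert np.linalg.norm(R[:, 0]) == pytest.approx(1.0)

    def test_span_preserved(self, rng):
        Q = rng.normal(size=(8, 3))
        R = gram_schmidt(Q)
        # every original column is reproduced by the orthonormal basis
        np.testing.assert_allclose(R @ (R.T @ Q), Q, atol=1e-8)


class TestOrthonormWeight:
    def test_hand_example_row_three_four(self):
        R = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(orthonorm_weight(R, 1), [[0.36, 0.64]])

    def test_zero_rows_stay_zero(self):
        R = np.array([[0.0, 0.0], [3.0, 4.0]])
        V = orthonorm_weight(R, 2)
        np.testing.assert_array_equal(V[0], 0.0)

    def test_eta_zero_is_plain_row_normalisation(self):
        R = np.array([[3.0, 4.0], [0.0, 2.0]])
        np.testing.assert_allclose(
            orthonorm_weight(R, 0), [[0.6, 0.8], [0.0, 1.0]]
        )

    def test_sign_preserving_on_negative_entries(self):
        V = orthonorm_weight(np.array([[-3.0, 4.0]]), 1)
        np.testing.assert_allclose(V, [[-0.36, 0.64]])

    def test_frobenius_attenuation_in_eta(self, rng):
        R = rng.normal(size=(10, 3))
        norms = [np.linalg.norm(orthonorm_weight(R, eta)) for eta in range(1, 5)]
        assert (np.diff(norms) <= 1e-12).all()


class TestIntegrate:
    def test_single_view_returns_its_basis(self, rng):
        U = _orthobasis(rng, 9, 3)
        basis = integrate([_sv("a", U)], 3)
        np.testing.assert_array_equal(basis.b, U)
        np.testing.assert_allclose(basis.b.T @ basis.b, np.eye(3), atol=1e-10)

    def test_duplicated_view_is_noop(self, rng):
        U = _orthobasis(rng, 9, 3)
        basis = integrate([_sv("a", U), _sv("a_copy", U.copy())], 3)
        np.testing.assert_allclose(basis.b, U, atol=1e-8)

    def test_residual_orthogonality_at_each_step(self, rng):
        svs = [_sv(f"v{i}", _orthobasis(rng, 12, 3)) for i in range(4)]
        b = svs[0].U_k.copy()
        for eta, sv in enumerate(svs[1:], start=1):
            b_orth = gram_schmidt(b)
            R = gram_schmidt(residual(sv.U_k, project_basis(b_orth, sv.U_k)))
            # R is orthogonal to the accretive subspace, hence to b itself
            assert np.abs(b.T @ R).max() < 1e-8
            b = b + orthonorm_weight(R, eta)

    def test_finite_everywhere(self, rng):
        svs = [_sv(f"v{i}", _orthobasis(rng, 10, 2)) for i in range(3)]
        assert np.isfinite(integrate(svs, 2).b).all()

    def test_mismatched_sample_count_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            integrate(
                [_sv("a", _orthobasis(rng, 8, 2)), _sv("b", _orthobasis(rng, 9, 2))],
                2,
            )


class TestClusterAccretive:
    def test_planted_split_recovered(self):
        b = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([10.0, 10.0], (5, 1))])
        labels = cluster_accretive(b, 2, seed=0)
        truth = np.repeat([0, 1], 5)
        assert adjusted_rand(labels, truth) == 1.0

    def test_deterministic_given_seed(self, rng):
        b = rng.normal(size=(20, 3))
        np.testing.assert_array_equal(
            cluster_accretive(b, 3, seed=7), cluster_accretive(b, 3, seed=7)
        )

    def test_permutation_equivariance(self, rng):
        b = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 8])
        perm = rng.permutation(8)
        lab = cluster_accretive(b, 2, seed=1)
        lab_p = cluster_accretive(b[perm], 2, seed=1)
        assert adjusted_rand(lab_p, lab[perm]) == 1.0

    def test_labels_canonical_first_occurrence(self):
        assert canonicalize_labels(np.array([2, 2, 0, 1, 0])).tolist() == [
            0, 0, 1, 2, 1,
        ]
        b = np.vstack([np.ones((3, 2)) * 5, np.zeros((3, 2))])
        assert cluster_accretive(b, 2, seed=0)[0] == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_accretive(np.zeros((2, 2)), 3)


class TestRisyngRun:
    def _dataset(self, seed=0, n=60):
        spec = SyntheticSpec(
            n=n, k=2, cluster_proportions=[0.5, 0.5],
            views=[ViewSpec(30, 6.0, 1.0, True), ViewSpec(30, 6.0, 1.0, True)],
            seed=seed,
        )
        return make_multiview(spec)

    def test_deterministic_given_seed(self):
        data, _ = self._dataset()
        r1 = risyng_run(data, 2, {"seed": 4})
        r2 = risyng_run(data, 2, {"seed": 4})
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.b_final, r2.b_final)

    def test_single_view_reduces_to_spectral_embedding(self):
        data, _ = self._dataset()
        single = type(data)(views=[data.views[0]], sample_ids=data.sample_ids)
        result = risyng_run(single, 2, {"seed": 0})
        rep = build_representations(data.views[0])
        from risyng.synergy import select_beta

        sv = select_beta(rep.G, rep.Lmod, 2, seed=0, name=data.views[0].name)
        np.testing.assert_allclose(result.b_final, sv.U_k, atol=1e-12)

    def test_recovers_planted_clusters(self):
        data, truth = self._dataset(seed=1)
        result = risyng_run(data, 2, {"seed": 1})
        assert adjusted_rand(result.labels, truth) >= 0.9

    def test_diagnostics_one_row_per_view(self):
        data, _ = self._dataset()
        result = risyng_run(data, 2, {"seed": 0})
        assert len(result.per_view) == 2
        for row in result.per_view:
            assert 0.0 <= row["beta"] <= 1.0
            assert row["rank"] in (1, 2)


class TestEstimatorAPI:
    def test_get_set_params_round_trip(self):
        model = RISynG(n_clusters=4, alpha=0.2)
        params = model.get_params()
        clone = RISynG(**params)
        assert clone.get_params() == params
        model.set_params(alpha=0.5)
        assert model.alpha == 0.5

    def test_sklearn_clone(self):
        from sklearn.base import clone

        model = RISynG(n_clusters=3, eig_mode="largest")
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_fit_predict_matches_labels(self):
        spec = SyntheticSpec(40, 2, [0.5, 0.5], [ViewSpec(20, 6.0, 1.0, True)], 0)
        data, _ = make_multiview(spec)
        model = RISynG(n_clusters=2, random_state=0)
        labels = model.fit_predict(data)
        np.testing.assert_array_equal(labels, model.labels_)
        assert model.embedding_.shape == (40, 2)

    def test_accepts_samples_by_features_arrays(self, rng):
        X1 = rng.normal(size=(30, 8))
        X2 = rng.normal(size=(30, 12))
        model = RISynG(n_clusters=2, random_state=0).fit([X1, X2])
        assert model.labels_.shape == (30,)
        assert model.n_views_ == 2

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n_clusters"):
            RISynG(n_clusters=10, random_state=0).fit([np.eye(4)])

    def test_invalid_parameters_rejected(self, rng):
        X = [np.asarray(np.eye(8))]
        with pytest.raises(ValueError):
            RISynG(n_clusters=1).fit(X)
        with pytest.raises(ValueError):
            RISynG(n_clusters=2, alpha=1.0).fit(X)
        with pytest.raises(ValueError):
            RISynG(n_clusters=2, eig_mode="middle").fit(X)
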