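"""Sphering, Infomax learning, component ordering and recovery metrics."""

import numpy as np
import pytest
from scipy.linalg import sqrtm
from sklearn.base import clone

from icpolarity.ica import (
    InfomaxICA,
    amari_index,
    infomax,
    initial_mixing,
    order_by_variance,
    sphering_matrix,
)
from icpolarity.polarity import topo_dominance
from icpolarity.synthetic_data import default_scenario, simulate_sources
SUITE_SEED = 0


def random_spd_sqrt(rng, n, dof=None):
    """Principal square root of a well-conditioned Wishart covariance —
    the form a sphering inverse takes."""
    dof = dof or rng.integers(3 * n, 10 * n)
    g = rng.standard_normal((n, dof))
    return np.real(sqrtm(g @ g.T / dof))


class TestSphering:
    def test_identity_on_white_data(self, rng):
        x = rng.standard_normal((6, 20000))
        S = sphering_matrix(x)
        np.testing.assert_allclose(S, np.eye(6), atol=0.05)

    def test_sphered_covariance_is_identity(self, rng):
        mix = rng.standard_normal((8, 8))
        x = mix @ rng.standard_normal((8, 5000))
        S = sphering_matrix(x)
        z = S @ (x - x.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(z @ z.T / z.shape[1], np.eye(8), atol=1e-8)

    def test_symmetric_with_positive_diagonal(self, rng):
        for _ in range(20):
            mix = rng.standard_normal((7, 7))
            x = mix @ rng.standard_normal((7, 3000))
            S = sphering_matrix(x)
            np.testing.assert_allclose(S, S.T, atol=1e-10 * np.abs(S).max())
            assert np.all(np.diag(S) > 0)

    def test_rank_deficient_covariance_rejected(self, rng):
        x = rng.standard_normal((5, 1000))
        x = x - x.mean(axis=0, keepdims=True)  # average reference: exact null
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            sphering_matrix(x)


class TestIdentityInitializationPolarity:
    def test_initial_topographies_all_positive_dominant(self, rng):
        """Iteration-0 mixing is C^{1/2}: SPD with positive diagonal, and for
        sphering matrices of well-conditioned covariance every column's
        peak-magnitude entry is the (positive) diagonal one."""
        for _ in range(50):
            n = int(rng.integers(5, 40))
            A0 = random_spd_sqrt(rng, n)
            doms = [topo_dominance(A0[:, k]) for k in range(n)]
            assert doms == [1] * n

    def test_initial_mixing_inverts_sphering(self, rng):
        x = rng.standard_normal((6, 6)) @ rng.standard_normal((6, 4000))
        S = sphering_matrix(x)
        np.testing.assert_allclose(initial_mixing(S) @ S, np.eye(6), atol=1e-10)


class TestInfomax:
    def _sources(self, n=6, seconds=40.0):
        specs, _ = default_scenario(SUITE_SEED)
        brain = [s for s in specs if s.class_label.startswith("brain")][:n]
        return simulate_sources(brain, seconds, 250.0, SUITE_SEED)

    def test_independent_inputs_give_diagonal_dominant_positive_mixing(self):
        src = self._sources()
        S = sphering_matrix(src)
        z = S @ (src - src.mean(axis=1, keepdims=True))
        W, _, _ = infomax(z, shuffle_seed=SUITE_SEED, max_iter=200)
        A = np.linalg.inv(W @ S)
        # already-independent inputs: recovered mixing is a scaled identity up
        # to small cross-talk, with positive diagonal (polarity retained)
        for k in range(A.shape[1]):
            col = np.abs(A[:, k])
            assert col.argmax() == k
            assert A[k, k] > 0

    def test_permutation_init_equivariance(self):
        src = self._sources(n=4, seconds=20.0)
        S = sphering_matrix(src)
        z = S @ (src - src.mean(axis=1, keepdims=True))
        perm = np.eye(4)[[2, 0, 3, 1]]
        W_id, _, _ = infomax(z, shuffle_seed=SUITE_SEED, max_iter=60)
        W_pm, _, _ = infomax(z, init=perm, shuffle_seed=SUITE_SEED, max_iter=60)
        np.testing.assert_allclose(W_pm, perm @ W_id, rtol=1e-8, atol=1e-10)

    def test_weight_blowup_raises(self):
        src = self._sources(n=4, seconds=10.0)
        S = sphering_matrix(src)
        z = S @ src
        with pytest.raises(FloatingPointError, match="lrate"):
            infomax(z, lrate=10.0, max_iter=5)

    def test_singular_init_rejected(self):
        z = np.random.default_rng(0).standard_normal((3, 100))
        with pytest.raises(ValueError, match="full-rank"):
            infomax(z, init=np.zeros((3, 3)))


class TestOrdering:
    def test_single_component_order(self, rng):
        from icpolarity.ica import UnmixingModel

        model = UnmixingModel(np.eye(1), np.eye(1), np.eye(1), np.eye(1),
                              np.array([0]), 1, True)
        out = order_by_variance(model, rng.standard_normal((1, 50)))
        assert out.order.tolist() == [0]

    def test_projected_variances_non_increasing(self, rng):
        from icpolarity.ica import UnmixingModel, projected_variances

        mix = rng.standard_normal((5, 5))
        x = mix @ rng.standard_normal((5, 2000))
        U = np.linalg.inv(mix)
        model = UnmixingModel(np.eye(5), U, U, mix, np.arange(5), 1, True)
        out = order_by_variance(model, x)
        pv = projected_variances(out, x)
        assert np.all(np.diff(pv) <= 1e-12)

    def test_variance_decomposition_identity(self, rng):
        """With exactly sample-uncorrelated sources the per-channel variances
        sum to the summed projected variances (linear-algebra identity)."""
        s = rng.standard_normal((4, 500))
        s -= s.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(s.T)  # orthogonalize the sample time series
        s = (q * np.sqrt(500)).T
        mix = rng.standard_normal((4, 4))
        x = mix @ s
        from icpolarity.ica import UnmixingModel

        U = np.linalg.inv(mix)
        model = UnmixingModel(np.eye(4), U, U, mix, np.arange(4), 1, True)
        pv = np.mean(model.mixing**2, axis=0) * np.var(model.unmixing @ x, axis=1)
        total = np.mean(np.var(x, axis=1))
        assert total == pytest.approx(pv.sum(), rel=1e-6)


class TestAmari:
    def test_zero_for_equal_matrices(self, rng):
        A = rng.standard_normal((6, 6))
        assert amari_index(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_permutation_and_scaling(self, rng):
        A = rng.standard_normal((6, 6))
        perm = np.eye(6)[rng.permutation(6)]
        scale = np.diag(rng.uniform(0.5, 2.0, 6) * rng.choice([-1, 1], 6))
        assert amari_index(A @ perm @ scale, A) < 1e-10

    def test_random_pairs_clearly_nonzero(self, rng):
        vals = [amari_index(rng.standard_normal((10, 10)),
                            rng.standard_normal((10, 10)))
                for _ in range(300)]
        assert np.median(vals) > 0.3

    def test_singular_estimate_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            amari_index(np.zeros((3, 3)), np.eye(3))

    def test_rectangular_reduction(self, rng):
        A = rng.standard_normal((8, 8))
        assert amari_index(A, A[:, [3, 5, 1]]) < 1e-10


class TestEstimator:
    def test_sklearn_contract_and_reconstruction(self):
        specs, _ = default_scenario(SUITE_SEED)
        brain = [s for s in specs if s.class_label.startswith("brain")][:5]
        src = simulate_sources(brain, 20.0, 250.0, SUITE_SEED)
        rng = np.random.default_rng(SUITE_SEED)
        X = (rng.standard_normal((5, 5)) @ src).T

        est = InfomaxICA(max_iter=80, random_state=SUITE_SEED)
        assert clone(est).get_params() == est.get_params()
        est.fit(X)
        assert est.mixing_.shape == (5, 5)
        S = est.transform(X)
        np.testing.assert_allclose(est.inverse_transform(S), X,
                                   rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(est.mixing_ @ est.unmixing_, np.eye(5),
                                   atol=1e-8)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(SUITE_SEED)
        X = rng.standard_normal((2000, 4))
        a = InfomaxICA(max_iter=30, random_state=1).fit(X).mixing_
        b = InfomaxICA(max_iter=30, random_state=1).fit(X).mixing_
        np.testing.assert_array_equal(a, b)
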