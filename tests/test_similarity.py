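import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwce import (
    ConvergenceError,
    EnsembleStructureError,
    ICMatrix,
    ParameterError,
    ensemble_from_label_table,
    jaccard_network,
    kernel_similarity,
    pool_to_ic,
    random_walk_restart,
)

from .conftest import random_crisp_ensemble


class TestJaccardNetwork:
    def test_hand_values(self):
        # clusters {1,2}|{3,4} and {1}|{2,3,4}: e.g. {1,2} vs {2,3,4} -> 1/4
        ic = pool_to_ic(ensemble_from_label_table(np.array([[1, 1], [1, 2], [2, 2], [2, 2]])))
        J = jaccard_network(ic)
        assert J[0, 2] == pytest.approx(1 / 2)  # {1,2} vs {1} -> 1/2
        assert J[0, 3] == pytest.approx(1 / 4)  # {1,2} vs {2,3,4} -> 1/4
        assert J[1, 3] == pytest.approx(2 / 3)  # {3,4} vs {2,3,4} -> 2/3
        assert J[0, 1] == 0.0  # disjoint clusters of one clustering
        assert np.allclose(np.diag(J), 1.0)

    def test_identical_clusters_across_clusterings_hit_one(self):
        ic = pool_to_ic(ensemble_from_label_table(np.array([[1, 1], [1, 1], [2, 2]])))
        J = jaccard_network(ic)
        assert J[0, 2] == 1.0 and J[1, 3] == 1.0

    def test_matches_double_loop_oracle(self, small_ic):
        J = jaccard_network(small_ic)
        B = small_ic.values
        for x in range(small_ic.K_total):
            for y in range(small_ic.K_total):
                Lx, Ly = set(np.flatnonzero(B[:, x])), set(np.flatnonzero(B[:, y]))
                expected = len(Lx & Ly) / len(Lx | Ly)
                if x == y:
                    expected = 1.0
                assert J[x, y] == pytest.approx(expected, abs=1e-12)

    def test_within_clustering_blocks_are_zero(self, rng):
        ic = pool_to_ic(random_crisp_ensemble(n=30, M=5, k_max=5, rng=rng))
        J = jaccard_network(ic)
        for _, cols in ic.blocks():
            block = J[np.ix_(cols, cols)]
            off = block - np.diag(np.diag(block))
            assert np.all(off == 0.0)

    def test_symmetry_and_no_self_loops_flag(self, small_ic):
        J = jaccard_network(small_ic, self_loops=False)
        np.testing.assert_allclose(J, J.T)
        assert np.all(np.diag(J) == 0.0)


class TestRandomWalkRestart:
    def test_alpha_zero_returns_initial_state(self, small_ic):
        J = jaccard_network(small_ic)
        F = random_walk_restart(small_ic, J, alpha=0.0)
        np.testing.assert_array_equal(F, small_ic.values.astype(float))

    def test_identity_transition_fixes_initial_state(self, small_ic):
        I = np.eye(small_ic.K_total)
        F = random_walk_restart(small_ic, I, alpha=0.9, tol=1e-10)
        np.testing.assert_allclose(F, small_ic.values.astype(float), atol=1e-9)

    def test_matches_closed_form_solution(self, rng):
        ic = pool_to_ic(ensemble_from_label_table(
            np.array([[1, 1], [1, 2], [2, 2], [2, 3], [1, 3], [2, 1]])
        ))
        J = jaccard_network(ic)
        alpha = 0.9
        F = random_walk_restart(ic, J, alpha=alpha, tol=1e-12)
        A_hat = J / J.sum(axis=1, keepdims=True)
        F0 = ic.values.astype(float)
        closed = (1 - alpha) * F0 @ np.linalg.inv(np.eye(ic.K_total) - alpha * A_hat)
        np.testing.assert_allclose(F, closed, atol=1e-8)

    def test_returned_state_is_a_fixed_point(self, small_ic):
        J = jaccard_network(small_ic)
        alpha, tol = 0.9, 1e-6
        F = random_walk_restart(small_ic, J, alpha=alpha, tol=tol)
        A_hat = J / J.sum(axis=1, keepdims=True)
        residual = np.abs(F - (alpha * F @ A_hat + (1 - alpha) * small_ic.values)).max()
        assert residual < tol

    def test_raw_adjacency_can_diverge_and_reports_residual(self, small_ic):
        J = jaccard_network(small_ic)
        with pytest.raises(ConvergenceError) as exc:
            random_walk_restart(small_ic, 5.0 * J, alpha=0.9, normalize=False, max_iter=50)
        assert exc.value.residual > 0

    def test_parameter_validation(self, small_ic):
        J = jaccard_network(small_ic)
        with pytest.raises(ParameterError):
            random_walk_restart(small_ic, J, alpha=1.0)
        with pytest.raises(ParameterError):
            random_walk_restart(small_ic, J, alpha=0.5, tol=0.0)


class TestKernelSimilarity:
    def test_identical_profiles_give_one(self):
        Z = np.ones((5, 3))
        S = kernel_similarity(Z)
        np.testing.assert_allclose(S, 1.0)

    def test_known_distance(self):
        # columns differ in two coordinates by 1 -> rho2 = 2 -> exp(-1)
        Z = np.zeros((4, 2))
        Z[:2, 1] = 1.0
        S = kernel_similarity(Z, sigma=1.0)
        assert S[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        Z = rng.standard_normal((8, 6))
        S = kernel_similarity(Z, sigma=1.3)
        for i in range(6):
            for j in range(6):
                rho2 = np.sum((Z[:, i] - Z[:, j]) ** 2)
                expected = 1.0 if i == j else np.exp(-rho2 / (2 * 1.3**2))
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_distance(self):
        base = np.zeros((3, 4))
        for j, shift in enumerate([0.0, 0.5, 1.0, 2.0]):
            base[:, j] = shift
        S = kernel_similarity(base)
        sims = S[0, 1:]
        assert np.all(np.diff(sims) < 0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            kernel_similarity(np.ones((3, 2)), sigma=0.0)


def test_jaccard_rejects_empty_columns(small_ic):
    broken = ICMatrix(
        values=small_ic.values, cluster_index=small_ic.cluster_index, M=small_ic.M
    )
    broken.values = broken.values.copy()
    broken.values[:, 0] = 0
    with pytest.raises(EnsembleStructureError):
        jaccard_network(broken)


@settings(deadline=None, max_examples=15)
@given(st.integers(min_value=0, max_value=10_000), st.floats(min_value=0.0, max_value=0.95))
def test_walk_preserves_nonnegativity_and_fixed_point(seed, alpha):
    """Converged walk states are finite, nonnegative fixed points of the update map."""
    rng = np.random.default_rng(seed)
    ic = pool_to_ic(random_crisp_ensemble(n=12, M=3, k_max=4, rng=rng))
    J = jaccard_network(ic)
    F = random_walk_restart(ic, J, alpha=alpha, tol=1e-8)
    assert np.isfinite(F).all() and (F >= 0).all()
    A_hat = J / J.sum(axis=1, keepdims=True)
    residual = np.abs(F - (alpha * F @ A_hat + (1 - alpha) * ic.values)).max()
    assert residual < 1e-8
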