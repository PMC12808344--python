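"""Affinity calibration, symmetrization, low-dim kernel, cost and gradient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsne_sensitivity import (
    AffinityMatrix,
    DuplicateRowsError,
    calibrate_bandwidths,
    cost_gradient,
    joint_affinities,
    kl_cost,
    low_dim_affinities,
)


def _entropy_bits(p):
    p = p[p > 0]
    return -(p * np.log2(p)).sum()


class TestCalibration:
    def test_equilateral_triangle_rows_uniform(self):
        # symmetry forces each conditional row to (0, 1/2, 1/2) at any
        # bandwidth: test the row kernel directly across precisions
        from tsne_sensitivity.tsne import _row_conditional, pairwise_sq_distances

        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        d2 = pairwise_sq_distances(X)
        for beta in (0.1, 1.0, 10.0):
            for i in range(3):
                p, _ = _row_conditional(d2[i].copy(), beta, i)
                np.testing.assert_allclose(np.delete(p, i), 0.5, atol=1e-12)
                assert p[i] == 0.0

    @pytest.mark.parametrize("perplexity", [3.0, 5.0, 7.5])
    def test_achieved_perplexity(self, rng, perplexity):
        X = rng.standard_normal((10, 4))
        _, cond = calibrate_bandwidths(X, perplexity)
        for i in range(10):
            assert 2.0 ** _entropy_bits(cond.values[i]) == pytest.approx(
                perplexity, abs=1e-4
            )

    def test_rows_sum_to_one_zero_diag(self, rng):
        X = rng.standard_normal((12, 3))
        _, cond = calibrate_bandwidths(X, 4.0)
        np.testing.assert_allclose(cond.values.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(cond.values) == 0)

    def test_duplicate_rows_raise_with_pair(self, rng):
        X = rng.standard_normal((8, 3))
        X[5] = X[2]
        with pytest.raises(DuplicateRowsError) as err:
            calibrate_bandwidths(X, 4.0)
        assert err.value.pair == (2, 5)

    def test_duplicate_rows_jitter_flag(self, rng):
        X = rng.standard_normal((8, 3))
        X[5] = X[2]
        _, cond = calibrate_bandwidths(X, 4.0, jitter=True)
        np.testing.assert_allclose(cond.values.sum(axis=1), 1.0, atol=1e-10)

    def test_perplexity_out_of_range(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            calibrate_bandwidths(X, 5.0)  # N - 1 = 5

    def test_unreachable_perplexity_warns_and_terminates(self):
        # two far-separated pairs: near the perplexity -> N-1 limit the
        # bandwidths grow without bound and bisection must stop at the cap
        X = np.array([[0.0], [0.1], [1e6], [1e6 + 0.1]])
        with pytest.warns(RuntimeWarning):
            sigmas, _ = calibrate_bandwidths(X, 2.95, max_bisect=30)
        assert np.all(np.isfinite(sigmas))


class TestJointAffinities:
    def test_uniform_conditional_gives_uniform_joint(self):
        n = 6
        cond = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(cond, 0.0)
        P = joint_affinities(AffinityMatrix(cond, "conditional")).values
        off = P[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / (n * (n - 1)), atol=1e-15)

    def test_brute_force_elementwise(self, rng):
        n = 5
        cond = rng.random((n, n))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        P = joint_affinities(AffinityMatrix(cond, "conditional")).values
        for i in range(n):
            for j in range(n):
                assert P[i, j] == pytest.approx(
                    (cond[i, j] + cond[j, i]) / (2 * n), abs=1e-15
                )

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_joint_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        cond = rng.random((n, n))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        P = joint_affinities(AffinityMatrix(cond, "conditional"))
        P.validate(atol=1e-12)


class TestLowDimAffinities:
    def test_two_points_half_each(self, rng):
        for scale in (0.1, 1.0, 50.0):
            Q = low_dim_affinities(np.array([[0.0, 0.0], [scale, 0.0]])).values
            assert Q[0, 1] == pytest.approx(0.5)
            assert Q[1, 0] == pytest.approx(0.5)

    def test_three_collinear_hand_computation(self):
        # kernel values 1/2, 1/2, 1/5; ordered-pair normalizer 2.4
        Q = low_dim_affinities(np.array([[0.0], [1.0], [2.0]])).values
        np.testing.assert_allclose(Q[0, 1], 0.5 / 2.4)
        np.testing.assert_allclose(Q[1, 2], 0.5 / 2.4)
        np.testing.assert_allclose(Q[0, 2], 0.2 / 2.4)

    def test_rigid_motion_invariance(self, rng):
        Z = rng.standard_normal((9, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Q1 = low_dim_affinities(Z).values
        Q2 = low_dim_affinities(Z @ R.T + np.array([3.0, -1.5])).values
        np.testing.assert_allclose(Q1, Q2, atol=1e-12)

    def test_coincident_points_allowed(self):
        Q = low_dim_affinities(np.zeros((4, 2)))
        Q.validate(atol=1e-12)


class TestKlCost:
    def test_zero_when_p_equals_q(self):
        Z = np.array([[0.0, 0.0], [2.0, 1.0]])
        Q = low_dim_affinities(Z)
        P = AffinityMatrix(Q.values.copy(), "joint")
        assert kl_cost(P, Z) == pytest.approx(0.0, abs=1e-15)

    def test_nonnegative_and_matches_brute_force(self, rng):
        Z = rng.standard_normal((4, 2))
        cond = rng.random((4, 4))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        P = joint_affinities(AffinityMatrix(cond, "conditional"))
        Q = low_dim_affinities(Z).values
        expected = sum(
            P.values[i, j] * np.log(P.values[i, j] / Q[i, j])
            for i in range(4)
            for j in range(4)
            if i != j and P.values[i, j] > 0
        )
        c = kl_cost(P, Z)
        assert c >= 0
        assert c == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_rotation(self, rng):
        Z = rng.standard_normal((7, 2))
        cond = rng.random((7, 7))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        P = joint_affinities(AffinityMatrix(cond, "conditional"))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert kl_cost(P, Z) == pytest.approx(kl_cost(P, Z @ R.T + 5.0), abs=1e-12)


class TestCostGradient:
    def test_components_sum_to_zero(self, rng):
        Z = rng.standard_normal((8, 2))
        _, cond = calibrate_bandwidths(rng.standard_normal((8, 4)), 4.0)
        P = joint_affinities(cond)
        g = cost_gradient(P, Z)
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-14)

    def test_matches_finite_differences(self, rng):
        X = rng.standard_normal((6, 3))
        Z = rng.standard_normal((6, 2))
        _, cond = calibrate_bandwidths(X, 3.0)
        P = joint_affinities(cond)
        g = cost_gradient(P, Z)
        eps = 1e-5
        for i in range(6):
            for a in range(2):
                Zp, Zm = Z.copy(), Z.copy()
                Zp[i, a] += eps
                Zm[i, a] -= eps
                fd = (kl_cost(P, Zp) - kl_cost(P, Zm)) / (2 * eps)
                assert g[i, a] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_small_at_converged_embedding(self, cluster30):
        from tsne_sensitivity.optimize import _joint_from_data

        P = _joint_from_data(cluster30["data"].values, cluster30["config"])
        g = cost_gradient(P, cluster30["emb"].coords)
        assert np.abs(g).max() <= cluster30["config"].grad_tol
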