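"""Analytic Hessian, mixed partials and pseudoinverse against FD oracles."""

import numpy as np
import pytest

from tsne_sensitivity import (
    MixedJacobian,
    calibrate_bandwidths,
    cost_gradient,
    hessian_pseudoinverse,
    hessian_vector_product,
    hessian_zz,
    joint_affinities,
    mixed_jacobian_yz,
    rigid_motion_generators,
)


@pytest.fixture(scope="module")
def small_instance():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((6, 3))
    Z = rng.standard_normal((6, 2))
    _, cond = calibrate_bandwidths(X, 3.0)
    P = joint_affinities(cond)
    return X, Z, P


class TestHessian:
    def test_symmetric(self, small_instance):
        _, Z, P = small_instance
        H = hessian_zz(P, Z)
        np.testing.assert_allclose(H, H.T, atol=1e-8)

    def test_annihilates_translations_anywhere(self, small_instance):
        # exact at any coords, not just stationary ones
        _, Z, P = small_instance
        H = hessian_zz(P, Z)
        for axis in range(2):
            t = np.zeros((6, 2))
            t[:, axis] = 1.0
            assert np.abs(H @ t.ravel()).max() < 1e-14 * np.abs(H).max()

    def test_annihilates_rotation_at_stationarity(self, fix12):
        from tsne_sensitivity.optimize import _joint_from_data

        P = _joint_from_data(fix12["data"].values, fix12["config"])
        Z = fix12["emb"].coords
        H = hessian_zz(P, Z)
        Zc = Z - Z.mean(axis=0)
        r = np.column_stack([-Zc[:, 1], Zc[:, 0]]).ravel()
        r /= np.linalg.norm(r)
        assert np.abs(H @ r).max() < 1e-9 * np.abs(H).max()

    def test_matches_fd_of_gradient(self, small_instance):
        _, Z, P = small_instance
        H = hessian_zz(P, Z)
        eps = 1e-6
        Hfd = np.zeros_like(H)
        for i in range(6):
            for a in range(2):
                Zp, Zm = Z.copy(), Z.copy()
                Zp[i, a] += eps
                Zm[i, a] -= eps
                Hfd[:, 2 * i + a] = (
                    (cost_gradient(P, Zp) - cost_gradient(P, Zm)) / (2 * eps)
                ).ravel()
        assert np.abs(H - Hfd).max() / np.abs(H).max() < 1e-4

    def test_hvp_matches_dense(self, small_instance, rng):
        _, Z, P = small_instance
        H = hessian_zz(P, Z)
        for _ in range(3):
            v = rng.standard_normal(12)
            np.testing.assert_allclose(
                hessian_vector_product(P, Z, v), H @ v, atol=1e-13
            )


class TestMixedJacobian:
    def test_matches_fd_through_calibration(self, small_instance):
        X, Z, _ = small_instance
        perp = 3.0
        M = mixed_jacobian_yz(X, Z, perp)
        eps = 1e-6
        Mfd = np.zeros_like(M)
        for m in range(6):
            for k in range(3):
                cols = []
                for s in (+1.0, -1.0):
                    Xs = X.copy()
                    Xs[m, k] += s * eps
                    _, cond = calibrate_bandwidths(Xs, perp)
                    cols.append(cost_gradient(joint_affinities(cond), Z).ravel())
                Mfd[:, m * 3 + k] = (cols[0] - cols[1]) / (2 * eps)
        assert np.abs(M - Mfd).max() / np.abs(M).max() < 1e-4

    def test_frozen_sigma_matches_fd_with_frozen_sigma(self, small_instance):
        """In freeze-sigma mode the oracle must also hold bandwidths fixed."""
        X, Z, _ = small_instance
        perp = 3.0
        sigmas, _ = calibrate_bandwidths(X, perp)
        betas = 1.0 / (2 * sigmas**2)
        M = mixed_jacobian_yz(X, Z, perp, freeze_sigma=True)

        def grad_fixed_beta(Xs):
            from scipy.spatial.distance import pdist, squareform

            d2 = squareform(pdist(Xs, "sqeuclidean"))
            e = np.exp(-betas[:, None] * d2)
            np.fill_diagonal(e, 0.0)
            cond = e / e.sum(axis=1, keepdims=True)
            from tsne_sensitivity import AffinityMatrix

            return cost_gradient(
                joint_affinities(AffinityMatrix(cond, "conditional")), Z
            ).ravel()

        eps = 1e-6
        for m, k in [(0, 0), (2, 1), (5, 2)]:
            Xp, Xm = X.copy(), X.copy()
            Xp[m, k] += eps
            Xm[m, k] -= eps
            fd = (grad_fixed_beta(Xp) - grad_fixed_beta(Xm)) / (2 * eps)
            np.testing.assert_allclose(
                M[:, m * 3 + k], fd, atol=1e-6 * max(1.0, np.abs(M).max())
            )

    def test_uniform_feature_shift_maps_to_zero(self, small_instance):
        # a constant added to one feature leaves all pairwise distances
        # unchanged, so the mixed Jacobian must annihilate that direction
        X, Z, _ = small_instance
        mj = MixedJacobian(X, Z, 3.0)
        for d in range(3):
            shift = np.zeros((6, 3))
            shift[:, d] = 1.0
            assert np.abs(mj.jvp(shift)).max() < 1e-12

    def test_duplicated_feature_duplicates_columns(self, small_instance):
        X, Z, _ = small_instance
        Xdup = np.hstack([X, X[:, [0]]])
        # duplicating a feature rescales distances, so compare against the
        # duplicated matrix's own Jacobian structure: columns of the copy
        # must equal columns of the original feature 0 within that matrix
        M = mixed_jacobian_yz(Xdup, Z, 3.0)
        M4 = M.reshape(12, 6, 4)
        np.testing.assert_allclose(M4[:, :, 3], M4[:, :, 0], atol=1e-12)

    def test_jvp_vjp_adjoint_consistency(self, small_instance, rng):
        X, Z, _ = small_instance
        mj = MixedJacobian(X, Z, 3.0)
        M = mj.dense()
        v = rng.standard_normal(18)
        u = rng.standard_normal(12)
        np.testing.assert_allclose(mj.jvp(v).ravel(), M @ v, atol=1e-13)
        np.testing.assert_allclose(mj.vjp(u).ravel(), u @ M, atol=1e-13)
        # adjoint identity <u, Mv> = <M^T u, v>
        assert float(u @ mj.jvp(v).ravel()) == pytest.approx(
            float(mj.vjp(u).ravel() @ v), rel=1e-10
        )


class TestPseudoinverse:
    def test_diagonal_closed_form(self):
        H = np.diag([0.0, 0.0, 0.0, 2.0, 5.0])
        pinv, spectrum = hessian_pseudoinverse(H)
        np.testing.assert_allclose(pinv(np.eye(5)), np.diag([0, 0, 0, 0.5, 0.2]),
                                   atol=1e-14)
        assert spectrum.null_dim == 3

    def test_projector_property(self, fix12):
        from tsne_sensitivity.optimize import _joint_from_data

        P = _joint_from_data(fix12["data"].values, fix12["config"])
        Z = fix12["emb"].coords
        H = hessian_zz(P, Z)
        pinv, spectrum = hessian_pseudoinverse(H)
        proj = pinv(H)  # H^+ H
        null = spectrum.null_basis
        # identity on the complement of the null space
        rng = np.random.default_rng(5)
        v = rng.standard_normal(H.shape[0])
        v -= null @ (null.T @ v)
        np.testing.assert_allclose(proj @ v, v, atol=1e-6)
        # zero on translations
        t = np.tile([1.0, 0.0], H.shape[0] // 2)
        np.testing.assert_allclose(proj @ t, 0.0, atol=1e-8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hessian_pseudoinverse(np.zeros((4, 4)))

    def test_unexpected_null_dim_warns(self):
        H = np.diag([0.0, 0.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="null-space"):
            hessian_pseudoinverse(H, expected_null_dim=3)


def test_rigid_motion_generators_orthonormal_and_in_null_space(fix12):
    from tsne_sensitivity.optimize import _joint_from_data

    Z = fix12["emb"].coords
    gens = rigid_motion_generators(Z)
    assert gens.shape == (24, 3)
    np.testing.assert_allclose(gens.T @ gens, np.eye(3), atol=1e-12)
    P = _joint_from_data(fix12["data"].values, fix12["config"])
    H = hessian_zz(P, Z)
    assert np.abs(H @ gens).max() < 1e-9 * np.abs(H).max()
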