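"""Analytic second derivatives of the t-SNE cost.

Two objects are needed to differentiate the stationarity condition
``grad_z C(y*, z*) = 0`` with the Implicit Function Theorem:

* the embedding Hessian ``H = d^2 C / dz^2`` (an NP x NP symmetric matrix,
  singular along the rigid-motion directions), and
* the mixed partials ``M = d^2 C / dy dz`` (NP x ND), where the dependence
  of the joint affinities on ``y`` runs *through* the per-point bandwidth
  calibration: ``sigma_i`` is defined implicitly by the entropy constraint
  ``H(p_.|i) = log2(perplexity)``, and is differentiated implicitly.

Both are derived in closed form from the cost

    C = - sum_{i != j} p_ij log w_ij + log(sum_{k != l} w_kl),   w_ij = 1/(1+||z_i-z_j||^2)

(the constant entropy of P is dropped).  Writing ``u_ij = z_i - z_j``,
``Z = sum w``, ``q = w / Z`` and ``s_i = sum_j w_ij^2 u_ij``, the Hessian
splits into a pairwise part with blocks (for ``i != m``)

    B_im = (8 p_im w_im^2 - 16 w_im^3 / Z) u u^T + (4 w_im^2 / Z - 4 p_im w_im) I

with diagonal blocks ``B_ii = -sum_m B_im`` (which enforces exact
translation invariance), minus the rank-one term ``(16 / Z^2) s s^T``.

For the mixed partials, with ``beta_i = 1/(2 sigma_i^2)``,
``b_l = d2_il - E_i`` (centred squared input distances under ``p_.|i``) and
``V_i = Var_{p_.|i}[d2]``, the total derivative of the conditional
affinities with respect to squared distances is

    A^(i)_{jl} = d p_{j|i} / d d2_il
              = -beta_i p_{j|i} (delta_jl - p_{l|i})            (bandwidth fixed)
                + beta_i p_{j|i} b_j p_{l|i} b_l / V_i          (implicit d beta_i)

and the chain rule through ``d d2_il / dy`` yields M.  The implicit term is
dropped in ``freeze_sigma`` mode.  Everything is validated against
finite-difference oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .tsne import (
    AffinityMatrix,
    _as_values,
    calibrate_bandwidths,
    pairwise_sq_distances,
    student_t_kernel,
)

__all__ = [
    "hessian_zz",
    "hessian_vector_product",
    "MixedJacobian",
    "mixed_jacobian_yz",
    "rigid_motion_generators",
    "HessianSpectrum",
    "hessian_pseudoinverse",
]


# ---------------------------------------------------------------------------
# Hessian with respect to the embedding
# ---------------------------------------------------------------------------

def _pair_terms(joint: AffinityMatrix, coords: np.ndarray):
    Z = np.asarray(coords, dtype=float)
    n, p = Z.shape
    P = joint.values
    W = student_t_kernel(Z)
    zsum = W.sum()
    U = Z[:, None, :] - Z[None, :, :]  # U[i, m] = z_i - z_m
    c1 = 8.0 * P * W**2 - 16.0 * W**3 / zsum
    c2 = 4.0 * W**2 / zsum - 4.0 * P * W
    s = np.einsum("im,ima->ia", W**2, U)  # s_i = sum_m w_im^2 u_im
    return Z, n, p, U, c1, c2, s, zsum


def hessian_zz(joint: AffinityMatrix, coords: np.ndarray) -> np.ndarray:
    """Dense Hessian ``d^2 C / dz^2`` at (P, Z), shape (N*P, N*P).

    Row/column order is sample-major: indices ``i*P + a``.  The matrix is
    symmetric and annihilates uniform translations exactly; at a stationary
    point it also annihilates the infinitesimal rotation of the embedding.
    """
    if joint.kind != "joint":
        raise ValueError("hessian_zz expects joint affinities")
    Z, n, p, U, c1, c2, s, zsum = _pair_terms(joint, coords)
    B = np.einsum("im,ima,imb->imab", c1, U, U)
    B += c2[:, :, None, None] * np.eye(p)
    # diagonal blocks: minus the row sums of the pairwise blocks
    diag = -B.sum(axis=1)
    B[np.arange(n), np.arange(n)] = diag
    H = B.transpose(0, 2, 1, 3).reshape(n * p, n * p)
    H -= (16.0 / zsum**2) * np.outer(s.ravel(), s.ravel())
    return 0.5 * (H + H.T)


def hessian_vector_product(
    joint: AffinityMatrix, coords: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Matrix-free ``H @ v`` in O(N^2 P) memory, ``v`` of shape (N*P,) or (N, P)."""
    Z, n, p, U, c1, c2, s, zsum = _pair_terms(joint, coords)
    V = np.asarray(v, dtype=float).reshape(n, p)
    dV = V[None, :, :] - V[:, None, :]  # dV[i, m] = v_m - v_i
    proj = np.einsum("ima,ima->im", U, dV)
    out = np.einsum("im,ima->ia", c1 * proj, U)
    out += np.einsum("im,ima->ia", c2, dV)
    out -= (16.0 / zsum**2) * s * float(s.ravel() @ V.ravel())
    return out.reshape(np.asarray(v).shape)


# ---------------------------------------------------------------------------
# Mixed partials d^2 C / dy dz, through the perplexity calibration
# ---------------------------------------------------------------------------

class MixedJacobian:
    """Mixed partials ``M = d^2 C / dy dz`` evaluated at ``(Y, Z)``.

    Precomputes the calibration intermediates once; exposes a dense
    materialization and matrix-free JVP/VJP contractions.

    Parameters
    ----------
    data : Dataset or ndarray (N, D)
    coords : ndarray (N, P)
        The (stationary) embedding.
    perplexity : float
    freeze_sigma : bool
        If True, treat the calibrated bandwidths as constants instead of
        differentiating the entropy constraint implicitly.
    """

    def __init__(
        self,
        data,
        coords: np.ndarray,
        perplexity: float,
        freeze_sigma: bool = False,
        calib_tol: float = 1e-12,
        max_bisect: int = 200,
    ):
        self.Y = _as_values(data)
        self.Z = np.asarray(coords, dtype=float)
        self.n, self.d = self.Y.shape
        self.p = self.Z.shape[1]
        self.perplexity = perplexity
        self.freeze_sigma = freeze_sigma

        sigmas, cond = calibrate_bandwidths(
            self.Y, perplexity, tol=calib_tol, max_bisect=max_bisect
        )
        self.sigmas = sigmas
        self.betas = 1.0 / (2.0 * sigmas**2)
        self.Pc = cond.values  # Pc[i, l] = p_{l|i}
        self.d2 = pairwise_sq_distances(self.Y)
        E = np.einsum("il,il->i", self.Pc, self.d2)
        self.B = self.d2 - E[:, None]  # centred squared distances per row
        self.B[np.arange(self.n), np.arange(self.n)] = 0.0
        self.var = np.einsum("il,il->i", self.Pc, self.B**2)
        if not self.freeze_sigma and np.any(self.var <= 1e-300):
            raise ValueError(
                "degenerate conditional distribution (zero distance variance); "
                "cannot differentiate the entropy constraint"
            )
        # low-dim pieces for the final contraction
        self.W = student_t_kernel(self.Z)
        self.U = self.Z[:, None, :] - self.Z[None, :, :]
        # geometry factor G[i, l, d] = d d2_il / d y_id = 2 (y_id - y_ld)
        self.G = 2.0 * (self.Y[:, None, :] - self.Y[None, :, :])

    # -- conditional-affinity derivative contractions -----------------------

    def _a_dot(self, X: np.ndarray) -> np.ndarray:
        """Rowwise contraction ``sum_l A^(i)_{jl} X[i, l]`` -> (N, N) over j."""
        Pc, B = self.Pc, self.B
        m1 = np.einsum("il,il->i", Pc, X)
        out = -self.betas[:, None] * Pc * (X - m1[:, None])
        if not self.freeze_sigma:
            m2 = np.einsum("il,il,il->i", Pc, B, X)
            out += (self.betas / self.var)[:, None] * Pc * B * m2[:, None]
        return out

    def _a_dot_T(self, F: np.ndarray) -> np.ndarray:
        """Rowwise transpose contraction ``sum_j A^(i)_{jl} F[i, j]`` -> (N, N) over l."""
        Pc, B = self.Pc, self.B
        m1 = np.einsum("ij,ij->i", Pc, F)
        out = self.betas[:, None] * Pc * (m1[:, None] - F)
        if not self.freeze_sigma:
            m2 = np.einsum("ij,ij,ij->i", Pc, B, F)
            out += (self.betas / self.var)[:, None] * Pc * B * m2[:, None]
        return out

    # -- matrix-free products ----------------------------------------------

    def jvp(self, v: np.ndarray) -> np.ndarray:
        """``M @ vec(V)`` for an input-space direction ``V`` (N, D) -> (N, P)."""
        V = np.asarray(v, dtype=float).reshape(self.n, self.d)
        dY = self.Y[:, None, :] - self.Y[None, :, :]
        dV = V[:, None, :] - V[None, :, :]
        dD2 = 2.0 * np.einsum("ilk,ilk->il", dY, dV)  # d d2_il in direction V
        dPc = self._a_dot(dD2)
        dPj = (dPc + dPc.T) / (2.0 * self.n)
        return 4.0 * np.einsum("ij,ij,ija->ia", dPj, self.W, self.U)

    def vjp(self, u: np.ndarray) -> np.ndarray:
        """``vec(U)^T @ M`` for an embedding-space covector ``U`` (N, P) -> (N, D)."""
        Uc = np.asarray(u, dtype=float).reshape(self.n, self.p)
        F = 4.0 * np.einsum("ija,ia->ij", self.U, Uc) * self.W
        Ft = F + F.T
        K = self._a_dot_T(Ft)  # K[i, l]
        t1 = -np.einsum("im,imd->md", K, self.G)
        t2 = np.einsum("ml,mld->md", K, self.G)
        return (t1 + t2) / (2.0 * self.n)

    # -- dense materialization ---------------------------------------------

    def dense(self) -> np.ndarray:
        """Materialize M as an (N*P, N*D) array (sample-major both ways)."""
        n, d, p = self.n, self.d, self.p
        Pc, B, G = self.Pc, self.B, self.G
        # A[i, j, l] = d p_{j|i} / d d2_il
        A = -self.betas[:, None, None] * Pc[:, :, None] * (
            np.eye(n)[None, :, :] - Pc[:, None, :]
        )
        if not self.freeze_sigma:
            A += (self.betas / self.var)[:, None, None] * (
                (Pc * B)[:, :, None] * (Pc * B)[:, None, :]
            )
        # dPc[i, j, m, d] = d p_{j|i} / d y_md
        dPc = -np.einsum("ijm,imd->ijmd", A, G)
        dPc[np.arange(n), :, np.arange(n), :] = np.einsum("ijl,ild->ijd", A, G)
        dPj = (dPc + dPc.transpose(1, 0, 2, 3)) / (2.0 * n)
        M = 4.0 * np.einsum("ijmd,ij,ija->iamd", dPj, self.W, self.U)
        return M.reshape(n * p, n * d)


def mixed_jacobian_yz(
    data, coords: np.ndarray, perplexity: float, freeze_sigma: bool = False
) -> np.ndarray:
    """Dense mixed partials ``d^2 C / dy dz`` at ``(Y, Z)``; see MixedJacobian."""
    return MixedJacobian(data, coords, perplexity, freeze_sigma=freeze_sigma).dense()


# ---------------------------------------------------------------------------
# Null space and pseudoinverse
# ---------------------------------------------------------------------------

def rigid_motion_generators(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the rigid-motion directions at Z, shape (NP, n_gen).

    P translations plus P(P-1)/2 infinitesimal rotations about the centroid;
    for P=2 this is the three-dimensional null space of the t-SNE Hessian at
    a stationary point.
    """
    Z = np.asarray(coords, dtype=float)
    n, p = Z.shape
    Zc = Z - Z.mean(axis=0)
    gens = []
    for a in range(p):
        t = np.zeros((n, p))
        t[:, a] = 1.0
        gens.append(t.ravel())
    for a in range(p):
        for b in range(a + 1, p):
            r = np.zeros((n, p))
            r[:, a] = -Zc[:, b]
            r[:, b] = Zc[:, a]
            gens.append(r.ravel())
    Q, _ = np.linalg.qr(np.column_stack(gens))
    return Q


@dataclass
class HessianSpectrum:
    """Eigendecomposition summary of the embedding Hessian.

    ``eigenvalues`` ascending; ``null_dim`` counts modes with
    ``|lambda| <= rank_tol * max|lambda|``; ``null_basis`` spans them.
    """

    eigenvalues: np.ndarray
    null_dim: int
    null_basis: np.ndarray
    rank_tol: float

    def summary(self) -> dict:
        lam = self.eigenvalues
        return {
            "null_dim": int(self.null_dim),
            "rank_tol": float(self.rank_tol),
            "min_eigenvalue": float(lam.min()),
            "max_eigenvalue": float(lam.max()),
            "smallest_abs_eigenvalues": [float(x) for x in np.sort(np.abs(lam))[:6]],
        }


def hessian_pseudoinverse(
    H: np.ndarray, rank_tol: float = 1e-8, expected_null_dim: int | None = None
):
    """Moore-Penrose pseudoinverse of a symmetric Hessian via eigendecomposition.

    Eigenvalues with ``|lambda| <= rank_tol * max|lambda|`` are mapped to
    zero — for a converged 2-D embedding these are the two translations and
    one rotation, the directions along which the cost is flat and the plot
    carries no information.  Returns ``(apply, spectrum)`` where ``apply``
    maps a vector (or matrix of columns) through H^+.

    A null dimension other than 3 (for P=2: expected translations+rotation)
    triggers a warning: extra near-null modes signal structural instability
    of the embedding, not an error.
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise ValueError("hessian_pseudoinverse expects a symmetric matrix")
    lam, V = np.linalg.eigh(0.5 * (H + H.T))
    scale = np.abs(lam).max()
    if scale == 0.0:
        raise ValueError("Hessian is identically zero; degenerate embedding")
    null_mask = np.abs(lam) <= rank_tol * scale
    null_dim = int(null_mask.sum())
    if null_dim == lam.size:
        raise ValueError("all Hessian eigenvalues below tolerance; degenerate embedding")
    if expected_null_dim is not None and null_dim != expected_null_dim:
        warnings.warn(
            f"Hessian null-space dimension {null_dim} differs from the "
            f"{expected_null_dim} rigid-motion modes expected at a generic "
            "stationary embedding; extra near-null modes signal structural "
            "instability",
            RuntimeWarning,
            stacklevel=2,
        )
    inv = np.where(null_mask, 0.0, 1.0 / np.where(null_mask, 1.0, lam))
    spectrum = HessianSpectrum(
        eigenvalues=lam,
        null_dim=null_dim,
        null_basis=V[:, null_mask],
        rank_tol=rank_tol,
    )

    def apply(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return V @ (inv[:, None] * (V.T @ x)) if x.ndim == 2 else V @ (inv * (V.T @ x))

    return apply, spectrum
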