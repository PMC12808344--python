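"""The sensitivity Jacobian of a converged t-SNE embedding.

At a stationary point ``grad_z C(y*, z*) = 0`` the Implicit Function
Theorem gives the derivative of the optimal-embedding map,

    J = dz*/dy = -H^+ M,

where ``H = d^2C/dz^2`` (singular along rigid motions; Moore-Penrose
pseudoinverse fixes the gauge by assigning those directions zero
sensitivity) and ``M = d^2C/dy dz``.  J is NP x ND, sample-major on both
axes: rows ``2j, 2j+1`` (0-based) are the x/y coordinates of sample j and
column ``m*D + d`` is feature d of sample m.

A finite-difference oracle (perturb one input entry, re-polish the
embedding, rigidly align, central difference) is provided for validation;
alignment removes the rigid-motion components and matches the pseudoinverse
gauge to first order.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg
from sklearn.base import BaseEstimator

from .alignment import rigid_align
from .datasets import Dataset
from .derivatives import (
    HessianSpectrum,
    MixedJacobian,
    hessian_pseudoinverse,
    hessian_vector_product,
    hessian_zz,
    rigid_motion_generators,
)
from .optimize import Embedding, TsneConfig, polish_embedding
from .tsne import _as_values, calibrate_bandwidths, joint_affinities

__all__ = [
    "SensitivityJacobian",
    "sensitivity_jacobian",
    "finite_difference_jacobian",
    "NotConvergedError",
    "TSNESensitivity",
]


class NotConvergedError(RuntimeError):
    """Raised when an uncertified embedding reaches an IFT stage."""


def _require_converged(emb: Embedding, force: bool) -> None:
    if not emb.converged:
        if force:
            warnings.warn(
                "embedding is not certified stationary "
                f"(grad max-norm {emb.final_grad_maxnorm:.3e}); IFT results "
                "lack their theoretical meaning",
                RuntimeWarning,
                stacklevel=3,
            )
        else:
            raise NotConvergedError(
                "embedding is not certified stationary (grad max-norm "
                f"{emb.final_grad_maxnorm:.3e} > grad_tol); polish it first or "
                "pass force=True"
            )


class SensitivityJacobian:
    """Dense sensitivity Jacobian with its labels and Hessian spectrum.

    ``values`` is (N*P, N*D), gauge-fixed by the minimum-norm pseudoinverse:
    rows lie in the orthogonal complement of the rigid-motion null space.
    """

    gauge = "pseudoinverse-minimum-norm"

    def __init__(
        self,
        values: np.ndarray,
        spectrum: HessianSpectrum,
        sample_names: list[str],
        feature_names: list[str],
        out_dim: int,
    ):
        self.values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Jacobian contains non-finite entries")
        self.spectrum = spectrum
        self.sample_names = list(sample_names)
        self.feature_names = list(feature_names)
        self.out_dim = out_dim

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row_labels(self) -> list[str]:
        axes = "xyz"[: self.out_dim] if self.out_dim <= 3 else [
            f"dim{a}" for a in range(self.out_dim)
        ]
        return [f"{s}:{a}" for s in self.sample_names for a in axes]

    def col_labels(self) -> list[str]:
        return [f"{s}:{f}" for s in self.sample_names for f in self.feature_names]


def sensitivity_jacobian(
    data,
    emb: Embedding,
    mode: str = "dense",
    rank_tol: float = 1e-8,
    freeze_sigma: bool = False,
    force: bool = False,
) -> SensitivityJacobian:
    """Compute ``J = -H^+ M`` at a certified stationary embedding.

    Parameters
    ----------
    data : Dataset or ndarray (N, D)
    emb : Embedding
        Must carry ``converged=True`` unless ``force`` is set.
    mode : {"dense", "matrix_free"}
        ``dense`` materializes H and M and multiplies; ``matrix_free``
        builds J column-by-column from deflated conjugate-gradient solves
        against Hessian-vector products and mixed-Jacobian JVPs.  Both
        return the same dense result (the matrix is needed downstream for
        the absolute-value summaries); matrix_free avoids materializing H
        and M.
    rank_tol : float
        Relative eigenvalue threshold below which Hessian modes are treated
        as the null space.
    freeze_sigma : bool
        Treat calibrated bandwidths as constants (documented fallback)
        instead of differentiating the entropy constraint.
    """
    if mode not in {"dense", "matrix_free"}:
        raise ValueError(f"unknown mode {mode!r}")
    _require_converged(emb, force)
    X = _as_values(data)
    n, d = X.shape
    p = emb.out_dim
    cfg = emb.config
    mixed = MixedJacobian(X, emb.coords, cfg.perplexity, freeze_sigma=freeze_sigma)
    _, cond = calibrate_bandwidths(X, cfg.perplexity)
    P = joint_affinities(cond)
    expected_null = p + p * (p - 1) // 2

    if mode == "dense":
        H = hessian_zz(P, emb.coords)
        pinv, spectrum = hessian_pseudoinverse(
            H, rank_tol=rank_tol, expected_null_dim=expected_null
        )
        J = -pinv(mixed.dense())
    else:
        # deflated CG: solve H x = m_k on the complement of the null space
        null = rigid_motion_generators(emb.coords)  # (NP, 3) for P=2
        spectrum = None

        def deflate(v):
            return v - null @ (null.T @ v)

        op = LinearOperator(
            (n * p, n * p),
            matvec=lambda v: deflate(
                hessian_vector_product(P, emb.coords, deflate(v)).ravel()
            )
            + null @ (null.T @ v),  # identity on the null space keeps CG definite
        )
        cols = np.empty((n * p, n * d))
        eye = np.eye(n * d)
        for k in range(n * d):
            mk = mixed.jvp(eye[k]).ravel()
            x, info = cg(op, deflate(mk), rtol=1e-12, atol=0.0, maxiter=10 * n * p)
            if info != 0:
                raise RuntimeError(f"CG failed to converge for Jacobian column {k}")
            cols[:, k] = -deflate(x)
        J = cols
        # spectrum still reported from the dense Hessian (cheap relative to ND solves)
        H = hessian_zz(P, emb.coords)
        _, spectrum = hessian_pseudoinverse(
            H, rank_tol=rank_tol, expected_null_dim=expected_null
        )

    names = (
        (data.sample_names, data.feature_names)
        if isinstance(data, Dataset)
        else ([f"sample{i}" for i in range(n)], [f"feature{j}" for j in range(d)])
    )
    return SensitivityJacobian(J, spectrum, names[0], names[1], p)


def finite_difference_jacobian(
    data,
    emb: Embedding,
    eps: float = 1e-4,
    relative: bool = True,
    basin_jump_factor: float = 50.0,
) -> np.ndarray:
    """Finite-difference oracle for the sensitivity Jacobian.

    For each input entry: perturb by ±eps, re-polish the embedding from z*
    to stationarity, rigidly align each perturbed solution back onto z*
    (removing the rigid-motion gauge freedom), and take the central
    difference.  Columns whose perturbed embedding moves by more than
    ``basin_jump_factor`` times the median displacement are flagged with a
    warning — the perturbed optimization likely jumped to a different basin
    and that column is unreliable.

    Returns the (N*P, N*D) matrix in the same layout as
    :func:`sensitivity_jacobian`.
    """
    _require_converged(emb, force=False)
    X = _as_values(data)
    n, d = X.shape
    p = emb.out_dim
    cfg = emb.config
    scale = float(np.std(X)) if relative else 1.0
    h = eps * (scale if scale > 0 else 1.0)
    J = np.empty((n * p, n * d))
    disps = np.empty(n * d)
    for m in range(n):
        for k in range(d):
            col = m * d + k
            deltas = []
            for sign in (+1.0, -1.0):
                Xp = X.copy()
                Xp[m, k] += sign * h
                pol = polish_embedding(Xp, emb.coords, cfg)
                if not pol.converged:
                    raise NotConvergedError(
                        f"re-polish failed for perturbed entry ({m}, {k})"
                    )
                deltas.append(rigid_align(pol.coords, emb.coords) - emb.coords)
            J[:, col] = ((deltas[0] - deltas[1]) / (2.0 * h)).ravel()
            disps[col] = max(np.abs(deltas[0]).max(), np.abs(deltas[1]).max())
    med = np.median(disps)
    if med > 0:
        jumps = np.nonzero(disps > basin_jump_factor * med)[0]
        if jumps.size:
            warnings.warn(
                f"perturbed optimization likely jumped basins for columns "
                f"{jumps.tolist()}; finite differences there are unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
    return J


class TSNESensitivity(BaseEstimator):
    """Post-hoc sensitivity analysis of a converged t-SNE embedding.

    ``fit(X)`` optimizes (or accepts and polishes) an embedding, computes
    the IFT sensitivity Jacobian and its row/column summaries.

    Parameters
    ----------
    perplexity, grad_tol, random_state : passed to the embedded optimizer.
    rank_tol : relative eigenvalue cutoff for the Hessian pseudoinverse.
    freeze_sigma : treat bandwidths as constants instead of differentiating
        the perplexity constraint.
    mode : "dense" or "matrix_free" Jacobian assembly.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : ndarray (N, 2)
    jacobian_ : SensitivityJacobian
    null_dim_ : int
    eigenvalues_ : ndarray (N*P,)
    feature_influence_ : ndarray (N*D,)  — column-wise absolute sums
    sample_sensitivity_ : ndarray (N,)   — row-wise absolute sums per sample
    """

    def __init__(
        self,
        perplexity: float = 30.0,
        grad_tol: float = 1e-9,
        rank_tol: float = 1e-8,
        freeze_sigma: bool = False,
        mode: str = "dense",
        random_state: int = 0,
        max_iters: int = 20000,
    ):
        self.perplexity = perplexity
        self.grad_tol = grad_tol
        self.rank_tol = rank_tol
        self.freeze_sigma = freeze_sigma
        self.mode = mode
        self.random_state = random_state
        self.max_iters = max_iters

    def fit(self, X, y=None, coords: np.ndarray | None = None):
        from .optimize import optimize_embedding
        from .summaries import feature_influence, sample_sensitivity

        data = X if isinstance(X, Dataset) else np.asarray(X, dtype=float)
        cfg = TsneConfig(
            perplexity=self.perplexity,
            grad_tol=self.grad_tol,
            seed=self.random_state,
            max_iters=self.max_iters,
        )
        if coords is None:
            emb = optimize_embedding(_as_values(data), cfg)
        else:
            emb = polish_embedding(_as_values(data), coords, cfg)
        if not emb.converged:
            raise NotConvergedError(
                "optimizer failed to certify stationarity at grad_tol="
                f"{self.grad_tol:g} (reached {emb.final_grad_maxnorm:.3e})"
            )
        jac = sensitivity_jacobian(
            data, emb, mode=self.mode, rank_tol=self.rank_tol,
            freeze_sigma=self.freeze_sigma,
        )
        self.result_ = emb
        self.embedding_ = emb.coords
        self.jacobian_ = jac
        self.null_dim_ = jac.spectrum.null_dim
        self.eigenvalues_ = jac.spectrum.eigenvalues
        self.feature_influence_ = feature_influence(jac).scores
        self.sample_sensitivity_ = sample_sensitivity(jac).per_sample
        return self
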