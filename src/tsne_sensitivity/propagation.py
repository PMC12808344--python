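"""Gaussian error propagation through the sensitivity Jacobian.

Given input uncertainty ``y ~ N(y*, Sigma_y)``, the first-order Taylor
expansion of the optimal-embedding map gives an approximately Gaussian
output, ``z* ~ N(z*(y*), Sigma_z)`` with ``Sigma_z = J Sigma_y J^T``.
Because J's rows are orthogonal to the rigid-motion null space, Sigma_z is
singular by construction: rigid motions of the map carry no variance.
Sampling therefore uses an eigendecomposition square root (Cholesky would
fail), clipping the tiny negative eigenvalues that roundoff produces.

Hypothetical outcomes are draws ``z* + L xi``; the smooth animation loop
uses two independent draws combined as ``cos(theta) xi_a + sin(theta) xi_b``
so that every frame is marginally ``N(z*, Sigma_z)`` (cos^2 + sin^2 = 1)
while the path is cyclic and infinitely smooth in theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimize import Embedding
from .sensitivity import SensitivityJacobian

__all__ = [
    "InputUncertainty",
    "OutputCovariance",
    "HypotheticalOutcomes",
    "propagate_covariance",
    "sample_outcomes",
    "smooth_loop_path",
]


@dataclass
class InputUncertainty:
    """Gaussian input uncertainty: per-entry variances (diagonal Sigma_y) or
    a full ND x ND covariance.

    The diagonal form is the common case — e.g. per-gene variances of
    replicate means at each timepoint.
    """

    variances: np.ndarray | None = None  # (N, D) diagonal case
    full_cov: np.ndarray | None = None  # (ND, ND)

    def __post_init__(self):
        if (self.variances is None) == (self.full_cov is None):
            raise ValueError("provide exactly one of variances or full_cov")
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
            if np.any(self.variances < 0):
                raise ValueError("variances must be nonnegative")
        else:
            C = np.asarray(self.full_cov, dtype=float)
            if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
                raise ValueError("full covariance must be symmetric")
            lam = np.linalg.eigvalsh(C)
            if lam.min() < -1e-10 * max(lam.max(), 1e-300):
                raise ValueError("full covariance must be positive semidefinite")
            self.full_cov = C

    @property
    def kind(self) -> str:
        return "diagonal" if self.variances is not None else "full"


@dataclass
class OutputCovariance:
    """Propagated embedding covariance Sigma_z (NP x NP, PSD) with the
    per-point P x P marginal blocks extracted for ellipse drawing."""

    values: np.ndarray
    point_marginals: list[np.ndarray]

    @property
    def n_samples(self) -> int:
        return len(self.point_marginals)

    def summary(self) -> dict:
        return {
            "trace": float(np.trace(self.values)),
            "marginal_determinants": [
                float(np.linalg.det(m)) for m in self.point_marginals
            ],
        }


@dataclass
class HypotheticalOutcomes:
    """K sampled embeddings (K, N, P); ``kind`` is "independent" or "loop"
    (cyclic: frame K wraps smoothly to frame 0)."""

    frames: np.ndarray
    kind: str
    seed: int

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("outcome frames must be finite")
        if self.kind not in {"independent", "loop"}:
            raise ValueError(f"unknown outcomes kind {self.kind!r}")


def propagate_covariance(J, unc: InputUncertainty, out_dim: int | None = None) -> OutputCovariance:
    """``Sigma_z = J Sigma_y J^T``; the diagonal case never materializes Sigma_y."""
    vals = J.values if isinstance(J, SensitivityJacobian) else np.asarray(J, dtype=float)
    if out_dim is None:
        out_dim = J.out_dim if isinstance(J, SensitivityJacobian) else 2
    if unc.kind == "diagonal":
        v = unc.variances.ravel()
        if v.size != vals.shape[1]:
            raise ValueError(
                f"variance vector length {v.size} does not match Jacobian "
                f"columns {vals.shape[1]}"
            )
        S = (vals * v) @ vals.T
    else:
        if unc.full_cov.shape[0] != vals.shape[1]:
            raise ValueError("full covariance does not match Jacobian columns")
        S = vals @ unc.full_cov @ vals.T
    S = 0.5 * (S + S.T)
    p = out_dim
    marginals = [S[i * p : (i + 1) * p, i * p : (i + 1) * p] for i in range(S.shape[0] // p)]
    return OutputCovariance(values=S, point_marginals=marginals)


def _sqrt_factor(cov: OutputCovariance) -> np.ndarray:
    lam, V = np.linalg.eigh(cov.values)
    floor = -1e-10 * max(lam.max(), 0.0)
    if lam.min() < floor:
        raise ValueError(
            f"output covariance has a significantly negative eigenvalue "
            f"({lam.min():.3e}); internal error in propagation"
        )
    return V * np.sqrt(np.clip(lam, 0.0, None))


def sample_outcomes(emb: Embedding, cov: OutputCovariance, K: int, seed: int = 0) -> HypotheticalOutcomes:
    """K independent draws from N(z*, Sigma_z), reshaped to (K, N, P)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    n, p = emb.coords.shape
    L = _sqrt_factor(cov)
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((K, n * p))
    frames = emb.coords.ravel()[None, :] + xi @ L.T
    return HypotheticalOutcomes(frames.reshape(K, n, p), "independent", seed)


def smooth_loop_path(emb: Embedding, cov: OutputCovariance, K: int, seed: int = 0) -> HypotheticalOutcomes:
    """A cyclic path of K equiprobable embeddings for smooth animation.

    frame_k = z* + L (cos(theta_k) xi_a + sin(theta_k) xi_b) with
    theta_k = 2 pi k / K; every frame is marginally N(z*, Sigma_z) and the
    path closes on itself (theta wraps).
    """
    if K < 3:
        raise ValueError("a loop needs K >= 3 frames")
    n, p = emb.coords.shape
    L = _sqrt_factor(cov)
    rng = np.random.default_rng(seed)
    xi_a = rng.standard_normal(n * p)
    xi_b = rng.standard_normal(n * p)
    theta = 2.0 * np.pi * np.arange(K) / K
    mix = np.cos(theta)[:, None] * xi_a[None, :] + np.sin(theta)[:, None] * xi_b[None, :]
    frames = emb.coords.ravel()[None, :] + mix @ L.T
    return HypotheticalOutcomes(frames.reshape(K, n, p), "loop", seed)
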