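"""Exact t-SNE primitives: affinities, KL cost and its analytic gradient.

Everything here is the O(N^2) exact formulation.  The later sensitivity
analysis differentiates the stationarity condition of this cost, so the cost
must be evaluated exactly — no Barnes-Hut or interpolation approximations.

Notation (used throughout the package):

* ``Y`` — the N x D input matrix, vectorized row-major as ``y``.
* ``Z`` — the N x P embedding, vectorized row-major as ``z``.
* ``p_{j|i}`` — conditional neighbor probability with per-point bandwidth
  ``sigma_i`` calibrated so the conditional distribution's perplexity
  ``2^{H(p_{.|i})}`` matches the user's perplexity.
* ``p_ij = (p_{j|i} + p_{i|j}) / 2N`` — symmetrized joint affinities.
* ``q_ij`` — Student-t (df=1) low-dimensional affinities.
* ``C = sum_{i != j} p_ij log(p_ij / q_ij)`` — the KL cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datasets import Dataset

__all__ = [
    "AffinityMatrix",
    "DuplicateRowsError",
    "pairwise_sq_distances",
    "calibrate_bandwidths",
    "joint_affinities",
    "low_dim_affinities",
    "student_t_kernel",
    "kl_cost",
    "cost_gradient",
]


class DuplicateRowsError(ValueError):
    """Raised when two input rows coincide; bandwidth calibration diverges."""

    def __init__(self, i: int, j: int):
        self.pair = (i, j)
        super().__init__(
            f"input rows {i} and {j} are identical; perplexity calibration "
            "cannot assign a finite bandwidth (pass jitter=True to break ties)"
        )


@dataclass
class AffinityMatrix:
    """An N x N affinity matrix tagged by its role in the t-SNE cost.

    ``kind`` is one of ``conditional`` (rows sum to 1), ``joint`` (symmetric,
    sums to 1 over all entries) or ``lowdim`` (same, from the Student-t
    kernel).  The diagonal is always zero.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in {"conditional", "joint", "lowdim"}:
            raise ValueError(f"unknown affinity kind {self.kind!r}")
        n, m = self.values.shape
        if n != m:
            raise ValueError("affinity matrix must be square")

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValueError("affinity diagonal must be zero")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("affinities must lie in [0, 1]")
        if self.kind == "conditional":
            if not np.allclose(v.sum(axis=1), 1.0, atol=atol):
                raise ValueError("conditional rows must sum to 1")
        else:
            if not np.allclose(v, v.T, atol=atol):
                raise ValueError(f"{self.kind} affinities must be symmetric")
            if abs(v.sum() - 1.0) > atol:
                raise ValueError(f"{self.kind} affinities must sum to 1")


def _as_values(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.values
    return np.asarray(data, dtype=float)


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, exact and symmetric with zero diagonal."""
    return squareform(pdist(np.asarray(X, dtype=float), "sqeuclidean"))


def _row_conditional(d2_row: np.ndarray, beta: float, i: int) -> tuple[np.ndarray, float]:
    """Conditional distribution of row i at precision beta; returns (p, H2).

    H2 is the Shannon entropy in bits.  Uses the log-sum-exp-stable form
    H_nats = beta * E[d2] + log S.
    """
    w = -beta * d2_row
    w[i] = -np.inf
    w -= w.max()
    e = np.exp(w)
    p = e / e.sum()
    logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), 0.0)
    h_nats = -float(p @ logp)
    return p, h_nats / np.log(2.0)


def calibrate_bandwidths(
    data,
    perplexity: float,
    tol: float = 1e-12,
    max_bisect: int = 200,
    jitter: bool = False,
    seed: int = 0,
):
    """Per-point bandwidths matching a target perplexity, by bisection.

    For each sample ``i`` the precision ``beta_i = 1/(2 sigma_i^2)`` is
    bisected (bracket expansion by doubling, then bisection) until the
    conditional distribution's entropy is within ``tol`` bits of
    ``log2(perplexity)`` or the bracket collapses to machine precision.
    The default tolerance is deliberately near machine precision: the
    sensitivity analysis differentiates the entropy constraint analytically
    and assumes it holds exactly at the converged embedding.

    Parameters
    ----------
    data : Dataset or ndarray (N, D)
    perplexity : float
        Must satisfy ``1 <= perplexity < N - 1``.
    tol : float
        Entropy tolerance in bits.
    max_bisect : int
        Maximum bisection iterations per point; hitting it with a still-open
        bracket emits a warning (the perplexity -> N-1 divergence).
    jitter : bool
        Break exactly duplicated rows with 1e-10 noise instead of raising.

    Returns
    -------
    sigmas : ndarray (N,)
    conditional : AffinityMatrix (kind="conditional")
    """
    X = _as_values(data)
    n = X.shape[0]
    if not (1.0 <= perplexity < n - 1):
        raise ValueError(
            f"perplexity must lie in [1, N-1) = [1, {n - 1}), got {perplexity}"
        )
    d2 = pairwise_sq_distances(X)
    off = d2 + np.diag(np.full(n, np.inf))
    dup = np.argwhere(off == 0.0)
    if dup.size:
        i, j = map(int, dup[0])
        if not jitter:
            raise DuplicateRowsError(i, j)
        rng = np.random.default_rng(seed)
        X = X + 1e-10 * rng.standard_normal(X.shape)
        d2 = pairwise_sq_distances(X)

    target = np.log2(perplexity)
    betas = np.empty(n)
    cond = np.zeros((n, n))
    hit_cap = False
    for i in range(n):
        lo, hi = None, None
        beta = 1.0 / max(np.median(off[i][np.isfinite(off[i])]), 1e-12)
        p, h = _row_conditional(d2[i].copy(), beta, i)
        for _ in range(max_bisect):
            if abs(h - target) <= tol:
                break
            if lo is not None and hi is not None and hi - lo <= 1e-15 * hi:
                break  # bracket exhausted at machine precision
            if h > target:  # too entropic -> narrow kernel -> raise beta
                lo = beta
                beta = beta * 2.0 if hi is None else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = beta / 2.0 if lo is None else 0.5 * (beta + lo)
            p, h = _row_conditional(d2[i].copy(), beta, i)
        else:
            hit_cap = True
        betas[i] = beta
        cond[i] = p
        cond[i, i] = 0.0
    if hit_cap:
        warnings.warn(
            "perplexity calibration hit the bisection cap for at least one "
            "point; achieved perplexities may miss the target",
            RuntimeWarning,
            stacklevel=2,
        )
    sigmas = np.sqrt(1.0 / (2.0 * betas))
    return sigmas, AffinityMatrix(cond, "conditional")


def joint_affinities(conditional: AffinityMatrix, n: int | None = None) -> AffinityMatrix:
    """Symmetrize conditional affinities: ``p_ij = (p_{j|i} + p_{i|j}) / 2N``."""
    if conditional.kind != "conditional":
        raise ValueError("joint_affinities expects a conditional affinity matrix")
    P = conditional.values
    if n is None:
        n = P.shape[0]
    return AffinityMatrix((P + P.T) / (2.0 * n), "joint")


def student_t_kernel(coords: np.ndarray) -> np.ndarray:
    """Unnormalized heavy-tailed kernel ``w_ij = 1/(1+||z_i-z_j||^2)``, zero diag."""
    Z = np.asarray(coords, dtype=float)
    W = 1.0 / (1.0 + pairwise_sq_distances(Z))
    np.fill_diagonal(W, 0.0)
    return W


def low_dim_affinities(coords: np.ndarray) -> AffinityMatrix:
    """Student-t joint affinities of the embedding (normalized over ordered pairs)."""
    W = student_t_kernel(coords)
    return AffinityMatrix(W / W.sum(), "lowdim")


def kl_cost(joint: AffinityMatrix, coords: np.ndarray) -> float:
    """KL divergence ``C = sum_{i != j} p_ij log(p_ij / q_ij)``.

    Terms with ``p_ij = 0`` contribute zero; ``q_ij`` is strictly positive
    off-diagonal by construction of the Student-t kernel.
    """
    if joint.kind != "joint":
        raise ValueError("kl_cost expects joint affinities")
    P = joint.values
    Q = low_dim_affinities(coords).values
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def cost_gradient(joint: AffinityMatrix, coords: np.ndarray) -> np.ndarray:
    """Analytic gradient dC/dz_i = 4 sum_j (p_ij - q_ij) w_ij (z_i - z_j).

    Returns an (N, P) array.  Antisymmetry of the summand makes the gradient
    components sum to zero over samples (translation invariance of C).
    """
    if joint.kind != "joint":
        raise ValueError("cost_gradient expects joint affinities")
    Z = np.asarray(coords, dtype=float)
    P = joint.values
    W = student_t_kernel(Z)
    Q = W / W.sum()
    M = (P - Q) * W
    return 4.0 * (M.sum(axis=1)[:, None] * Z - M @ Z)
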