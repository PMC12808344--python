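"""Rigid Procrustes alignment of embeddings.

The t-SNE cost is invariant under rigid motions of the embedding, so two
solutions of the same (or a perturbed) problem are only comparable after
removing an arbitrary translation and rotation.  Aligning a perturbed
embedding onto a reference by least-squares rigid Procrustes (rotation +
translation, no scaling) projects out exactly the rigid-motion components
— to first order the same gauge the Hessian pseudoinverse fixes, which is
what makes finite-difference Jacobians comparable to the analytic ones.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes

__all__ = ["rigid_align"]


def rigid_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly align ``coords`` onto ``reference`` (rotation + translation).

    Solves ``min_R,t || (coords - mean) R + mean_ref - reference ||_F`` over
    orthogonal R; no scaling is applied, preserving the embedding's metric
    structure.
    """
    X = np.asarray(coords, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if X.shape != ref.shape:
        raise ValueError("coords and reference must have the same shape")
    mu_x = X.mean(axis=0)
    mu_r = ref.mean(axis=0)
    R, _ = orthogonal_procrustes(X - mu_x, ref - mu_r)
    return (X - mu_x) @ R + mu_r
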