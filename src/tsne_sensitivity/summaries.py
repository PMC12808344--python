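"""Scalar summaries of the sensitivity Jacobian.

Column-wise absolute sums give a *feature influence* score per input entry
(which measurements shape the whole map); row-wise absolute sums give a
*sample sensitivity* score per embedded point (whose position is fragile).
Both conserve the total absolute mass of the Jacobian, so the two views are
different marginals of the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivity import SensitivityJacobian

__all__ = ["FeatureInfluence", "SampleSensitivity", "feature_influence", "sample_sensitivity"]


def _values(J) -> np.ndarray:
    return J.values if isinstance(J, SensitivityJacobian) else np.asarray(J, dtype=float)


@dataclass
class FeatureInfluence:
    """Per-input-entry influence scores ``s_k = sum_i |J_ik|`` (length N*D).

    ``reshape(N, D)`` views the flat scores as a samples x features matrix
    (for a time series: timepoints x genes).  ``zscored`` optionally
    standardizes each feature column for cross-dataset comparability; the
    raw sums are the primary quantity.
    """

    scores: np.ndarray
    labels: list[tuple[str, str]] | None = None

    def reshape(self, n_samples: int, n_features: int) -> np.ndarray:
        if n_samples * n_features != self.scores.size:
            raise ValueError(
                f"layout {n_samples}x{n_features} does not tile {self.scores.size} scores"
            )
        return self.scores.reshape(n_samples, n_features)

    def zscored(self, n_samples: int, n_features: int) -> np.ndarray:
        mat = self.reshape(n_samples, n_features)
        sd = mat.std(axis=0, ddof=0)
        return (mat - mat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)


@dataclass
class SampleSensitivity:
    """Row summaries: ``r_i = sum_k |J_ik|`` per embedding coordinate and
    ``S_j = r_{2j-1} + r_{2j}`` per sample (1-based row indexing)."""

    per_coord: np.ndarray
    per_sample: np.ndarray


def feature_influence(J) -> FeatureInfluence:
    """Column-wise absolute sums of the Jacobian over all 2N embedding coords."""
    vals = _values(J)
    scores = np.abs(vals).sum(axis=0)
    labels = None
    if isinstance(J, SensitivityJacobian):
        labels = [(s, f) for s in J.sample_names for f in J.feature_names]
    return FeatureInfluence(scores=scores, labels=labels)


def sample_sensitivity(J, out_dim: int | None = None) -> SampleSensitivity:
    """Row-wise absolute sums, aggregated over each sample's P coordinates."""
    vals = _values(J)
    if out_dim is None:
        out_dim = J.out_dim if isinstance(J, SensitivityJacobian) else 2
    r = np.abs(vals).sum(axis=1)
    if r.size % out_dim:
        raise ValueError(f"row count {r.size} not divisible by out_dim {out_dim}")
    S = r.reshape(-1, out_dim).sum(axis=1)
    return SampleSensitivity(per_coord=r, per_sample=S)
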