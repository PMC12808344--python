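"""Synthetic fixtures with the statistical structure of the target use cases.

Two generators cover the two analysis settings the pipeline is built for:

* :func:`make_clusters` — Gaussian cluster mixtures, optionally with one
  deliberately under-separated pair, emulating cell-type structure where
  some populations (e.g. closely related T-cell subtypes) overlap.
* :func:`make_timeseries` — a replicated expression time course on a log
  scale: ``T`` timepoints x ``R`` replicates x ``G`` genes, with a block of
  "switch" genes upregulated from an onset timepoint onwards, emulating a
  metabolic-switch experiment.  :func:`replicate_moments` reduces the
  replicate tensor to per-timepoint means (the point estimate) and the
  variance of those means (the diagonal input covariance), the standard
  preparation for uncertainty propagation.

These are Gaussian caricatures: no count noise, dropout or library-size
effects — enough structure to exercise the math, not to mimic real assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .propagation import InputUncertainty

__all__ = [
    "ClusterSpec",
    "TimeSeriesSpec",
    "make_clusters",
    "make_timeseries",
    "replicate_moments",
]


@dataclass
class ClusterSpec:
    """Gaussian blob mixture layout.

    ``separation`` is the pairwise centroid distance (centroids sit at the
    vertices of a regular simplex, so ``n_clusters <= dim + 1``).
    ``overlap_pair`` optionally names two clusters whose separation is
    reduced to ``overlap_separation`` to create an ambiguous boundary.
    """

    n_clusters: int = 3
    points_per_cluster: int = 10
    dim: int = 5
    separation: float = 2.0
    sd: float = 1.0
    overlap_pair: tuple[int, int] | None = None
    overlap_separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1 or self.points_per_cluster < 1 or self.dim < 1:
            raise ValueError("counts must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n_clusters > self.dim + 1:
            raise ValueError("a regular simplex needs n_clusters <= dim + 1")
        if self.overlap_pair is not None:
            a, b = self.overlap_pair
            if not (0 <= a < self.n_clusters and 0 <= b < self.n_clusters and a != b):
                raise ValueError("overlap_pair must name two distinct clusters")


def _simplex_centroids(k: int, dim: int, edge: float) -> np.ndarray:
    """k points in R^dim, all pairwise distances equal to ``edge``."""
    # centred identity corners have all pairwise distances sqrt(2) and span
    # a (k-1)-dimensional subspace; express them in that subspace before
    # padding, so distances survive the embedding into R^dim
    corners = np.eye(k) - 1.0 / k
    U, s, _ = np.linalg.svd(corners, full_matrices=False)
    flat = U[:, : k - 1] * s[: k - 1]
    flat *= edge / np.sqrt(2.0)
    out = np.zeros((k, dim))
    out[:, : k - 1] = flat
    return out


def make_clusters(spec: ClusterSpec) -> tuple[Dataset, np.ndarray]:
    """Sample a Gaussian cluster mixture; returns (Dataset, integer labels)."""
    rng = np.random.default_rng(spec.seed)
    cent = _simplex_centroids(spec.n_clusters, spec.dim, spec.separation)
    if spec.overlap_pair is not None:
        a, b = spec.overlap_pair
        direction = cent[b] - cent[a]
        direction /= np.linalg.norm(direction)
        cent[b] = cent[a] + spec.overlap_separation * direction
    labels = np.repeat(np.arange(spec.n_clusters), spec.points_per_cluster)
    X = cent[labels] + spec.sd * rng.standard_normal((labels.size, spec.dim))
    data = Dataset(
        X,
        sample_names=[f"c{c}_s{i}" for c in range(spec.n_clusters)
                      for i in range(spec.points_per_cluster)],
        feature_names=[f"f{j}" for j in range(spec.dim)],
    )
    return data, labels


@dataclass
class TimeSeriesSpec:
    """Replicated log-scale expression time course with a switch-gene block.

    The block spans ``switch_genes = (start, stop)`` (half-open) and is
    shifted by ``log2(fold_change)`` at timepoints ``>= onset`` (0-based),
    on top of a per-gene constant baseline, plus i.i.d. Gaussian noise per
    entry.  Defaults mirror a bacterial phosphate-depletion course: 8
    timepoints, 3 biological replicates, a late-onset antibiotic-synthesis
    block with a strong (8-fold) induction.
    """

    T: int = 8
    R: int = 3
    G: int = 60
    switch_genes: tuple[int, int] = (0, 6)
    onset: int = 4
    fold_change: float = 8.0
    noise_sd: float = 0.25
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.onset < self.T):
            raise ValueError("onset must lie within the time course")
        lo, hi = self.switch_genes
        if not (0 <= lo <= hi <= self.G):
            raise ValueError("switch gene range must lie within [0, G]")
        if self.fold_change <= 0 or self.noise_sd < 0:
            raise ValueError("fold_change must be positive, noise_sd nonnegative")


def make_timeseries(spec: TimeSeriesSpec) -> np.ndarray:
    """Simulate the replicate tensor, shape (T, R, G), log2 expression units."""
    rng = np.random.default_rng(spec.seed)
    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.G)
    signal = np.tile(baseline, (spec.T, 1))
    lo, hi = spec.switch_genes
    signal[spec.onset :, lo:hi] += np.log2(spec.fold_change)
    noise = spec.noise_sd * rng.standard_normal((spec.T, spec.R, spec.G))
    return signal[:, None, :] + noise


def replicate_moments(tensor: np.ndarray) -> tuple[Dataset, InputUncertainty]:
    """Per-timepoint means and variance-of-the-mean from a (T, R, G) tensor.

    The mean over replicates is the point estimate; its sampling variance is
    the unbiased replicate variance (ddof=1) divided by R.  Requires R >= 2.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("expected a (T, R, G) replicate tensor")
    T, R, G = tensor.shape
    if R < 2:
        raise ValueError("variance of the mean is undefined for R < 2 replicates")
    means = tensor.mean(axis=1)
    var_of_mean = tensor.var(axis=1, ddof=1) / R
    data = Dataset(
        means,
        sample_names=[f"t{t + 1}" for t in range(T)],
        feature_names=[f"g{g}" for g in range(G)],
    )
    return data, InputUncertainty(variances=var_of_mean)
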