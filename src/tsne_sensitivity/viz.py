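"""Visualizations of the Jacobian, its summaries, and positional uncertainty.

Four complementary views of one analysis:

* a signed heatmap of the full Jacobian (embedding coordinates x input
  features, diverging colormap centred at zero),
* a sequential heatmap of column-summarized feature influence (reshapable
  to e.g. timepoints x genes),
* the embedding scatter with points filled by sample sensitivity (optionally
  bordered by group labels), and
* uncertainty-aware plots: per-point confidence ellipses from the 2x2
  marginals of Sigma_z, a semi-transparent overlay of hypothetical
  outcomes, or an animated GIF of the smooth loop path.

All functions are pure file producers: the same inputs and spec yield
byte-identical output files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse
from scipy.stats import chi2

from .optimize import Embedding
from .propagation import HypotheticalOutcomes, OutputCovariance
from .summaries import FeatureInfluence, SampleSensitivity

__all__ = [
    "PlotSpec",
    "plot_jacobian_heatmap",
    "plot_influence_heatmap",
    "plot_sensitivity_scatter",
    "plot_uncertainty",
    "ellipse_axes",
]

# beyond this many cells a Jacobian heatmap is unreadable and enormous;
# summarized views are the intended fallback
HEATMAP_CELL_GUARD = 2_000_000


@dataclass
class PlotSpec:
    """Figure styling shared by all plots."""

    sequential_cmap: str = "viridis"
    diverging_cmap: str = "RdBu_r"
    figsize: tuple[float, float] = (6.0, 5.0)
    dpi: int = 120
    point_size: float = 45.0
    border_cmap: str = "tab10"
    ellipse_quantile: float = 0.68
    frame_rate: int = 10
    alpha_overlay: float = 0.15

    def __post_init__(self):
        if not (0.0 < self.ellipse_quantile < 1.0):
            raise ValueError("ellipse_quantile must lie in (0, 1)")


def _save(fig, path: str | Path) -> Path:
    """Deterministic PNG export (no timestamps or software metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format=path.suffix.lstrip(".") or "png",
                metadata={"Software": None}, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_jacobian_heatmap(J, path, spec: PlotSpec | None = None,
                          force: bool = False) -> Path:
    """Signed heatmap of the full Jacobian, diverging colors centred at 0."""
    spec = spec or PlotSpec()
    vals = J.values if hasattr(J, "values") else np.asarray(J, dtype=float)
    if vals.size > HEATMAP_CELL_GUARD and not force:
        raise ValueError(
            f"Jacobian has {vals.size} cells (> {HEATMAP_CELL_GUARD}); plot a "
            "summary instead, or pass force=True"
        )
    vmax = np.abs(vals).max() or 1.0
    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    im = ax.imshow(vals, cmap=spec.diverging_cmap, vmin=-vmax, vmax=vmax,
                   aspect="auto", interpolation="nearest")
    ax.set_xlabel("input entry (sample-major: sample x feature)")
    ax.set_ylabel("embedding coordinate (sample-major)")
    ax.set_title("sensitivity Jacobian  dz*/dy")
    fig.colorbar(im, ax=ax, label="d coordinate / d input")
    return _save(fig, path)


def plot_influence_heatmap(inf: FeatureInfluence, layout: tuple[int, int], path,
                           spec: PlotSpec | None = None,
                           feature_names: list[str] | None = None,
                           sort_columns: bool = False) -> Path:
    """Sequential heatmap of feature-influence scores reshaped to ``layout``."""
    spec = spec or PlotSpec()
    mat = inf.reshape(*layout)
    order = np.arange(mat.shape[1])
    if sort_columns:
        order = np.argsort(-mat.sum(axis=0), kind="stable")
        mat = mat[:, order]
    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    im = ax.imshow(mat, cmap=spec.sequential_cmap, aspect="auto",
                   interpolation="nearest")
    ax.set_xlabel("feature")
    ax.set_ylabel("sample")
    ax.set_title("feature influence  $s_k = \\sum_i |J_{ik}|$")
    if feature_names is not None and len(feature_names) == mat.shape[1]:
        ax.set_xticks(range(mat.shape[1]))
        ax.set_xticklabels([feature_names[o] for o in order], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="influence score")
    return _save(fig, path)


def plot_sensitivity_scatter(emb: Embedding, S: SampleSensitivity, path,
                             groups: np.ndarray | None = None,
                             spec: PlotSpec | None = None) -> Path:
    """Embedding scatter filled by per-sample sensitivity scores.

    Optional group labels are drawn as colored point borders so that
    cluster identity stays readable under the sensitivity fill.
    """
    spec = spec or PlotSpec()
    Z = emb.coords
    fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
    edge = None
    if groups is not None:
        cmap = plt.get_cmap(spec.border_cmap)
        uniq = {g: i for i, g in enumerate(np.unique(groups))}
        edge = [cmap(uniq[g] % cmap.N) for g in groups]
    sc = ax.scatter(Z[:, 0], Z[:, 1], c=S.per_sample, cmap=spec.sequential_cmap,
                    s=spec.point_size, edgecolors=edge, linewidths=1.2)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title("sample sensitivity  $S_j$")
    fig.colorbar(sc, ax=ax, label="sensitivity score")
    return _save(fig, path)


def ellipse_axes(marginal: np.ndarray, quantile: float) -> tuple[np.ndarray, np.ndarray]:
    """Semi-axes and principal directions of a confidence ellipse.

    The ellipse ``{x : x^T Sigma^-1 x <= chi2_q(2)}`` has semi-axis lengths
    ``sqrt(lambda_i * chi2_q)`` along Sigma's eigenvectors.
    """
    lam, V = np.linalg.eigh(np.asarray(marginal, dtype=float))
    lam = np.clip(lam, 0.0, None)
    r = float(chi2.ppf(quantile, df=2))
    return np.sqrt(lam * r), V


def _scatter_frame(ax, Z, groups, spec: PlotSpec, alpha: float = 1.0):
    color = "0.3"
    if groups is not None:
        cmap = plt.get_cmap(spec.border_cmap)
        uniq = {g: i for i, g in enumerate(np.unique(groups))}
        color = [cmap(uniq[g] % cmap.N) for g in groups]
    ax.scatter(Z[:, 0], Z[:, 1], c=color, s=spec.point_size, alpha=alpha)


def plot_uncertainty(emb: Embedding, cov: OutputCovariance | None, path,
                     outcomes: HypotheticalOutcomes | None = None,
                     mode: str = "ellipses",
                     groups: np.ndarray | None = None,
                     spec: PlotSpec | None = None) -> Path:
    """Uncertainty-aware embedding plot.

    mode="ellipses": confidence ellipses from the 2x2 marginals of Sigma_z
    at ``spec.ellipse_quantile``.  mode="overlay": all outcome frames as
    semi-transparent points.  mode="animation": the loop path written as a
    GIF (requires outcomes with kind="loop").
    """
    spec = spec or PlotSpec()
    Z = emb.coords
    if mode == "ellipses":
        if cov is None:
            raise ValueError("ellipses mode needs an OutputCovariance")
        fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
        _scatter_frame(ax, Z, groups, spec)
        for i, marg in enumerate(cov.point_marginals):
            axes, V = ellipse_axes(marg, spec.ellipse_quantile)
            angle = float(np.degrees(np.arctan2(V[1, -1], V[0, -1])))
            ax.add_patch(Ellipse(Z[i], width=2 * axes[-1], height=2 * axes[0],
                                 angle=angle, fill=False, color="0.4", lw=1.0))
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.set_title(f"{spec.ellipse_quantile:.0%} confidence ellipses")
        return _save(fig, path)
    if mode == "overlay":
        if outcomes is None:
            raise ValueError("overlay mode needs HypotheticalOutcomes")
        fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
        for frame in outcomes.frames:
            _scatter_frame(ax, frame, groups, spec, alpha=spec.alpha_overlay)
        _scatter_frame(ax, Z, groups, spec)
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.set_title(f"{outcomes.frames.shape[0]} hypothetical outcomes")
        return _save(fig, path)
    if mode == "animation":
        if outcomes is None or outcomes.kind != "loop":
            raise ValueError("animation mode requires loop-path outcomes")
        return _write_gif(emb, outcomes, path, groups, spec)
    raise ValueError(f"unknown uncertainty mode {mode!r}")


def _write_gif(emb: Embedding, outcomes: HypotheticalOutcomes, path,
               groups, spec: PlotSpec) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    allpts = outcomes.frames.reshape(-1, outcomes.frames.shape[-1])
    pad = 0.05 * (allpts.max(axis=0) - allpts.min(axis=0) + 1e-12)
    lims = (allpts.min(axis=0) - pad, allpts.max(axis=0) + pad)
    images = []
    for frame in outcomes.frames:
        fig, ax = plt.subplots(figsize=spec.figsize, dpi=spec.dpi)
        _scatter_frame(ax, frame, groups, spec)
        ax.set_xlim(lims[0][0], lims[1][0])
        ax.set_ylim(lims[0][1], lims[1][1])
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        buf = _io.BytesIO()
        fig.savefig(buf, format="png", metadata={"Software": None})
        plt.close(fig)
        buf.seek(0)
        images.append(iio.imread(buf.getvalue(), extension=".png"))
    iio.imwrite(path, images, extension=".gif",
                duration=1000.0 / spec.frame_rate, loop=0)
    return path
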