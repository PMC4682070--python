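"""Shape modes: K-means in eigenshape-score space with validity indices.

Representative morphologies ("shape modes") are the K-means cluster
centroids of the per-cell eigenshape scores.  The number of modes is
selected by minimizing the Xie–Beni index

    XB = sum_i ||x_i - c_label(i)||^2 / (n * min_{j != k} ||c_j - c_k||^2)

(hard assignments, since K-means is used); a Dunn-style separation index

    SEP = min_{j != k} ||c_j - c_k|| / max_k diameter(cluster k)

is reported alongside as a diagnostic.  Each centroid is mapped back
through the eigenshape basis to a reconstructed outline for the mode
gallery, and mode ids are ordered by descending cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .eigen import EigenshapeModel
from .errors import InvalidClusteringError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeModeModel",
    "ModeDistribution",
    "cluster_validity",
    "select_num_modes",
    "fit_shape_modes",
    "mode_distribution",
    "mode_gallery_frame",
    "plot_mode_gallery",
]

#: sentinel replacing an infinite separation when every cluster has zero scatter
SEPARATION_CAP = 1e12


def cluster_validity(scores: np.ndarray, centroids: np.ndarray,
                     labels: np.ndarray):
    """Xie–Beni and separation indices of a hard clustering.

    ``labels`` are 0-based cluster indices into ``centroids``.
    """
    X = np.asarray(scores, float)
    C = np.asarray(centroids, float)
    labels = np.asarray(labels)
    K = C.shape[0]
    if K < 2:
        raise InvalidClusteringError("validity indices need >= 2 clusters")
    counts = np.bincount(labels, minlength=K)
    if np.any(counts == 0):
        raise InvalidClusteringError("empty cluster in validity computation")

    d2 = np.sum((X - C[labels]) ** 2)
    between = pdist(C)
    min_between = float(between.min())
    xie_beni = float(d2 / (X.shape[0] * min_between ** 2)) if min_between > 0 \
        else np.inf

    diameters = np.zeros(K)
    for k in range(K):
        pts = X[labels == k]
        diameters[k] = pdist(pts).max() if pts.shape[0] > 1 else 0.0
    max_diam = diameters.max()
    separation = min_between / max_diam if max_diam > 0 else SEPARATION_CAP
    return xie_beni, float(min(separation, SEPARATION_CAP))


def _kmeans(X: np.ndarray, K: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                random_state=seed)
    km.fit(X)
    return km


def select_num_modes(scores: np.ndarray, k_min: int = 2, k_max: int = 10,
                     seed: int = 0, n_init: int = 20):
    """Run K-means across a candidate range and pick K by the Xie–Beni index.

    Returns ``(K_best, diagnostics)``: diagnostics is a DataFrame with one
    row per candidate K (xie_beni, separation, inertia) plus a
    ``low_confidence`` attribute flag set when no interior Xie–Beni
    minimum exists (e.g. a single isotropic cloud).
    """
    X = np.asarray(scores, float)
    if X.ndim == 1:
        X = X[:, None]
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be smaller than the number of cells")
    rows = []
    for K in range(k_min, k_max + 1):
        try:
            km = _kmeans(X, K, seed, n_init)
            xb, sep = cluster_validity(X, km.cluster_centers_, km.labels_)
            rows.append({"K": K, "xie_beni": xb, "separation": sep,
                         "inertia": km.inertia_})
        except InvalidClusteringError as e:
            logger.warning("K=%d rejected: %s", K, e)
    if not rows:
        raise SelectionError("no candidate K produced a valid clustering")
    diag = pd.DataFrame(rows)
    best_pos = int(diag["xie_beni"].idxmin())
    K_best = int(diag.loc[best_pos, "K"])
    # no interior minimum (flat or boundary argmin) => weak cluster structure
    low_confidence = bool(K_best == diag["K"].max()
                          or not np.isfinite(diag.loc[best_pos, "xie_beni"]))
    diag.attrs["low_confidence"] = low_confidence
    diag.attrs["K_best"] = K_best
    return K_best, diag


@dataclass
class ShapeModeModel:
    """K-means shape modes: centroids, labels (1..K), gallery outlines."""

    K: int
    centroids: np.ndarray            # (K, m) in score space, mode order
    mode_outlines: list              # K reconstructed (n_points, 2) outlines
    labels: np.ndarray               # per-cell mode id in 1..K
    diagnostics: pd.DataFrame | None
    seed: int
    n_init: int
    compartment: str = "cell"

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid mode ids (1..K) for new score vectors."""
        X = np.atleast_2d(np.asarray(scores, float))
        d = ((X[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1


def fit_shape_modes(scores: np.ndarray, K: int, eigen_model: EigenshapeModel,
                    seed: int = 0, n_init: int = 20,
                    diagnostics: pd.DataFrame | None = None) -> ShapeModeModel:
    """Fit K shape modes; mode ids are sorted by descending cluster size."""
    X = np.asarray(scores, float)
    if X.ndim == 1:
        X = X[:, None]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > X.shape[0]:
        raise ValueError("K cannot exceed the number of cells")
    if K == 1:
        centroids = X.mean(axis=0, keepdims=True)
        raw_labels = np.zeros(X.shape[0], int)
    else:
        km = _kmeans(X, K, seed, n_init)
        centroids = km.cluster_centers_
        raw_labels = km.labels_
    counts = np.bincount(raw_labels, minlength=K)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(K, int)
    remap[order] = np.arange(K)
    labels = remap[raw_labels] + 1
    centroids = centroids[order]
    outlines = [eigen_model.reconstruct_outline(c) for c in centroids]
    return ShapeModeModel(K=K, centroids=centroids, mode_outlines=outlines,
                          labels=labels, diagnostics=diagnostics, seed=seed,
                          n_init=n_init, compartment=eigen_model.compartment)


def mode_gallery_frame(model: ShapeModeModel) -> pd.DataFrame:
    """Mode outlines as a long table (mode, vertex_index, x, y)."""
    rows = []
    for k, outline in enumerate(model.mode_outlines, start=1):
        rows.append(pd.DataFrame({
            "mode": k, "vertex_index": np.arange(outline.shape[0]),
            "x": outline[:, 0], "y": outline[:, 1]}))
    return pd.concat(rows, ignore_index=True)


def plot_mode_gallery(model: ShapeModeModel, path=None):
    """Montage of reconstructed mode outlines, one panel per mode.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = model.K
    ncol = min(K, 5)
    nrow = int(np.ceil(K / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2 * ncol, 2 * nrow),
                             squeeze=False)
    counts = np.bincount(model.labels - 1, minlength=K)
    for k in range(nrow * ncol):
        ax = axes[k // ncol][k % ncol]
        ax.set_axis_off()
        if k < K:
            o = model.mode_outlines[k]
            closed = np.vstack([o, o[:1]])
            ax.plot(closed[:, 0], closed[:, 1], lw=1.5)
            ax.set_title(f"mode {k + 1} ({counts[k]})", fontsize=8)
            ax.set_aspect("equal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


@dataclass
class ModeDistribution:
    """Per-sample empirical shape-mode frequencies, marginal and joint."""

    sample_id: str
    p_nucleus: np.ndarray        # (K_N,) P(NS_k)
    p_cell: np.ndarray           # (K_C,) P(CS_j)
    p_joint: np.ndarray          # (K_N, K_C) P(NS_k & CS_j)
    n_cells: int


def mode_distribution(labels_nucleus, labels_cell, K_N: int, K_C: int,
                      sample_id: str = "") -> ModeDistribution:
    """Empirical marginal and joint shape-mode frequencies for paired labels."""
    ln = np.asarray(labels_nucleus, int)
    lc = np.asarray(labels_cell, int)
    if ln.shape != lc.shape:
        raise ValueError("nucleus and cell label vectors must be paired")
    n = ln.size
    if n == 0:
        raise ValueError("no cells")
    if ln.min() < 1 or ln.max() > K_N or lc.min() < 1 or lc.max() > K_C:
        raise ValueError("labels out of the 1..K range")
    joint = np.zeros((K_N, K_C))
    np.add.at(joint, (ln - 1, lc - 1), 1.0)
    joint /= n
    return ModeDistribution(sample_id=sample_id,
                            p_nucleus=joint.sum(axis=1),
                            p_cell=joint.sum(axis=0),
                            p_joint=joint, n_cells=n)
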