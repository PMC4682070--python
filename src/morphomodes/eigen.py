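"""Eigenshape model: PCA on registered boundary-coordinate vectors.

Each registered shape is a 100-number vector (x1..x50, y1..y50); PCA on
the pooled population yields *eigenshapes*, the orthonormal directions
of shape variation.  The model keeps the smallest number of components
whose cumulative explained variance reaches the configured threshold
(default 95%), and maps shapes to projection scores in that basis.
Covariance (not correlation) PCA is used: after normalization all
coordinates share the same dimensionless units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["EigenshapeModel", "fit_eigenshapes", "project_and_reconstruct"]

_ZERO_VAR = 1e-24


@dataclass
class EigenshapeModel:
    """Mean shape, orthonormal eigenshapes, and explained-variance spectrum."""

    mean_shape: np.ndarray        # (d,)
    components: np.ndarray        # (m, d), rows orthonormal
    explained_fraction: np.ndarray  # (m,), nonincreasing
    variance_threshold: float
    compartment: str = "cell"
    full_spectrum: np.ndarray | None = None  # all ratios, for bookkeeping

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct_outline(self, scores: np.ndarray) -> np.ndarray:
        """Map an m-vector of scores back to a (n_points, 2) outline."""
        flat = self.mean_shape + np.asarray(scores, float) @ self.components
        n = flat.size // 2
        return np.column_stack([flat[:n], flat[n:]])

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(f"{prefix}_mean.csv", self.mean_shape[None], delimiter=",")
        np.savetxt(f"{prefix}_components.csv", self.components, delimiter=",")
        np.savetxt(f"{prefix}_explained.csv", self.explained_fraction[None],
                   delimiter=",")
        meta = {"variance_threshold": self.variance_threshold,
                "compartment": self.compartment,
                "n_components": int(self.n_components)}
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "EigenshapeModel":
        prefix = Path(prefix)
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
        mean = np.loadtxt(f"{prefix}_mean.csv", delimiter=",")
        comps = np.loadtxt(f"{prefix}_components.csv", delimiter=",")
        expl = np.atleast_1d(np.loadtxt(f"{prefix}_explained.csv", delimiter=","))
        comps = np.atleast_2d(comps)
        return cls(mean_shape=mean, components=comps, explained_fraction=expl,
                   variance_threshold=meta["variance_threshold"],
                   compartment=meta["compartment"])


def fit_eigenshapes(features: np.ndarray, variance_threshold: float = 0.95,
                    compartment: str = "cell") -> EigenshapeModel:
    """Fit the eigenshape basis on an (n, d) feature matrix.

    The number of retained components m is the smallest count whose
    cumulative explained-variance fraction reaches ``variance_threshold``.
    Zero-variance data yield an empty (m = 0) model.
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n >= 2, d) feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")

    mean = X.mean(axis=0)
    total_var = float(np.sum(np.var(X, axis=0)))
    if total_var <= _ZERO_VAR:
        logger.warning("zero-variance feature matrix: empty eigenshape model")
        return EigenshapeModel(mean_shape=mean,
                               components=np.empty((0, X.shape[1])),
                               explained_fraction=np.empty(0),
                               variance_threshold=variance_threshold,
                               compartment=compartment,
                               full_spectrum=np.empty(0))

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    # discard numerically-zero directions so exact low-rank data report
    # cumulative explained variance 1.0 with exactly rank components
    nonzero = ratios > 1e-12
    ratios = ratios[nonzero]
    comps = pca.components_[nonzero]
    cum = np.cumsum(ratios)
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = min(m, ratios.size)

    comps = comps[:m].copy()
    # deterministic sign: largest-magnitude entry of each component positive
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return EigenshapeModel(mean_shape=mean, components=comps,
                           explained_fraction=ratios[:m].copy(),
                           variance_threshold=variance_threshold,
                           compartment=compartment,
                           full_spectrum=ratios.copy())


def project_and_reconstruct(model: EigenshapeModel, features: np.ndarray):
    """Project features onto the eigenshape basis and reconstruct.

    Returns ``(scores, reconstructions, residual_fraction)`` where
    ``residual_fraction`` is the fraction of these data's variance not
    captured by the retained components.
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[1] != model.mean_shape.size:
        raise ValueError(
            f"feature width {X.shape} does not match model width "
            f"{model.mean_shape.size}")
    centered = X - model.mean_shape
    scores = centered @ model.components.T
    recon = model.mean_shape + scores @ model.components
    total = float(np.sum(centered ** 2))
    if total <= _ZERO_VAR:
        residual = 0.0
    else:
        residual = float(np.sum((X - recon) ** 2) / total)
    return scores, recon, residual
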