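"""Heterogeneity metrics: size CVs and shape-mode entropies.

The five-metric panel per sample: coefficient of variation of nucleus
and cell size (CV(R_N), CV(R_C)), Shannon entropy of the nucleus and
cell shape-mode distributions (S(NS), S(CS)), and the entropy of the
paired nucleus-cell mode distribution (S(NS&CS)).  Entropies are in bits
(log base 2); probabilities are computed against the global mode
catalogues so panels are comparable across samples; CV uses the sample
(n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modes import mode_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "coefficient_of_variation",
    "shannon_entropy",
    "joint_entropy",
    "HeterogeneityPanel",
    "heterogeneity_panel",
    "panels_to_frame",
]


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(v.std(ddof=1) / mean)


def _checked_probs(p, name: str) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    s = p.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"{name} sums to {s}, not 1")
    if s != 1.0:
        logger.debug("renormalizing %s (sum %.9f)", name, s)
        p = p / s
    return p


def shannon_entropy(p) -> float:
    """Shannon entropy in bits, with the 0*log0 = 0 convention."""
    p = _checked_probs(p, "probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def joint_entropy(p_joint) -> float:
    """Entropy in bits of a joint probability matrix."""
    return shannon_entropy(np.asarray(p_joint, float).ravel())


@dataclass
class HeterogeneityPanel:
    """One sample's five-metric heterogeneity profile under one condition."""

    sample_id: str
    cv_nucleus_size: float
    cv_cell_size: float
    entropy_nucleus: float   # bits
    entropy_cell: float      # bits
    entropy_joint: float     # bits
    n_cells: int
    condition_tag: str = "all"
    available: bool = True

    @classmethod
    def unavailable(cls, sample_id: str, condition_tag: str, n_cells: int
                    ) -> "HeterogeneityPanel":
        return cls(sample_id=sample_id, cv_nucleus_size=np.nan,
                   cv_cell_size=np.nan, entropy_nucleus=np.nan,
                   entropy_cell=np.nan, entropy_joint=np.nan,
                   n_cells=n_cells, condition_tag=condition_tag,
                   available=False)


def heterogeneity_panel(records: pd.DataFrame, K_N: int, K_C: int,
                        condition: pd.Series | np.ndarray | None = None,
                        condition_tag: str = "all",
                        sample_id: str | None = None) -> HeterogeneityPanel:
    """Compute the five-metric panel on a (optionally filtered) cell table.

    ``records`` must carry R_N, R_C, nucleus_mode, cell_mode columns;
    ``condition`` is an optional boolean mask applied before computing.
    Fewer than two surviving cells yield an unavailable panel.
    """
    df = records if condition is None else records.loc[np.asarray(condition, bool)]
    if sample_id is None:
        ids = df["sample_id"].unique() if "sample_id" in df and len(df) else []
        sample_id = str(ids[0]) if len(ids) == 1 else "pooled"
    if len(df) < 2:
        return HeterogeneityPanel.unavailable(sample_id, condition_tag, len(df))
    dist = mode_distribution(df["nucleus_mode"], df["cell_mode"], K_N, K_C,
                             sample_id=sample_id)
    return HeterogeneityPanel(
        sample_id=sample_id,
        cv_nucleus_size=coefficient_of_variation(df["R_N"]),
        cv_cell_size=coefficient_of_variation(df["R_C"]),
        entropy_nucleus=shannon_entropy(dist.p_nucleus),
        entropy_cell=shannon_entropy(dist.p_cell),
        entropy_joint=joint_entropy(dist.p_joint),
        n_cells=len(df),
        condition_tag=condition_tag,
    )


def panels_to_frame(panels) -> pd.DataFrame:
    """Long-format panel table, one row per (sample, condition)."""
    return pd.DataFrame([{
        "sample_id": p.sample_id,
        "condition": p.condition_tag,
        "cv_nucleus_size": p.cv_nucleus_size,
        "cv_cell_size": p.cv_cell_size,
        "entropy_nucleus": p.entropy_nucleus,
        "entropy_cell": p.entropy_cell,
        "entropy_joint": p.entropy_joint,
        "n_cells": p.n_cells,
        "available": p.available,
    } for p in panels])
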