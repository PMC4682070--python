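"""Hierarchy of heterogeneity: clonal structure and heritable variation.

After sparse seeding and a few days of growth, cells form spatially
distinct colonies (clones).  This module quantifies how much of the
morphological variance is heritable:

* spatial colonies by single-linkage clustering of cell positions;
* paired (proximity) correlation of size features over cell pairs as a
  function of separation, against a label-permutation null band;
* variance decomposition: population variance of R_N and R_C under
  different conditions (singlet, crowded, G0/G1, G2/M, within-clone),
  scaled by the all-population variance;
* heritable variation as the CV of colony-mean sizes;
* the three-feature metastatic signature (CV of nucleus size among
  clustered cells, CV of cell size among singlets, nucleus-shape entropy
  among singlets) with subsampling leave-one-sample-out nearest-centroid
  cross-validation.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .heterogeneity import coefficient_of_variation, shannon_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "identify_colonies",
    "proximity_correlation",
    "variance_decomposition",
    "heritable_variation",
    "signature_features",
    "signature_and_classification",
]

UNASSIGNED = -1

FEATURES = ("R_N", "R_C")

CONDITIONS = ("all", "singlet", "crowded", "G0G1", "G2M",
              "clone_all", "clone_G0G1")


def identify_colonies(records: pd.DataFrame, linkage_distance: float,
                      min_size: int = 5) -> np.ndarray:
    """Single-linkage spatial clustering of cell positions into colonies.

    Cells in clusters smaller than ``min_size`` are left unassigned (-1).
    Returns the per-cell colony id array (also usable as a column).
    """
    if "x" not in records or "y" not in records:
        raise ValueError("records need x and y positions")
    pos = records[["x", "y"]].to_numpy(float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    if len(pos) == 1:
        return np.array([UNASSIGNED if min_size > 1 else 0])
    Z = linkage(pos, method="single")
    raw = fcluster(Z, t=linkage_distance, criterion="distance")
    ids = np.full(len(pos), UNASSIGNED)
    next_id = 0
    for lab in np.unique(raw):
        sel = raw == lab
        if sel.sum() >= min_size:
            ids[sel] = next_id
            next_id += 1
    return ids


def proximity_correlation(records: pd.DataFrame, feature: str,
                          distance_bins, n_permutations: int = 1000,
                          seed: int = 0, phase_filter: str | None = None):
    """Pearson correlation of a size feature over cell pairs, by separation.

    Every unordered pair whose separation falls in a bin contributes both
    orderings (symmetric duplication), making the estimator exchangeable.
    A permutation null (feature values shuffled across cells) provides a
    2.5–97.5 percentile band per bin.  Returns a DataFrame with one row
    per bin: correlation, the null band, and the pair count.
    """
    edges = np.asarray(distance_bins, float)
    if edges.size < 3:
        raise ValueError("need >= 2 distance bins")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    df = records
    if phase_filter is not None:
        df = df[df["phase"] == phase_filter]
    pos = df[["x", "y"]].to_numpy(float)
    vals = df[feature].to_numpy(float)
    n = len(df)
    if n < 3:
        raise ValueError("too few cells for pair correlation")
    d = pdist(pos)
    iu = np.triu_indices(n, k=1)
    bin_idx = np.digitize(d, edges) - 1  # bin b covers [edges[b], edges[b+1])
    n_bins = edges.size - 1

    def _bin_corrs(values: np.ndarray) -> np.ndarray:
        a = values[iu[0]]
        b = values[iu[1]]
        out = np.full(n_bins, np.nan)
        for k in range(n_bins):
            sel = bin_idx == k
            if sel.sum() < 2:
                continue
            x = np.concatenate([a[sel], b[sel]])
            y = np.concatenate([b[sel], a[sel]])
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            out[k] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        return out

    corr = _bin_corrs(vals)
    rng = np.random.default_rng(seed)
    null = np.full((n_permutations, n_bins), np.nan)
    for p in range(n_permutations):
        null[p] = _bin_corrs(rng.permutation(vals))
    lo = np.nanpercentile(null, 2.5, axis=0)
    hi = np.nanpercentile(null, 97.5, axis=0)
    counts = np.array([(bin_idx == k).sum() for k in range(n_bins)])
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:], "n_pairs": counts,
        "correlation": corr, "null_lo": lo, "null_hi": hi,
    })


def _subset_masks(records: pd.DataFrame):
    yield "all", np.ones(len(records), bool)
    if "density_category" in records:
        yield "singlet", (records["density_category"] == "singlet").to_numpy()
        yield "crowded", (records["density_category"] == "crowded").to_numpy()
    if "phase" in records:
        yield "G0G1", (records["phase"] == "G0G1").to_numpy()
        yield "G2M", (records["phase"] == "G2M").to_numpy()


def variance_decomposition(records: pd.DataFrame, min_size: int = 5,
                           colony_col: str = "colony_id") -> pd.DataFrame:
    """Size variance under each condition, scaled by the all-population variance.

    Within-clone entries average the within-colony variance over colonies
    with at least ``min_size`` cells (the mean clone variance <sigma_p^2>),
    for all cells and for G0/G1 cells only.  Returns a long DataFrame
    (feature, condition, scaled_variance, n); the 'all' entry is exactly 1.
    """
    rows = []
    for feature in FEATURES:
        v = records[feature].to_numpy(float)
        v_all = v.var(ddof=1)
        if v_all <= 0:
            raise ValueError(f"{feature}: zero all-population variance")
        for name, mask in _subset_masks(records):
            sub = v[mask]
            if sub.size < 2:
                rows.append({"feature": feature, "condition": name,
                             "scaled_variance": np.nan, "n": int(sub.size)})
                continue
            rows.append({"feature": feature, "condition": name,
                         "scaled_variance": float(sub.var(ddof=1) / v_all),
                         "n": int(sub.size)})
        for name, phase in (("clone_all", None), ("clone_G0G1", "G0G1")):
            df = records if phase is None else records[records["phase"] == phase]
            if colony_col not in df:
                rows.append({"feature": feature, "condition": name,
                             "scaled_variance": np.nan, "n": 0})
                continue
            per_colony = []
            n_used = 0
            for cid, g in df.groupby(colony_col):
                if cid == UNASSIGNED or len(g) < min_size:
                    continue
                per_colony.append(g[feature].var(ddof=1))
                n_used += len(g)
            if per_colony:
                rows.append({"feature": feature, "condition": name,
                             "scaled_variance": float(np.mean(per_colony) / v_all),
                             "n": n_used})
            else:
                rows.append({"feature": feature, "condition": name,
                             "scaled_variance": np.nan, "n": 0})
    return pd.DataFrame(rows)


def heritable_variation(records: pd.DataFrame, phase_filter: str | None = None,
                        min_size: int = 5, colony_col: str = "colony_id"
                        ) -> dict:
    """CV of colony-mean R_N and R_C: the heritable component of size variation.

    Requires at least three colonies with ``min_size`` cells (after the
    optional G0/G1 filter); returns {feature: CV} plus the colony count.
    """
    df = records
    if phase_filter is not None:
        df = df[df["phase"] == phase_filter]
    means = {f: [] for f in FEATURES}
    for cid, g in df.groupby(colony_col):
        if cid == UNASSIGNED or len(g) < min_size:
            continue
        for f in FEATURES:
            means[f].append(g[f].mean())
    n_colonies = len(means[FEATURES[0]])
    if n_colonies < 3:
        raise ValueError(
            f"need >= 3 colonies with >= {min_size} cells, found {n_colonies}")
    out = {f: coefficient_of_variation(means[f]) for f in FEATURES}
    out["n_colonies"] = n_colonies
    return out


def signature_features(records: pd.DataFrame, K_N: int) -> dict:
    """The three-feature metastatic signature of one sample.

    CV of nucleus size among clustered cells (rho_D > 0), CV of cell size
    among singlets, and nucleus shape-mode entropy among singlets.
    """
    clustered = records[records["rho_D"] > 0]
    singlet = records[records["rho_D"] == 0]
    counts = np.bincount(singlet["nucleus_mode"].to_numpy(int) - 1,
                         minlength=K_N) if len(singlet) else np.zeros(K_N)
    total = counts.sum()
    entropy = shannon_entropy(counts / total) if total > 0 else np.nan
    return {
        "cv_nucleus_size_clustered": (coefficient_of_variation(clustered["R_N"])
                                      if len(clustered) >= 2 else np.nan),
        "cv_cell_size_singlet": (coefficient_of_variation(singlet["R_C"])
                                 if len(singlet) >= 2 else np.nan),
        "entropy_nucleus_shape_singlet": entropy,
    }


_SIG_COLS = ["cv_nucleus_size_clustered", "cv_cell_size_singlet",
             "entropy_nucleus_shape_singlet"]


def _nearest_centroid_loo(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Leave-one-sample-out nearest-centroid prediction on z-scored features."""
    preds = {}
    for held in features.index:
        train = features.drop(index=held)
        train_labels = labels.drop(index=held)
        mu = train.mean()
        sd = train.std(ddof=1).replace(0, 1.0)
        z_train = (train - mu) / sd
        z_held = (features.loc[held] - mu) / sd
        centroids = z_train.groupby(train_labels).mean()
        dists = ((centroids - z_held) ** 2).sum(axis=1)
        preds[held] = dists.idxmin()
    return pd.Series(preds)


def signature_and_classification(records: pd.DataFrame, group_labels: dict,
                                 K_N: int, subsample_sizes=(50, 100, 200, 400),
                                 n_repeats: int = 20, seed: int = 0):
    """Signature vectors per sample and subsampling cross-validation accuracy.

    ``group_labels`` maps sample_id -> class (e.g. PT / LM).  For each
    repeat and subsample size, that many cells are drawn from each
    sample, the three signature features recomputed, and every sample
    classified by leave-one-sample-out nearest centroid on z-scored
    features.  Returns ``(signatures, accuracy_curve)``.
    """
    samples = sorted(records["sample_id"].unique())
    labels = pd.Series({s: group_labels[s] for s in samples})
    if labels.nunique() < 2:
        raise ValueError("classification needs at least two classes")
    if labels.value_counts().min() < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out")

    full_feats = pd.DataFrame({s: signature_features(
        records[records["sample_id"] == s], K_N) for s in samples}).T
    preds = _nearest_centroid_loo(full_feats[_SIG_COLS], labels)
    signatures = full_feats.copy()
    signatures["class_label"] = labels
    signatures["predicted_label"] = preds
    signatures.index.name = "sample_id"

    rng = np.random.default_rng(seed)
    by_sample = {s: records[records["sample_id"] == s] for s in samples}
    rows = []
    for size in subsample_sizes:
        accs = []
        for _rep in range(n_repeats):
            feats = {}
            for s in samples:
                g = by_sample[s]
                if size >= len(g):
                    sub = g
                else:
                    sub = g.iloc[rng.choice(len(g), size=size, replace=False)]
                feats[s] = signature_features(sub, K_N)
            fdf = pd.DataFrame(feats).T[_SIG_COLS]
            pred = _nearest_centroid_loo(fdf, labels)
            accs.append(float((pred == labels).mean()))
        rows.append({"subsample_size": int(size),
                     "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1))
                     if len(accs) > 1 else 0.0,
                     "n_repeats": n_repeats})
    return signatures, pd.DataFrame(rows)
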