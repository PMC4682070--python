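"""Cell-cycle and local-density context for each cell.

DNA-content gating (image cytometry): the integrated nuclear DNA
intensity of a population is normalized by the location of its G0/G1
peak (the dominant mode of a kernel-smoothed intensity histogram) so
G0/G1 cells sit at 1.0; cells are then gated into G0/G1, S and G2/M by
fold-of-G1 thresholds.  Local density: two cells are in contact when
their cell masks come within ``contact_gap`` pixels (dilation-overlap
test); the contact count rho_D classifies cells as singlet (rho_D = 0),
semi-crowded (0 < rho_D < 4) or crowded (rho_D >= 4).  Tiled scans are
stitched into global coordinates first so contacts across tile borders
are preserved.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import gaussian_kde, pearsonr

from .errors import GatingError, TileConflictError
from .heterogeneity import heterogeneity_panel

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_and_gate_dna",
    "gate_phases",
    "stitch_tiles",
    "build_contact_graph",
    "density_category",
    "covariate_trend_analysis",
    "conditioned_panels",
    "PHASE_CONDITIONS",
    "DENSITY_CONDITIONS",
]

PHASE_CONDITIONS = ("G0G1", "S", "G2M")
DENSITY_CONDITIONS = ("singlet", "semi", "crowded")


def gate_phases(norm: np.ndarray, g1_hi: float = 1.25, g2_lo: float = 1.75
                ) -> np.ndarray:
    """Phase labels from fold-of-G1 DNA content."""
    norm = np.asarray(norm, float)
    return np.where(norm <= g1_hi, "G0G1", np.where(norm >= g2_lo, "G2M", "S"))


def normalize_and_gate_dna(raw, g1_hi: float = 1.25, g2_lo: float = 1.75,
                           min_cells: int = 50):
    """Normalize raw DNA intensities by the G0/G1 peak and gate phases.

    The G0/G1 peak is located as the dominant mode of a Gaussian-kernel
    density estimate of the raw intensities; the whole distribution is
    divided by it, making the result invariant to detector gain.
    Returns ``(dna_content_norm, phases)``.
    """
    raw = np.asarray(raw, float)
    if raw.size == 0:
        raise GatingError("no cells to gate")
    if np.any(raw < 0):
        raise GatingError("negative DNA intensities")
    if raw.size < min_cells:
        logger.warning("gating %d cells (< %d): low confidence", raw.size,
                       min_cells)
    if raw.std() == 0:
        g1_peak = float(raw[0])
        if g1_peak <= 0:
            raise GatingError("constant zero intensities: no G0/G1 peak")
    else:
        try:
            kde = gaussian_kde(raw)
        except np.linalg.LinAlgError as e:  # pragma: no cover - singular data
            raise GatingError(f"density estimate failed: {e}") from e
        lo, hi = np.percentile(raw, [0.5, 99.5])
        grid = np.linspace(lo, hi, 512)
        dens = kde(grid)
        g1_peak = float(grid[np.argmax(dens)])
        if g1_peak <= 0:
            raise GatingError("no positive G0/G1 peak detected")
    norm = raw / g1_peak
    return norm, gate_phases(norm, g1_hi=g1_hi, g2_lo=g2_lo)


def stitch_tiles(tiles) -> np.ndarray:
    """Paste tile label masks into one global canvas.

    ``tiles`` is a sequence of ``(mask, (x_origin, y_origin))``; labels are
    assumed globally unique cell ids.  Two tiles claiming the same global
    pixel with different labels raise a conflict error; agreeing overlap
    is allowed.
    """
    if not tiles:
        return np.zeros((0, 0), np.int32)
    H = max(int(round(oy)) + m.shape[0] for m, (ox, oy) in tiles)
    W = max(int(round(ox)) + m.shape[1] for m, (ox, oy) in tiles)
    canvas = np.zeros((H, W), np.int32)
    for i, (m, (ox, oy)) in enumerate(tiles):
        ox, oy = int(round(ox)), int(round(oy))
        view = canvas[oy:oy + m.shape[0], ox:ox + m.shape[1]]
        clash = (view > 0) & (m > 0) & (view != m)
        if clash.any():
            raise TileConflictError(
                f"tile {i} overlaps a previous tile with conflicting labels")
        view[m > 0] = m[m > 0]
    return canvas


def build_contact_graph(cell_mask_or_tiles, contact_gap: int = 1):
    """Contact graph of a labeled scene (single mask or list of tiles).

    Two cells are in contact iff their masks come within ``contact_gap``
    pixels of each other.  Returns ``(graph, rho_D, category)`` where
    ``graph`` is an undirected :class:`networkx.Graph` on cell ids,
    ``rho_D`` maps id -> contact count, ``category`` maps id -> density
    class per the singlet / semi-crowded / crowded thresholds.
    """
    if isinstance(cell_mask_or_tiles, np.ndarray):
        mask = cell_mask_or_tiles
    else:
        mask = stitch_tiles(list(cell_mask_or_tiles))
    G = nx.Graph()
    labels = np.unique(mask)
    labels = labels[labels > 0]
    G.add_nodes_from(int(l) for l in labels)
    struct = ndi.generate_binary_structure(2, 2)
    objects = ndi.find_objects(mask)
    for lab in labels:
        sl = objects[int(lab) - 1]
        if sl is None:
            continue
        pad = contact_gap + 1
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, mask.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, mask.shape[1])
        crop = mask[r0:r1, c0:c1]
        sel = crop == lab
        dil = ndi.binary_dilation(sel, structure=struct, iterations=contact_gap)
        touching = np.unique(crop[dil & (crop != lab) & (crop > 0)])
        for other in touching:
            G.add_edge(int(lab), int(other))
    rho = {n: G.degree(n) for n in G.nodes}
    cat = {n: density_category(d) for n, d in rho.items()}
    return G, rho, cat


def density_category(rho_d: int) -> str:
    if rho_d == 0:
        return "singlet"
    return "semi" if rho_d < 4 else "crowded"


def covariate_trend_analysis(records: pd.DataFrame, covariate: str = "dna",
                             n_groups: int = 9):
    """Morphology trends along DNA content or local density.

    Cells are sorted by the covariate (ties broken by cell_id) and split
    into ``n_groups`` equal-size groups (remainder spread over the
    leading groups).  Returns ``(group_table, occurrence, correlations)``:

    * ``group_table``: per group, mean covariate and mean R_N / R_C,
      each size normalized by the lowest group mean;
    * ``occurrence``: P(mode | group) per compartment and mode;
    * ``correlations``: per mode, Pearson r between the group-mean
      covariate and the mode occurrence across groups.
    """
    col = {"dna": "dna_content_norm", "density": "rho_D"}.get(covariate)
    if col is None:
        raise ValueError("covariate must be 'dna' or 'density'")
    if len(records) < n_groups:
        raise ValueError("fewer cells than groups")
    df = records.sort_values([col, "cell_id"], kind="mergesort").reset_index(drop=True)
    groups = np.array_split(np.arange(len(df)), n_groups)

    rows, occ_rows = [], []
    for gi, idx in enumerate(groups):
        g = df.iloc[idx]
        rows.append({"group": gi + 1, "n": len(g),
                     "mean_covariate": g[col].mean(),
                     "mean_R_N": g["R_N"].mean(),
                     "mean_R_C": g["R_C"].mean()})
        for compartment, mcol in (("nucleus", "nucleus_mode"),
                                  ("cell", "cell_mode")):
            counts = g[mcol].value_counts(normalize=True)
            for mode, p in counts.items():
                occ_rows.append({"group": gi + 1, "compartment": compartment,
                                 "mode": int(mode), "probability": p})
    group_table = pd.DataFrame(rows)
    group_table["norm_R_N"] = group_table["mean_R_N"] / group_table["mean_R_N"].min()
    group_table["norm_R_C"] = group_table["mean_R_C"] / group_table["mean_R_C"].min()
    occurrence = (pd.DataFrame(occ_rows)
                  .pivot_table(index=["compartment", "mode"], columns="group",
                               values="probability", fill_value=0.0))
    occurrence = occurrence.reindex(columns=range(1, n_groups + 1), fill_value=0.0)

    corr_rows = []
    x = group_table["mean_covariate"].to_numpy()
    constant = np.ptp(x) == 0
    for (compartment, mode), row in occurrence.iterrows():
        y = row.to_numpy(float)
        if constant or np.ptp(y) == 0:
            r = np.nan
        else:
            r = pearsonr(x, y).statistic
        corr_rows.append({"compartment": compartment, "mode": int(mode),
                          "covariate": covariate, "pearson_r": r})
    correlations = pd.DataFrame(corr_rows)
    return group_table, occurrence, correlations


def conditioned_panels(records: pd.DataFrame, K_N: int, K_C: int,
                       phase_col: str = "phase",
                       density_col: str = "density_category") -> pd.DataFrame:
    """Heterogeneity panels per sample under every phase/density condition.

    Returns a long table with one row per (sample, condition), conditions
    being 'all', the three cell-cycle phases and the three density
    classes; conditions with fewer than two cells are marked unavailable.
    """
    from .heterogeneity import panels_to_frame

    panels = []
    for sample_id, g in records.groupby("sample_id"):
        panels.append(heterogeneity_panel(g, K_N, K_C, condition_tag="all",
                                          sample_id=str(sample_id)))
        for phase in PHASE_CONDITIONS:
            panels.append(heterogeneity_panel(
                g, K_N, K_C, condition=(g[phase_col] == phase).to_numpy(),
                condition_tag=f"phase:{phase}", sample_id=str(sample_id)))
        for cat in DENSITY_CONDITIONS:
            panels.append(heterogeneity_panel(
                g, K_N, K_C, condition=(g[density_col] == cat).to_numpy(),
                condition_tag=f"density:{cat}", sample_id=str(sample_id)))
    return panels_to_frame(panels)
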