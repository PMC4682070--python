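"""Synthetic scene generation with known ground truth.

Every downstream stage of the pipeline (segmentation, registration,
eigenshapes, shape modes, heterogeneity and heritability analyses) is
exercised against populations generated here, where the latent shape
subtype, cell-cycle phase, DNA content, colony membership and cell-cell
contacts of every cell are known exactly.

The shape family is a radial Fourier series (star-convex outlines):
r(theta) = base_scale * (1 + sum_h [a_h cos(h theta) + b_h sin(h theta)]),
which guarantees simple closed curves and produces visually distinct
morphological subtypes.  Study conditions emulated by the defaults:

* cell-cycle mixture: 60% G0/G1 (DNA content 1.0), 25% S (uniform in
  (1, 2)), 15% G2/M (2.0), with multiplicative lognormal measurement
  noise (CV 5%) on the rendered intensity;
* cell and nucleus size coupled to the cube root of DNA content (volume
  doubles over the cycle, linear size scales as its cube root);
* spatially distinct colonies (clones) with a per-colony multiplicative
  size factor — the heritable component of size variation;
* a configurable fraction of cells placed in contact so masks touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CapacityError, RenderError
from .traces import BoundaryTrace

__all__ = [
    "ShapeTemplate",
    "generate_templates",
    "sample_population",
    "layout_scene",
    "render_scene",
    "rosette_scene",
    "simulate_sample",
    "synthesize_cell_table",
    "SceneData",
]

TRUTH_COLUMNS = ["cell_id", "template_id", "phase", "dna_content",
                 "colony_id", "contact_count", "x", "y"]

#: default cell-cycle phase mixture (G0/G1, S, G2/M)
PHASE_PROBS = (0.60, 0.25, 0.15)
PHASES = ("G0G1", "S", "G2M")


@dataclass
class ShapeTemplate:
    """A latent morphological subtype: radial Fourier outline coefficients.

    ``control_radii[0]`` is the constant (unit circle) term; subsequent
    entries are interleaved cosine/sine coefficients for harmonics 2..H
    (harmonic 1 is omitted to keep the outline centered).
    """

    template_id: int
    control_radii: np.ndarray
    base_scale: float = 1.0
    _harmonics: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        cr = np.asarray(self.control_radii, dtype=float)
        if not np.all(np.isfinite(cr)) or cr[0] <= 0:
            raise ValueError("control_radii must be finite with positive constant term")
        self.control_radii = cr
        n_coef = (cr.size - 1) // 2
        self._harmonics = np.arange(2, 2 + n_coef)

    def radius(self, theta: np.ndarray,
               extra_coeffs: np.ndarray | None = None) -> np.ndarray:
        """Radial profile r(theta); optionally perturbed coefficients added."""
        theta = np.asarray(theta, dtype=float)
        coeffs = self.control_radii[1:].copy()
        if extra_coeffs is not None:
            coeffs = coeffs + extra_coeffs
        h = self._harmonics
        ac = coeffs[0::2]
        bs = coeffs[1::2]
        mod = (ac[None, :] * np.cos(np.outer(theta, h))
               + bs[None, :] * np.sin(np.outer(theta, h))).sum(axis=1)
        r = self.base_scale * (self.control_radii[0] + mod)
        # star-convexity guard: keep the radius strictly positive
        return np.maximum(r, 0.05 * self.base_scale * self.control_radii[0])

    def outline(self, scale: float = 1.0, n_vertices: int = 100,
                extra_coeffs: np.ndarray | None = None) -> np.ndarray:
        theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
        r = scale * self.radius(theta, extra_coeffs)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _draw_template(rng, i, irregularity, n_harmonics, base_scale):
    h = np.arange(2, 2 + n_harmonics)
    ac = rng.normal(0.0, 1.0, n_harmonics) * irregularity / h
    bs = rng.normal(0.0, 1.0, n_harmonics) * irregularity / h
    if irregularity > 0:
        # adherent cells have a clear major axis and front-rear asymmetry.
        # Build each template in canonical pose: the elongation (cos 2theta)
        # lies along x and dominates the higher harmonics, and the cos 3theta
        # amplitude has a guaranteed magnitude bounded by the elongation, so
        # the registration frame (major-axis alignment + skewness flip) is
        # well defined and stable under per-cell shape noise.  Diversity
        # between templates comes from the elongation strength, the tri-lobe
        # cos/sin 3theta amplitudes and the damped higher harmonics.
        ac[0] = 0.6 * irregularity + abs(rng.normal(0.0, irregularity))
        bs[0] = 0.0
        if n_harmonics >= 2:
            a3 = np.sign(ac[1] or 1.0) * (0.35 * irregularity + abs(ac[1]) * 1.5)
            ac[1] = np.clip(a3, -0.75 * ac[0], 0.75 * ac[0])
            # the sin 3theta lobe rotates into the skew term under axis
            # jitter; keep it subordinate to the cos 3theta amplitude
            b3 = rng.normal(0.0, irregularity / 3)
            bs[1] = np.clip(b3, -0.8 * abs(ac[1]), 0.8 * abs(ac[1]))
        ac[2:] /= h[2:]
        bs[2:] /= h[2:]
    # keep the outline comfortably star-convex
    worst = np.sum(np.abs(np.concatenate([ac, bs])))
    if worst > 0.7:
        ac *= 0.7 / worst
        bs *= 0.7 / worst
    coeffs = np.empty(2 * n_harmonics)
    coeffs[0::2] = ac
    coeffs[1::2] = bs
    return ShapeTemplate(template_id=i,
                         control_radii=np.concatenate([[1.0], coeffs]),
                         base_scale=base_scale)


def generate_templates(k: int, irregularity: float = 0.3, seed: int = 0,
                       n_harmonics: int = 5, base_scale: float = 1.0,
                       min_separation: float | None = None
                       ) -> list[ShapeTemplate]:
    """Draw ``k`` distinct latent shape templates.

    Harmonic coefficients are drawn from N(0, (irregularity / h)^2) for
    harmonics h = 2..(1 + n_harmonics) (damped 1/h^2 above h = 3);
    ``irregularity = 0`` yields circles.  Candidate templates whose
    registered feature distance to an already accepted template falls
    below ``min_separation`` (default ``4.5 * irregularity``) are
    redrawn, so the k subtypes are genuinely distinct morphologies.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if irregularity < 0:
        raise ValueError("irregularity must be nonnegative")
    if min_separation is None:
        min_separation = 4.5 * irregularity
    rng = np.random.default_rng(seed)
    templates: list[ShapeTemplate] = []
    accepted_feats = []
    if min_separation > 0 and irregularity > 0:
        from .register import register_shape
        from .traces import BoundaryTrace as _BT

        def _feat(t):
            return register_shape(
                _BT(vertices=t.outline(scale=20.0))).feature_vector
    else:
        _feat = None
    for i in range(k):
        best, best_d = None, -np.inf
        for _attempt in range(200):
            cand = _draw_template(rng, i, irregularity, n_harmonics, base_scale)
            if _feat is None or not templates:
                best = cand
                break
            f = _feat(cand)
            d = min(float(np.linalg.norm(f - g)) for g in accepted_feats)
            if d >= min_separation:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        if _feat is not None:
            accepted_feats.append(_feat(best))
        templates.append(best)
    return templates


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in TRUTH_COLUMNS})


def sample_population(templates, weights, n: int, shape_noise: float = 0.05,
                      seed: int = 0, mean_radius: float = 18.0,
                      size_cv: float = 0.08,
                      phase_probs=PHASE_PROBS, sample_id: str = "S1",
                      n_vertices: int = 100):
    """Draw ``n`` cell outlines from a template mixture with known truth.

    Returns ``(boundaries, truth)``: a list of cell-compartment
    :class:`BoundaryTrace` centered at the origin (positions are assigned
    by :func:`layout_scene`), and a truth table with one row per cell
    (template, phase, DNA content as fold-of-G1, placeholder position).

    ``shape_noise`` perturbs the per-harmonic Fourier coefficients
    (scaled 1/h, like the template draw); 0 reproduces each template
    exactly up to the similarity transform of size sampling.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if len(weights) != len(templates):
        raise ValueError("one weight per template required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)

    template_ids = rng.choice(len(templates), size=n, p=weights)
    phase_idx = rng.choice(3, size=n, p=np.asarray(phase_probs, float))
    dna = np.ones(n)
    dna[phase_idx == 1] = rng.uniform(1.0, 2.0, int((phase_idx == 1).sum()))
    dna[phase_idx == 2] = 2.0
    size_noise = rng.lognormal(0.0, size_cv, n) if size_cv > 0 else np.ones(n)

    boundaries = []
    rows = []
    for i in range(n):
        t = templates[template_ids[i]]
        n_coef = t.control_radii.size - 1
        extra = None
        if shape_noise > 0:
            h = np.repeat(np.arange(2, 2 + n_coef // 2), 2)
            extra = rng.normal(0.0, 1.0, n_coef) * shape_noise / h
        scale = mean_radius / t.base_scale * dna[i] ** (1.0 / 3.0) * size_noise[i]
        verts = t.outline(scale=scale, n_vertices=n_vertices, extra_coeffs=extra)
        boundaries.append(BoundaryTrace(
            vertices=verts, compartment="cell", cell_id=i, sample_id=sample_id))
        rows.append((i, int(template_ids[i]), PHASES[phase_idx[i]], float(dna[i]),
                     -1, 0, np.nan, np.nan))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["sample_id"] = sample_id
    return boundaries, truth


def _max_radius(trace: BoundaryTrace) -> float:
    return float(np.linalg.norm(trace.vertices, axis=1).max())


def _radius_along(trace: BoundaryTrace, phi: float) -> float:
    """Approximate boundary radius along direction ``phi`` (origin-centered)."""
    v = trace.vertices
    ang = np.arctan2(v[:, 1], v[:, 0])
    d = np.abs((ang - phi + np.pi) % (2 * np.pi) - np.pi)
    return float(np.linalg.norm(v[np.argmin(d)]))


def layout_scene(truth: pd.DataFrame, boundaries, image_shape=(1024, 1024),
                 n_colonies: int = 1, colony_spread: float = 80.0,
                 contact_fraction: float = 0.0, seed: int = 0,
                 colony_size_cv: float = 0.0, margin: float = 4.0,
                 max_tries: int = 2000):
    """Assign positions, colonies, and designed contacts to a population.

    Colony members are scattered around well separated colony centers; a
    ``contact_fraction`` of cells is placed against an already placed
    partner so that their masks touch (about one pixel of overlap along
    the connecting direction).  A per-colony lognormal size factor with
    coefficient of variation ``colony_size_cv`` models heritable size
    variation; boundaries are rescaled in place accordingly.

    Returns ``(truth, boundaries)`` with positions applied to the truth
    table; boundaries stay origin-centered (positions are applied at
    render time).
    """
    if min(n_colonies, 1) < 0 or colony_spread < 0 or contact_fraction < 0:
        raise ValueError("layout parameters must be nonnegative")
    n = len(truth)
    rng = np.random.default_rng(seed)
    H, W = image_shape
    radii = np.array([_max_radius(b) for b in boundaries])
    if n > 0 and (2 * radii.max() + 2 * margin > min(H, W)
                  or np.sum(np.pi * (radii + margin) ** 2) > 0.6 * H * W):
        raise CapacityError(
            f"image {image_shape} cannot hold {n} cells of max radius {radii.max():.1f}")

    # colony centers by rejection sampling, well separated; the required
    # separation is relaxed geometrically if the field is too tight
    centers = []
    rmax = radii.max() if n else 0.0
    pad = min(min(H, W) / 3.0, 1.5 * colony_spread + rmax + margin)
    sep = 3.0 * colony_spread + 2 * rmax
    for _ in range(n_colonies):
        placed_center = False
        while not placed_center:
            for _try in range(200):
                c = np.array([rng.uniform(pad, W - pad),
                              rng.uniform(pad, H - pad)])
                if all(np.linalg.norm(c - o) > sep for o in centers):
                    centers.append(c)
                    placed_center = True
                    break
            else:
                sep *= 0.7
                if sep < 2 * rmax + 2 * margin:
                    raise CapacityError(
                        "could not place well-separated colony centers")

    colony_of = rng.integers(0, n_colonies, n) if n_colonies > 0 else np.zeros(n, int)
    colony_factor = (rng.lognormal(0.0, colony_size_cv, n_colonies)
                     if colony_size_cv > 0 else np.ones(n_colonies))

    n_contact = int(round(contact_fraction * n))
    contact_flag = np.zeros(n, bool)
    if n_contact > 0:
        contact_flag[rng.choice(n, size=n_contact, replace=False)] = True

    scaled = []
    for i, b in enumerate(boundaries):
        f = colony_factor[colony_of[i]]
        scaled.append(BoundaryTrace(
            vertices=b.vertices * f, compartment=b.compartment,
            cell_id=b.cell_id, sample_id=b.sample_id, image_id=b.image_id))
    radii = radii * colony_factor[colony_of]

    pos = np.full((n, 2), np.nan)
    placed: list[int] = []
    contacts: list[tuple[int, int]] = []
    # non-contact cells are placed first so contact cells have anchors
    order = np.concatenate([np.where(~contact_flag)[0], np.where(contact_flag)[0]])
    for i in order:
        ci = colony_of[i]
        partner_pool = [j for j in placed if colony_of[j] == ci]
        want_contact = contact_flag[i] and partner_pool
        ok = False
        for _try in range(max_tries):
            if want_contact:
                j = partner_pool[rng.integers(len(partner_pool))]
                phi = rng.uniform(0, 2 * np.pi)
                d = (_radius_along(scaled[j], phi)
                     + _radius_along(scaled[i], phi + np.pi) - 1.0)
                p = pos[j] + d * np.array([np.cos(phi), np.sin(phi)])
                clearance_with = {j}
            else:
                p = centers[ci] + rng.normal(0.0, max(colony_spread, 1e-6), 2)
                clearance_with = set()
            if not (margin + radii[i] <= p[0] <= W - margin - radii[i]
                    and margin + radii[i] <= p[1] <= H - margin - radii[i]):
                continue
            clear = True
            for k in placed:
                if k in clearance_with:
                    continue
                if np.linalg.norm(p - pos[k]) < radii[i] + radii[k] + 3.0:
                    clear = False
                    break
            if clear:
                pos[i] = p
                if want_contact:
                    contacts.append((i, j))
                placed.append(i)
                ok = True
                break
        if not ok:
            raise CapacityError(f"could not place cell {i} without unintended overlap")

    truth = truth.copy()
    truth["x"] = pos[:, 0]
    truth["y"] = pos[:, 1]
    truth["colony_id"] = colony_of
    truth["colony_size_factor"] = colony_factor[colony_of]
    deg = np.zeros(n, int)
    for a, b_ in contacts:
        deg[a] += 1
        deg[b_] += 1
    truth["contact_count"] = deg
    return truth, scaled


def _rasterize(mask: np.ndarray, verts: np.ndarray, label: int):
    from skimage.draw import polygon
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape=mask.shape)
    mask[rr, cc] = label


def render_scene(truth: pd.DataFrame, cell_boundaries, nucleus_boundaries=None,
                 image_shape=(1024, 1024), dna_gain: float = 1000.0,
                 snr: float = 20.0, actin_level: float = 100.0,
                 seed: int = 0):
    """Render DNA and F-actin channels plus ground-truth label masks.

    Boundaries are origin-centered and are translated to the positions in
    ``truth``.  Before noise, the integrated DNA-channel intensity inside
    each nucleus mask is exactly ``dna_gain * dna_content``; Gaussian read
    noise with standard deviation (foreground level / snr) is then added.
    Returns a dict with noisy and noiseless channels and label masks
    (0 = background, labels = cell_id + 1).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    H, W = image_shape
    n = len(truth)
    if nucleus_boundaries is None:
        nucleus_boundaries = []
    cell_mask = np.zeros((H, W), dtype=np.int32)
    nucleus_mask = np.zeros((H, W), dtype=np.int32)
    placed_nuc = {}
    xs = truth["x"].to_numpy(float)
    ys = truth["y"].to_numpy(float)
    ids = truth["cell_id"].to_numpy(int)
    by_id = {int(c): k for k, c in enumerate(ids)}

    for b in cell_boundaries:
        k = by_id[b.cell_id]
        verts = b.vertices + np.array([xs[k], ys[k]])
        if (verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5
                or verts[:, 0].max() > W - 0.5 or verts[:, 1].max() > H - 0.5):
            raise RenderError(f"cell {b.cell_id} boundary falls outside the image")
        _rasterize(cell_mask, verts, b.cell_id + 1)
    for b in nucleus_boundaries:
        k = by_id[b.cell_id]
        verts = b.vertices + np.array([xs[k], ys[k]])
        if (verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5
                or verts[:, 0].max() > W - 0.5 or verts[:, 1].max() > H - 0.5):
            raise RenderError(f"nucleus {b.cell_id} boundary falls outside the image")
        _rasterize(nucleus_mask, verts, b.cell_id + 1)
        placed_nuc[b.cell_id] = True

    dna = np.zeros((H, W), dtype=float)
    dna_content = truth.set_index("cell_id")["dna_content"] if n else None
    for cid in placed_nuc:
        sel = nucleus_mask == cid + 1
        npix = int(sel.sum())
        if npix > 0:
            dna[sel] += dna_gain * float(dna_content.loc[cid]) / npix
    actin = np.where(cell_mask > 0, actin_level, 0.0)

    rng = np.random.default_rng(seed)
    fg_dna = dna[dna > 0].mean() if np.any(dna > 0) else 1.0
    noisy_dna = np.clip(dna + rng.normal(0.0, fg_dna / snr, dna.shape), 0, None)
    noisy_actin = np.clip(actin + rng.normal(0.0, actin_level / snr, actin.shape),
                          0, None)
    return {
        "dna": noisy_dna, "actin": noisy_actin,
        "dna_noiseless": dna, "actin_noiseless": actin,
        "nucleus_mask": nucleus_mask, "cell_mask": cell_mask,
    }


def rosette_scene(radius_px: float = 16.0, image_shape=(160, 160)):
    """Seven-cell hexagonal rosette: a center cell touching six petals.

    Petals also touch their two hexagonal neighbors, so the ground-truth
    contact degrees are 6 (center, crowded) and 3 (petals, semi-crowded).
    Returns ``(truth, cell_boundaries)`` ready for :func:`render_scene`.
    """
    H, W = image_shape
    c0 = np.array([W / 2.0, H / 2.0])
    d = 2 * radius_px - 1.0  # one-pixel overlap => masks touch
    theta = 2 * np.pi * np.arange(64) / 64
    circle = radius_px * np.column_stack([np.cos(theta), np.sin(theta)])
    rows = []
    boundaries = []
    positions = [c0] + [c0 + d * np.array([np.cos(a), np.sin(a)])
                        for a in np.pi / 3 * np.arange(6)]
    degrees = [6, 3, 3, 3, 3, 3, 3]
    for i, (p, deg) in enumerate(zip(positions, degrees)):
        boundaries.append(BoundaryTrace(vertices=circle.copy(), compartment="cell",
                                        cell_id=i, sample_id="rosette"))
        rows.append((i, 0, "G0G1", 1.0, 0, deg, p[0], p[1]))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["sample_id"] = "rosette"
    return truth, boundaries


@dataclass
class SceneData:
    """One fully simulated sample: truth, boundaries, rendered channels."""

    truth: pd.DataFrame
    cell_boundaries: list
    nucleus_boundaries: list
    images: dict


def simulate_sample(n_cells: int = 60, k_templates: int = 3, seed: int = 0,
                    image_shape=(1024, 1024), irregularity: float = 0.3,
                    shape_noise: float = 0.05, mean_radius: float = 18.0,
                    nucleus_fraction: float = 0.45, n_colonies: int = 3,
                    colony_spread: float = 80.0, contact_fraction: float = 0.2,
                    colony_size_cv: float = 0.0, snr: float = 20.0,
                    dna_gain: float = 1000.0, weights=None,
                    sample_id: str = "S1") -> SceneData:
    """End-to-end scene simulation: templates -> population -> layout -> render.

    Nuclei reuse the cell's template at ``nucleus_fraction`` of its linear
    size with lighter shape noise, so nuclear and cellular subtypes are
    coupled as they are in real cells.
    """
    templates = generate_templates(k_templates, irregularity=irregularity,
                                   seed=seed)
    if weights is None:
        weights = np.full(k_templates, 1.0 / k_templates)
    cells, truth = sample_population(
        templates, weights, n_cells, shape_noise=shape_noise,
        seed=seed + 1, mean_radius=mean_radius, sample_id=sample_id)
    truth, cells = layout_scene(
        truth, cells, image_shape=image_shape, n_colonies=n_colonies,
        colony_spread=colony_spread, contact_fraction=contact_fraction,
        seed=seed + 2, colony_size_cv=colony_size_cv)
    nuclei = []
    nuc_rng = np.random.default_rng(seed + 3)
    for b, (_, row) in zip(cells, truth.iterrows()):
        jitter = 1.0 + nuc_rng.normal(0.0, 0.02)
        nuclei.append(BoundaryTrace(
            vertices=b.vertices * nucleus_fraction * jitter,
            compartment="nucleus", cell_id=b.cell_id, sample_id=b.sample_id))
    images = render_scene(truth, cells, nuclei, image_shape=image_shape,
                          dna_gain=dna_gain, snr=snr, seed=seed + 4)
    return SceneData(truth=truth, cell_boundaries=cells,
                     nucleus_boundaries=nuclei, images=images)


def synthesize_cell_table(n_cells: int, seed: int = 0, sample_id: str = "S1",
                          K_N: int = 5, K_C: int = 5,
                          nucleus_mode_probs=None, cell_mode_probs=None,
                          mean_RN: float = 8.0, mean_RC: float = 18.0,
                          size_cv: float = 0.10, n_colonies: int = 5,
                          colony_size_cv: float = 0.0,
                          colony_spread: float = 60.0,
                          field_size: float = 2048.0,
                          phase_probs=PHASE_PROBS,
                          dna_noise_cv: float = 0.05,
                          dna_gain: float = 1000.0,
                          rho_probs=(0.45, 0.2, 0.1, 0.1, 0.05, 0.05, 0.05),
                          phase_size_coupling: bool = True) -> pd.DataFrame:
    """Generate a feature-level cell table with known composition.

    Emulates the per-cell phenotype rows produced by the full imaging
    pipeline (sizes, shape-mode labels, DNA content, contact counts,
    colony structure) directly at the feature level — the fast path for
    studying the heterogeneity and heritability statistics at large n
    without rendering images.

    Size model: R = mean * DNA^(1/3) * colony_factor * lognormal(size_cv);
    DNA raw intensity = gain * true_DNA * lognormal(dna_noise_cv).
    """
    rng = np.random.default_rng(seed)
    if nucleus_mode_probs is None:
        nucleus_mode_probs = np.full(K_N, 1.0 / K_N)
    if cell_mode_probs is None:
        cell_mode_probs = np.full(K_C, 1.0 / K_C)
    nucleus_mode_probs = np.asarray(nucleus_mode_probs, float)
    cell_mode_probs = np.asarray(cell_mode_probs, float)

    phase_idx = rng.choice(3, size=n_cells, p=np.asarray(phase_probs, float))
    dna = np.ones(n_cells)
    dna[phase_idx == 1] = rng.uniform(1.0, 2.0, int((phase_idx == 1).sum()))
    dna[phase_idx == 2] = 2.0
    dna_raw = dna_gain * dna * rng.lognormal(0.0, dna_noise_cv, n_cells)

    colony = rng.integers(0, n_colonies, n_cells)
    colony_factor = (rng.lognormal(0.0, colony_size_cv, n_colonies)
                     if colony_size_cv > 0 else np.ones(n_colonies))
    centers = rng.uniform(4 * colony_spread, field_size - 4 * colony_spread,
                          (n_colonies, 2))
    pos = centers[colony] + rng.normal(0.0, colony_spread, (n_cells, 2))

    growth = dna ** (1.0 / 3.0) if phase_size_coupling else np.ones(n_cells)
    R_N = mean_RN * growth * colony_factor[colony] * rng.lognormal(0, size_cv, n_cells)
    R_C = mean_RC * growth * colony_factor[colony] * rng.lognormal(0, size_cv, n_cells)

    rho = rng.choice(len(rho_probs), size=n_cells, p=np.asarray(rho_probs, float))
    cat = np.where(rho == 0, "singlet", np.where(rho < 4, "semi", "crowded"))

    df = pd.DataFrame({
        "sample_id": sample_id,
        "image_id": "synthetic",
        "cell_id": np.arange(n_cells),
        "R_N": R_N,
        "R_C": R_C,
        "nucleus_mode": rng.choice(K_N, size=n_cells, p=nucleus_mode_probs) + 1,
        "cell_mode": rng.choice(K_C, size=n_cells, p=cell_mode_probs) + 1,
        "dna_content_raw": dna_raw,
        "dna_content_true": dna,
        "phase_true": np.array(PHASES)[phase_idx],
        "rho_D": rho,
        "density_category": cat,
        "x": pos[:, 0],
        "y": pos[:, 1],
        "colony_id": colony,
        "shape_factor": np.clip(rng.normal(0.7, 0.1, n_cells), 0.05, 1.0),
        "aspect_ratio": 1.0 + np.abs(rng.normal(0.5, 0.3, n_cells)),
        "on_tile_border": False,
    })
    return df
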