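"""Image processing: segmentation, boundary extraction, intensity, z-stacks.

Segmentation recipe (configuration-isolated so an alternative segmenter
can be swapped in): nuclei from the smoothed DNA channel by Otsu
threshold, hole filling, small-object removal and a distance-transform
watershed to split touching nuclei; cells from the F-actin channel by a
watershed seeded at the nuclei and restricted to the actin foreground.
Nucleus-inside-cell is enforced, and nucleus/cell labels share ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

from .traces import BoundaryTrace, ensure_ccw

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "LabeledScene",
    "segment_scene",
    "extract_boundaries",
    "measure_dna_content",
    "project_zstack",
    "read_tile_manifest",
]


@dataclass
class SegmentationParams:
    """Tunable knobs of the stated segmentation recipe."""

    smooth_sigma: float = 2.0       # px, Gaussian smoothing before thresholding
    min_area: int = 40              # px^2, objects smaller than this are removed
    split_touching: bool = True     # distance-transform watershed on nuclei
    peak_min_distance: int = 12     # px, minimum separation of watershed seeds;
                                    # should exceed the typical nucleus radius
    threshold_method: str = "otsu"  # nucleus/cell foreground threshold


@dataclass
class LabeledScene:
    """Label masks plus the channel images they were derived from."""

    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    dna_image: np.ndarray
    actin_image: np.ndarray
    pixel_size: float = 1.0           # microns per pixel
    origin: tuple = (0.0, 0.0)        # (x, y) global offset of this tile
    image_id: str = ""
    sample_id: str = ""

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.cell_mask)
        return lab[lab > 0]


def _foreground(image: np.ndarray, sigma: float, method: str) -> np.ndarray:
    sm = filters.gaussian(image.astype(float), sigma=sigma, preserve_range=True)
    if np.ptp(sm) <= 1e-12:
        return np.zeros(image.shape, bool), sm
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    return (sm > filters.threshold_otsu(sm)), sm


def segment_scene(dna_image: np.ndarray, actin_image: np.ndarray,
                  params: SegmentationParams | None = None) -> LabeledScene:
    """Segment nuclei (DNA channel) and cells (actin channel) of one tile."""
    dna_image = np.asarray(dna_image, float)
    actin_image = np.asarray(actin_image, float)
    if dna_image.shape != actin_image.shape:
        raise ValueError("DNA and actin images must have the same shape")
    params = params or SegmentationParams()

    nuc_fg, _ = _foreground(dna_image, params.smooth_sigma, params.threshold_method)
    nuc_fg = ndi.binary_fill_holes(nuc_fg)
    if params.min_area > 0:
        # drop objects with fewer than min_area pixels
        nuc_fg = morphology.remove_small_objects(nuc_fg,
                                                 max_size=params.min_area - 1)

    if not nuc_fg.any():
        z = np.zeros(dna_image.shape, np.int32)
        return LabeledScene(z, z.copy(), dna_image, actin_image)

    if params.split_touching:
        dist = ndi.distance_transform_edt(nuc_fg)
        # smooth the distance map so lobes of one irregular nucleus do not
        # seed separate watershed basins
        dist_s = ndi.gaussian_filter(dist, 2.0)
        peaks = feature.peak_local_max(
            dist_s, min_distance=params.peak_min_distance, labels=nuc_fg,
            exclude_border=False)
        markers = np.zeros(dna_image.shape, np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            nucleus_mask = measure.label(nuc_fg).astype(np.int32)
        else:
            nucleus_mask = segmentation.watershed(-dist_s, markers, mask=nuc_fg)
    else:
        nucleus_mask = measure.label(nuc_fg).astype(np.int32)

    cell_fg, actin_sm = _foreground(actin_image, params.smooth_sigma,
                                    params.threshold_method)
    cell_fg = ndi.binary_fill_holes(cell_fg) | (nucleus_mask > 0)
    cell_mask = segmentation.watershed(-actin_sm, nucleus_mask, mask=cell_fg)

    # nucleus inside its cell, matched labels
    cell_mask = np.where(nucleus_mask > 0, nucleus_mask, cell_mask)

    # drop undersized objects consistently in both compartments
    keep = []
    for lab in np.unique(nucleus_mask):
        if lab == 0:
            continue
        if (nucleus_mask == lab).sum() >= params.min_area:
            keep.append(lab)
        else:
            logger.warning("dropping object %d below minimum area", lab)
    relabel = np.zeros(int(nucleus_mask.max()) + 1, np.int32)
    for new, lab in enumerate(sorted(keep), start=1):
        relabel[lab] = new
    nucleus_mask = relabel[nucleus_mask]
    cell_mask = relabel[cell_mask]
    return LabeledScene(nucleus_mask.astype(np.int32), cell_mask.astype(np.int32),
                        dna_image, actin_image)


def _contour_of_label(mask: np.ndarray, lab: int, pad: int = 2):
    """Sub-pixel outer contour of one label, in (x, y) = (col, row) coords."""
    sel = mask == lab
    rows = np.any(sel, axis=1)
    cols = np.any(sel, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    crop = np.pad(sel[r0:r1 + 1, c0:c1 + 1], pad).astype(float)
    contours = measure.find_contours(crop, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer contour; holes ignored
    y = contour[:, 0] + r0 - pad
    x = contour[:, 1] + c0 - pad
    verts = np.column_stack([x, y])
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    return verts


def extract_boundaries(scene: LabeledScene, compartments=("nucleus", "cell")
                       ) -> list[BoundaryTrace]:
    """One counterclockwise boundary trace per label per compartment."""
    traces = []
    masks = {"nucleus": scene.nucleus_mask, "cell": scene.cell_mask}
    H, W = scene.cell_mask.shape
    ox, oy = scene.origin
    for compartment in compartments:
        mask = masks[compartment]
        for lab in np.unique(mask):
            if lab == 0:
                continue
            verts = _contour_of_label(mask, int(lab))
            if verts is None or verts.shape[0] < 3:
                logger.warning("label %d (%s): contour with < 3 points, dropped",
                               lab, compartment)
                continue
            verts = ensure_ccw(verts)
            sel = mask == lab
            on_border = bool(sel[0, :].any() or sel[-1, :].any()
                             or sel[:, 0].any() or sel[:, -1].any())
            traces.append(BoundaryTrace(
                vertices=verts + np.array([ox, oy]),
                compartment=compartment, cell_id=int(lab),
                sample_id=scene.sample_id, image_id=scene.image_id,
                on_tile_border=on_border))
    return traces


def measure_dna_content(dna_image: np.ndarray, scene: LabeledScene,
                        fallback_percentile: float = 5.0):
    """Per-nucleus integrated, background-subtracted DNA intensity.

    Background is the median intensity outside all cell masks; on a
    confluent tile with no background pixels it falls back to a low
    percentile of the whole image (logged).
    """
    dna_image = np.asarray(dna_image, float)
    outside = scene.cell_mask == 0
    if outside.any():
        bg = float(np.median(dna_image[outside]))
    else:
        bg = float(np.percentile(dna_image, fallback_percentile))
        logger.warning("confluent tile: background from %gth percentile",
                       fallback_percentile)
    out = {}
    for lab in np.unique(scene.nucleus_mask):
        if lab == 0:
            continue
        sel = scene.nucleus_mask == lab
        out[int(lab)] = float(np.sum(dna_image[sel] - bg))
    return out


def read_tile_manifest(path) -> list[tuple]:
    """Load a tile manifest CSV (image_path, x_origin, y_origin, pixel_size).

    Paths are resolved relative to the manifest's directory.  Returns a
    list of ``(image, (x_origin, y_origin), pixel_size)`` tuples ready
    for stitching and contact analysis.
    """
    import pandas as pd
    import tifffile
    from pathlib import Path

    manifest_path = Path(path)
    df = pd.read_csv(manifest_path)
    tiles = []
    for _, row in df.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = manifest_path.parent / img_path
        tiles.append((tifffile.imread(img_path),
                      (float(row["x_origin"]), float(row["y_origin"])),
                      float(row.get("pixel_size", 1.0))))
    return tiles


def project_zstack(stack: np.ndarray, lowpass_sigma: float = 1.0) -> np.ndarray:
    """Gaussian low-pass each slice, then take the per-pixel maximum over z."""
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a 3D array with at least one slice")
    if lowpass_sigma < 0:
        raise ValueError("lowpass_sigma must be nonnegative")
    if lowpass_sigma == 0:
        return stack.max(axis=0)
    filtered = np.stack([
        ndi.gaussian_filter(sl, lowpass_sigma) for sl in stack])
    return filtered.max(axis=0)
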