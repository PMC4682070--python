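"""Segmentation, boundary extraction, DNA measurement, z-projection."""

import numpy as np
import pytest
from skimage.draw import disk

from morphomodes import (LabeledScene, extract_boundaries, measure_dna_content,
                         project_zstack, segment_scene, simulate_sample)
from morphomodes.traces import signed_area


@pytest.fixture(scope="module")
def rendered_scene():
    return simulate_sample(n_cells=20, k_templates=2, seed=21,
                           image_shape=(700, 700), contact_fraction=0.0,
                           n_colonies=2, snr=25.0)


class TestSegmentScene:
    def test_recovers_all_nontouching_cells(self, rendered_scene):
        scene = rendered_scene
        seg = segment_scene(scene.images["dna"], scene.images["actin"])
        n_nuc = len(np.unique(seg.nucleus_mask)) - 1
        n_cell = len(np.unique(seg.cell_mask)) - 1
        assert n_nuc == 20
        assert n_cell == 20
        # per-object area within 5% of the truth masks
        truth_cells = scene.images["cell_mask"]
        for lab in np.unique(seg.cell_mask):
            if lab == 0:
                continue
            sel = seg.cell_mask == lab
            truth_labels = truth_cells[sel]
            truth_lab = np.bincount(truth_labels[truth_labels > 0]).argmax()
            truth_area = (truth_cells == truth_lab).sum()
            assert abs(sel.sum() - truth_area) / truth_area < 0.05

    def test_nucleus_within_cell_and_matching_labels(self, rendered_scene):
        scene = rendered_scene
        seg = segment_scene(scene.images["dna"], scene.images["actin"])
        inside = seg.cell_mask[seg.nucleus_mask > 0]
        assert np.array_equal(inside, seg.nucleus_mask[seg.nucleus_mask > 0])

    def test_blank_images_give_empty_scene(self):
        blank = np.zeros((64, 64))
        seg = segment_scene(blank, blank)
        assert seg.nucleus_mask.max() == 0
        assert seg.cell_mask.max() == 0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            segment_scene(np.zeros((10, 10)), np.zeros((12, 10)))

    def test_touching_cells_split_into_two_labels(self):
        from morphomodes import render_scene, rosette_scene
        from morphomodes.traces import BoundaryTrace
        truth, bnds = rosette_scene(radius_px=14, image_shape=(140, 200))
        truth = truth.iloc[:2].copy()
        truth["x"] = [80.0, 107.0]   # centers 27 px apart, radius 14: touching
        truth["y"] = [70.0, 70.0]
        nuclei = [BoundaryTrace(vertices=b.vertices * 0.45,
                                compartment="nucleus", cell_id=b.cell_id)
                  for b in bnds[:2]]
        img = render_scene(truth, bnds[:2], nuclei, image_shape=(140, 200),
                           snr=30.0, seed=1)
        seg = segment_scene(img["dna"], img["actin"])
        assert len(np.unique(seg.cell_mask)) - 1 == 2
        from morphomodes import build_contact_graph
        G, rho, _ = build_contact_graph(seg.cell_mask)
        assert G.number_of_edges() == 1
        assert set(rho.values()) == {1}


class TestExtractBoundaries:
    def test_square_label_area(self):
        mask = np.zeros((20, 20), np.int32)
        mask[5:15, 5:15] = 1
        scene = LabeledScene(mask, mask, mask.astype(float), mask.astype(float))
        traces = extract_boundaries(scene, compartments=("cell",))
        assert len(traces) == 1
        area = abs(signed_area(traces[0].vertices))
        assert abs(area - 100) <= 20  # within one boundary-pixel band

    def test_disk_label_area_ratio(self):
        mask = np.zeros((80, 80), np.int32)
        rr, cc = disk((40, 40), 30)
        mask[rr, cc] = 1
        scene = LabeledScene(mask, mask, mask.astype(float), mask.astype(float))
        (trace,) = extract_boundaries(scene, compartments=("cell",))
        area = abs(signed_area(trace.vertices))
        assert 0.98 < area / (np.pi * 30 ** 2) < 1.02
        assert not trace.on_tile_border

    def test_counterclockwise_orientation(self, rendered_scene):
        seg = segment_scene(rendered_scene.images["dna"],
                            rendered_scene.images["actin"])
        for t in extract_boundaries(seg)[:10]:
            assert signed_area(t.vertices) > 0

    def test_border_label_flagged(self):
        mask = np.zeros((30, 30), np.int32)
        mask[0:10, 5:15] = 1
        scene = LabeledScene(mask, mask, mask.astype(float), mask.astype(float))
        (trace,) = extract_boundaries(scene, compartments=("cell",))
        assert trace.on_tile_border


class TestMeasureDnaContent:
    def test_ratio_recovered_on_noiseless_render(self):
        from morphomodes import render_scene, rosette_scene
        from morphomodes.traces import BoundaryTrace
        truth, bnds = rosette_scene(radius_px=12, image_shape=(100, 160))
        truth = truth.iloc[:2].copy()
        truth["x"] = [40.0, 120.0]
        truth["y"] = [50.0, 50.0]
        truth["dna_content"] = [1.0, 2.0]
        nuclei = [BoundaryTrace(vertices=b.vertices * 0.5,
                                compartment="nucleus", cell_id=b.cell_id)
                  for b in bnds[:2]]
        img = render_scene(truth, bnds[:2], nuclei, image_shape=(100, 160),
                           seed=0)
        scene = LabeledScene(img["nucleus_mask"], img["cell_mask"],
                             img["dna_noiseless"], img["actin_noiseless"])
        vals = measure_dna_content(img["dna_noiseless"], scene)
        assert abs(vals[2] / vals[1] - 2.0) < 0.01

    def test_zero_image_gives_zero(self):
        mask = np.zeros((20, 20), np.int32)
        mask[5:10, 5:10] = 1
        scene = LabeledScene(mask, mask, np.zeros((20, 20)), np.zeros((20, 20)))
        vals = measure_dna_content(np.zeros((20, 20)), scene)
        assert vals[1] == 0.0

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), np.int32)
        mask[10:20, 10:20] = 1
        img = rng.uniform(10, 12, (40, 40))
        img[10:20, 10:20] += 50
        scene = LabeledScene(mask, mask, img, img)
        base = measure_dna_content(img, scene)[1]
        shifted = measure_dna_content(img + 137.0, scene)[1]
        assert abs(shifted - base) / base < 0.01


class TestProjectZstack:
    def test_single_slice_sigma_zero_identity(self, rng):
        sl = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(project_zstack(sl[None], 0.0), sl)

    def test_max_semantics(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        rr, cc = disk((8, 8), 4)
        b[rr, cc] = 7.0
        out = project_zstack(np.stack([a, b]), 0.0)
        assert np.array_equal(out, b)

    def test_impulse_gaussian_peak_closed_form(self):
        sl = np.zeros((41, 41))
        sl[20, 20] = 1.0
        sigma = 2.0
        out = project_zstack(sl[None], sigma)
        # sampled, normalized Gaussian kernel (truncated at 4 sigma): the
        # filtered impulse peaks at the squared center weight
        k = np.arange(-8, 9)
        w = np.exp(-k ** 2 / (2 * sigma ** 2))
        peak = (w.max() / w.sum()) ** 2
        assert abs(out.max() - peak) < 1e-9
        # and agrees with the continuous closed form at coarse precision
        assert abs(out.max() - 1.0 / (2 * np.pi * sigma ** 2)) < 1e-5

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            project_zstack(np.zeros((0, 8, 8)), 1.0)


def test_read_tile_manifest_roundtrip(tmp_path):
    import pandas as pd
    import tifffile

    from morphomodes import read_tile_manifest
    rng = np.random.default_rng(0)
    for i in range(2):
        tifffile.imwrite(tmp_path / f"tile{i}.tif",
                         rng.integers(0, 100, (16, 16)).astype(np.uint16))
    pd.DataFrame({
        "image_path": ["tile0.tif", "tile1.tif"],
        "x_origin": [0, 16], "y_origin": [0, 0], "pixel_size": [0.65, 0.65],
    }).to_csv(tmp_path / "manifest.csv", index=False)
    tiles = read_tile_manifest(tmp_path / "manifest.csv")
    assert len(tiles) == 2
    img, origin, px = tiles[1]
    assert img.shape == (16, 16)
    assert origin == (16.0, 0.0)
    assert px == 0.65
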