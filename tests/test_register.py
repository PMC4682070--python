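"""Registration: resampling, scaling factor, similarity invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphomodes import (BoundaryTrace, DegenerateShapeError,
                         compute_scaling_factor, register_shape,
                         resample_boundary)
from morphomodes.traces import (curve_centroid, curve_rms_radius, ensure_ccw,
                                signed_area)

from conftest import star_polygon


def brute_force_resample(vertices, n_points):
    """Independent arc-length resampling oracle: walk the edges explicitly."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    perimeter = seg.sum()
    targets = perimeter * np.arange(n_points) / n_points
    out = []
    for s in targets:
        acc = 0.0
        for i in range(len(seg)):
            if acc + seg[i] >= s - 1e-15:
                t = (s - acc) / seg[i] if seg[i] > 0 else 0.0
                out.append(v[i] + t * (v[i + 1] - v[i]))
                break
            acc += seg[i]
    return np.array(out)


class TestResample:
    def test_unit_square_equal_spacing(self, unit_square):
        pts = resample_boundary(unit_square, 50)
        gaps = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        # all interior gaps equal perimeter/50; corner-straddling gaps are
        # chords of the corner, slightly shorter
        arc = 4.0 / 50
        assert pts.shape == (50, 2)
        assert np.all(gaps <= arc + 1e-12)
        straight = np.isclose(gaps, arc, atol=1e-12)
        assert straight.sum() >= 42  # 50 minus at most 2 per corner

    def test_unit_square_arclength_positions(self, unit_square):
        pts = resample_boundary(unit_square, 50)
        oracle = brute_force_resample(unit_square.vertices, 50)
        assert np.allclose(pts, oracle, atol=1e-12)

    def test_circle_radius_and_angles(self, circle_trace):
        pts = resample_boundary(circle_trace, 50)
        radii = np.linalg.norm(pts, axis=1)
        assert np.all(np.abs(radii - 1.0) < 1e-3)
        ang = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
        gaps = np.diff(ang)
        assert np.allclose(gaps, 2 * np.pi / 50, atol=1e-3)

    def test_matches_bruteforce_oracle_on_random_polygons(self, rng):
        for _ in range(50):
            poly = star_polygon(rng, n_vertices=int(rng.integers(10, 120)))
            trace = BoundaryTrace(vertices=poly)
            pts = resample_boundary(trace, 50)
            oracle = brute_force_resample(ensure_ccw(poly), 50)
            assert np.abs(pts - oracle).max() < 1e-9

    def test_zero_perimeter_rejected(self):
        with pytest.raises(DegenerateShapeError):
            BoundaryTrace(vertices=np.zeros((5, 2)))


class TestScalingFactor:
    def test_circle_radius(self, circle_trace):
        pts = resample_boundary(circle_trace, 50)
        assert abs(compute_scaling_factor(pts) - 1.0) < 1e-3

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(3)
        pts = star_polygon(rng, 40)
        assert np.isclose(compute_scaling_factor(pts * c),
                          c * compute_scaling_factor(pts), rtol=1e-12)

    def test_square_against_direct_formula(self, unit_square):
        pts = resample_boundary(unit_square, 50)
        centroid = pts.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        assert abs(compute_scaling_factor(pts) - oracle) < 1e-12

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateShapeError):
            compute_scaling_factor(np.ones((10, 2)))


class TestRegisterShape:
    def test_registered_invariants(self, template_population):
        _, boundaries, _ = template_population
        for b in boundaries[:40]:
            reg = register_shape(b)
            pts = reg.points
            assert pts.shape == (50, 2)
            assert np.abs(pts.mean(axis=0)).max() < 1e-9
            assert abs(np.mean(np.sum(pts ** 2, axis=1)) - 1.0) < 1e-9
            cov = pts.T @ pts / 50
            assert abs(cov[0, 1]) < 1e-9
            assert cov[0, 0] >= cov[1, 1] - 1e-12
            assert signed_area(pts) > 0  # counterclockwise preserved

    def test_rotated_ellipse_axis_alignment(self):
        theta = 2 * np.pi * np.arange(200) / 200
        ell = np.column_stack([2 * np.cos(theta), np.sin(theta)])
        rot = np.deg2rad(30)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        reg = register_shape(BoundaryTrace(vertices=ell @ R.T))
        cov = reg.points.T @ reg.points / 50
        assert cov[0, 0] > cov[1, 1]
        assert abs(cov[0, 1]) < 1e-9

    def test_similarity_and_reindex_invariance(self, template_population, rng):
        _, boundaries, _ = template_population
        worst = 0.0
        for b in boundaries[:100]:
            ref = register_shape(b).feature_vector
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            v = (b.vertices @ R.T) * 3.1 + np.array([17.0, -5.0])
            v = np.roll(v, int(rng.integers(1, len(v))), axis=0)
            other = register_shape(BoundaryTrace(vertices=v)).feature_vector
            worst = max(worst, float(np.abs(ref - other).max()))
        assert worst < 1e-6

    def test_densified_polygon_same_features(self, template_population):
        """Inserting edge-midpoint vertices must not change the features."""
        _, boundaries, _ = template_population
        b = boundaries[0]
        v = b.vertices
        mid = (v + np.roll(v, -1, axis=0)) / 2
        dense = np.empty((2 * len(v), 2))
        dense[0::2] = v
        dense[1::2] = mid
        ref = register_shape(b).feature_vector
        out = register_shape(BoundaryTrace(vertices=dense)).feature_vector
        assert np.abs(ref - out).max() < 1e-9

    def test_idempotent_on_circle(self):
        theta = 2 * np.pi * np.arange(50) / 50
        circ = np.column_stack([np.cos(theta), np.sin(theta)])
        r1 = register_shape(BoundaryTrace(vertices=circ))
        r2 = register_shape(BoundaryTrace(vertices=r1.points))
        assert np.abs(r1.points - r2.points).max() < 1e-9

    def test_reregistration_transform_is_identity(self, template_population):
        """Re-registering a registered outline applies a ~unit transform;
        the points themselves only move at the resampling discretization
        scale (equal arc spacing along the original curve is not equal
        spacing along the 50-gon)."""
        _, boundaries, _ = template_population
        for b in boundaries[:20]:
            r1 = register_shape(b)
            r2 = register_shape(BoundaryTrace(vertices=r1.points))
            assert abs(r2.R - 1.0) < 5e-3
            assert np.abs(r2.centroid_original).max() < 5e-3
            assert np.abs(r1.points - r2.points).max() < 0.05

    def test_degenerate_circle_axis_flagged(self, circle_trace):
        reg = register_shape(circle_trace)
        assert reg.degenerate_axis
        assert reg.rotation_applied == 0.0

    def test_scaling_factor_in_pixels(self):
        theta = 2 * np.pi * np.arange(100) / 100
        circ = 17.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        reg = register_shape(BoundaryTrace(vertices=circ))
        assert abs(reg.R - 17.0) < 0.05


class TestCurveMoments:
    def test_centroid_matches_dense_sampling(self, rng):
        poly = star_polygon(rng, 30)
        c, P = curve_centroid(poly)
        dense = brute_force_resample(ensure_ccw(poly), 20000)
        assert np.abs(c - dense.mean(axis=0)).max() < 1e-6

    def test_rms_radius_matches_dense_sampling(self, rng):
        poly = star_polygon(rng, 30)
        R = curve_rms_radius(poly)
        dense = brute_force_resample(ensure_ccw(poly), 20000)
        d = dense - dense.mean(axis=0)
        assert abs(R - np.sqrt(np.mean(np.sum(d * d, axis=1)))) < 1e-6
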