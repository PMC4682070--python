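"""Boundary traces and exact polygon (curve) geometry.

A :class:`BoundaryTrace` is the raw closed outline of one compartment
(nucleus or cell) in image pixel coordinates, with the convention
x = column index, y = row index, 0-based, origin at the top-left pixel
center.  Orientation is counterclockwise in the mathematical sense:
positive shoelace signed area, first vertex not repeated at the end.

The module also provides *curve moments*: centroid, second-moment matrix,
RMS radius and third x-moment of the uniform measure on the polygon
*boundary* (arc length), computed as exact line integrals over the edges.
These are the quantities the registration stage uses, because they are
exactly invariant to cyclic re-indexing of vertices and to inserting
collinear vertices, unlike moments of a finite resampled point set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateShapeError

__all__ = [
    "BoundaryTrace",
    "signed_area",
    "perimeter",
    "arc_lengths",
    "ensure_ccw",
    "curve_centroid",
    "curve_second_moments",
    "curve_rms_radius",
    "curve_third_x_moment",
    "traces_to_frame",
    "frame_to_traces",
]


@dataclass
class BoundaryTrace:
    """Closed outline of one compartment of one cell, in pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)
    compartment: str = "cell"  # "nucleus" | "cell"
    cell_id: int = 0
    sample_id: str = ""
    image_id: str = ""
    on_tile_border: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateShapeError(
                f"trace needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise DegenerateShapeError("trace vertices must be finite")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise DegenerateShapeError("trace degenerates to < 3 distinct vertices")
        if np.ptp(v, axis=0).max() <= 0:
            raise DegenerateShapeError("zero-perimeter trace (coincident vertices)")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def translated(self, dx: float, dy: float) -> "BoundaryTrace":
        return replace(self, vertices=self.vertices + np.array([dx, dy]))


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive = counterclockwise convention."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def arc_lengths(vertices: np.ndarray) -> np.ndarray:
    """Edge lengths of the closed polygon (last edge closes the loop)."""
    v = np.asarray(vertices, dtype=float)
    return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)


def perimeter(vertices: np.ndarray) -> float:
    return float(arc_lengths(vertices).sum())


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return vertices in counterclockwise order, keeping vertex 0 first."""
    v = np.asarray(vertices, dtype=float)
    if signed_area(v) < 0:
        v = np.vstack([v[:1], v[1:][::-1]])
    return v


def _edge_arrays(vertices: np.ndarray):
    v = np.asarray(vertices, dtype=float)
    w = np.roll(v, -1, axis=0)
    L = np.linalg.norm(w - v, axis=1)
    return v, w, L


def curve_centroid(vertices: np.ndarray):
    """Centroid of the uniform arc-length measure on the polygon boundary.

    Returns (centroid (2,), perimeter).
    """
    v, w, L = _edge_arrays(vertices)
    P = float(L.sum())
    if P <= 0:
        raise DegenerateShapeError("zero-perimeter trace")
    c = ((v + w) / 2 * L[:, None]).sum(axis=0) / P
    return c, P


def curve_second_moments(vertices: np.ndarray, centroid: np.ndarray | None = None):
    """2x2 second-moment matrix of the boundary measure about the centroid.

    M = (1/P) * line integral of (p - c)(p - c)^T ds over the closed polygon.
    Exact per edge: with u = p0 - c, d = p1 - p0,
    integral over the edge = L * (u u^T + (u d^T + d u^T)/2 + d d^T / 3).
    """
    v, w, L = _edge_arrays(vertices)
    P = float(L.sum())
    if centroid is None:
        centroid, _ = curve_centroid(vertices)
    u = v - centroid
    d = w - v
    uu = np.einsum("ni,nj->nij", u, u)
    ud = np.einsum("ni,nj->nij", u, d)
    dd = np.einsum("ni,nj->nij", d, d)
    per_edge = uu + 0.5 * (ud + np.swapaxes(ud, 1, 2)) + dd / 3.0
    return np.einsum("n,nij->ij", L, per_edge) / P


def curve_rms_radius(vertices: np.ndarray, centroid: np.ndarray | None = None) -> float:
    """RMS distance of the boundary (arc-length measure) from its centroid."""
    M = curve_second_moments(vertices, centroid)
    return float(np.sqrt(np.trace(M)))


def curve_third_x_moment(vertices: np.ndarray, centroid: np.ndarray,
                         cos_t: float, sin_t: float) -> float:
    """Line integral of x'(s)^3 ds where x' = cos_t*(x-c) + sin_t*(y-c).

    Used to resolve the 180-degree major-axis ambiguity: the registered
    shape is oriented so that its x-skewness is nonnegative.
    """
    v, w, L = _edge_arrays(vertices)
    u = v - centroid
    d = w - v
    a = u[:, 0] * cos_t + u[:, 1] * sin_t
    b = d[:, 0] * cos_t + d[:, 1] * sin_t
    # integral over t in [0,1] of (a + t b)^3 dt
    per_edge = a**3 + 1.5 * a**2 * b + a * b**2 + 0.25 * b**3
    P = float(L.sum())
    return float((L * per_edge).sum() / P)


def traces_to_frame(traces: Iterable[BoundaryTrace]) -> pd.DataFrame:
    """Long-format boundary table (cell_id, compartment, vertex_index, x, y)."""
    rows = []
    for t in traces:
        n = t.n_vertices
        rows.append(pd.DataFrame({
            "sample_id": t.sample_id,
            "image_id": t.image_id,
            "cell_id": t.cell_id,
            "compartment": t.compartment,
            "on_tile_border": t.on_tile_border,
            "vertex_index": np.arange(n),
            "x": t.vertices[:, 0],
            "y": t.vertices[:, 1],
        }))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "image_id", "cell_id",
                                     "compartment", "on_tile_border",
                                     "vertex_index", "x", "y"])
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> list[BoundaryTrace]:
    traces = []
    keys = ["sample_id", "image_id", "cell_id", "compartment"]
    frame = frame.copy()
    # empty string ids round-trip through CSV as NaN
    for col in ("sample_id", "image_id"):
        frame[col] = frame[col].fillna("")
    for (sample_id, image_id, cell_id, compartment), g in frame.groupby(
            keys, sort=True):
        g = g.sort_values("vertex_index")
        traces.append(BoundaryTrace(
            vertices=g[["x", "y"]].to_numpy(float),
            compartment=str(compartment),
            cell_id=int(cell_id),
            sample_id=str(sample_id),
            image_id=str(image_id),
            on_tile_border=bool(g["on_tile_border"].iloc[0]),
        ))
    return traces
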