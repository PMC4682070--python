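"""Boundary registration: similarity-invariant 50-point shape features.

Every raw outline is converted into a size-, translation- and
rotation-normalized set of 50 equally spaced boundary points plus its
scaling factor R (centroid size).  The resulting 100-number feature
vector (x1..x50, y1..y50) is what the eigenshape PCA consumes.

Normalization conventions
-------------------------
* R (scaling factor) is the RMS distance of the boundary points from
  their centroid ("centroid size"), the standard morphometric size proxy
  for both the cell and the nucleus compartment.
* The major axis of the second-moment matrix is rotated onto the
  horizontal axis (x-variance >= y-variance, cross-moment = 0).
* The remaining 180-degree ambiguity is resolved by requiring the third
  moment of x (the skewness numerator) to be >= 0; mirror images are
  deliberately kept distinct.
* The point sequence starts at the outermost crossing of the positive
  x-axis (the "nose" of the aligned shape) and runs counterclockwise,
  so the 100-vector is well defined for PCA.  A crossing is a root of
  y(s) and therefore moves continuously under small shape perturbations,
  which keeps the feature vectors of near-identical shapes close; the
  max-x vertex is used as a fallback when the centroid lies outside the
  outline.

To make feature vectors invariant to how the *input* polygon happens to
be indexed (cyclic shifts, extra collinear vertices), the normalizing
transform and the canonical start point are derived from exact line
integrals over the polygon (see :mod:`morphomodes.traces`), which do not
depend on the vertex sampling of the curve; the 50 output points are
then resampled from the canonical start and re-normalized discretely so
the registered-shape invariants hold exactly on the 50 points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateShapeError
from .traces import (
    BoundaryTrace,
    arc_lengths,
    curve_centroid,
    curve_second_moments,
    curve_third_x_moment,
    ensure_ccw,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegisteredShape",
    "resample_boundary",
    "compute_scaling_factor",
    "register_shape",
    "register_traces",
    "feature_matrix",
    "registered_table",
]

_DEGENERATE_AXIS_TOL = 1e-12


@dataclass
class RegisteredShape:
    """A similarity-normalized 50-point outline plus its size factor R."""

    points: np.ndarray          # (n_points, 2), centroid 0, RMS radius 1
    R: float                    # scaling factor, pixels (centroid size)
    rotation_applied: float     # radians, total rotation applied to the input
    centroid_original: np.ndarray  # (2,) centroid of the resampled input, pixels
    compartment: str = "cell"
    cell_id: int = 0
    sample_id: str = ""
    degenerate_axis: bool = False

    @property
    def feature_vector(self) -> np.ndarray:
        """The 2*n_points vector (x1..xn, y1..yn) used by the eigenshape PCA."""
        return np.concatenate([self.points[:, 0], self.points[:, 1]])


def resample_boundary(trace: BoundaryTrace | np.ndarray,
                      n_points: int = 50) -> np.ndarray:
    """Resample a closed polygon at ``n_points`` equal arc-length steps.

    The first output point sits at the trace's arc-length origin (vertex 0)
    and the counterclockwise order of the input is preserved.
    """
    v = trace.vertices if isinstance(trace, BoundaryTrace) else np.asarray(trace, float)
    v = ensure_ccw(v)
    return _resample_from(v, 0.0, n_points)


def _resample_from(v: np.ndarray, s0: float, n_points: int) -> np.ndarray:
    """Equal arc-length resampling of closed polygon ``v`` starting at arc
    position ``s0`` (measured from vertex 0)."""
    L = arc_lengths(v)
    P = float(L.sum())
    if P <= 0:
        raise DegenerateShapeError("zero-perimeter trace cannot be resampled")
    cum = np.concatenate([[0.0], np.cumsum(L)])  # length n+1, cum[-1] = P
    s = (s0 + P * np.arange(n_points) / n_points) % P
    closed = np.vstack([v, v[:1]])
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def compute_scaling_factor(points: np.ndarray) -> float:
    """Centroid size: RMS Euclidean distance of the points from their centroid."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise DegenerateShapeError("scaling factor needs >= 3 points")
    r = p - p.mean(axis=0)
    R = float(np.sqrt(np.mean(np.sum(r * r, axis=1))))
    if R <= 0:
        raise DegenerateShapeError("coincident points have no scale")
    return R


def _principal_angle(M: np.ndarray) -> float:
    """Angle of the major principal axis of a 2x2 symmetric moment matrix."""
    return 0.5 * np.arctan2(2.0 * M[0, 1], M[0, 0] - M[1, 1])


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _canonical_start(vt: np.ndarray, cum: np.ndarray) -> float:
    """Arc position of the outermost positive-x-axis crossing of the
    transformed polygon ``vt`` (cumulative arc lengths ``cum``)."""
    n = vt.shape[0]
    y = vt[:, 1]
    x = vt[:, 0]
    y_next = np.roll(y, -1)
    x_next = np.roll(x, -1)
    seg = cum[1:] - cum[:-1]
    best_x = -np.inf
    best_s = None
    for i in range(n):
        if y[i] == 0.0:
            if x[i] > best_x:
                best_x = x[i]
                best_s = cum[i]
        elif y[i] * y_next[i] < 0.0:
            t = y[i] / (y[i] - y_next[i])
            xc = x[i] + t * (x_next[i] - x[i])
            if xc > best_x:
                best_x = xc
                best_s = cum[i] + t * seg[i]
    if best_s is None or best_x <= 0:
        order = np.lexsort((vt[:, 1], vt[:, 0]))
        best_s = cum[order[-1]]
    return float(best_s)


def register_shape(trace: BoundaryTrace, n_points: int = 50) -> RegisteredShape:
    """Register one boundary trace into the canonical shape frame."""
    v = ensure_ccw(trace.vertices)
    c, _P = curve_centroid(v)
    M = curve_second_moments(v, c)
    scale2 = float(np.trace(M))
    if scale2 <= 0:
        raise DegenerateShapeError("zero-extent trace")

    eigvals = np.linalg.eigvalsh(M)
    degenerate = abs(eigvals[1] - eigvals[0]) <= _DEGENERATE_AXIS_TOL * scale2
    if degenerate:
        theta = 0.0
        logger.debug("degenerate principal axis for cell %s/%s; rotation set to 0",
                     trace.cell_id, trace.compartment)
    else:
        theta = _principal_angle(M)
        # rotate by -theta; resolve the 180-degree ambiguity with the
        # third moment of the rotated x coordinate
        skew = curve_third_x_moment(v, c, np.cos(theta), np.sin(theta))
        if skew < 0:
            theta += np.pi

    # canonical start: the outermost crossing of the positive x-axis in the
    # transformed frame.  A root of y(s) moves continuously under small shape
    # perturbations, unlike an arg-max convention which jumps whenever two
    # boundary bumps compete for the largest x; falls back to the max-x
    # vertex if no positive crossing exists (centroid outside the outline).
    vt = (v - c) @ _rot(-theta).T
    L = arc_lengths(v)
    cum = np.concatenate([[0.0], np.cumsum(L)])
    s0 = _canonical_start(vt, cum)

    raw_pts = _resample_from(v, s0, n_points)

    # discrete finalization on the canonical 50 points so the invariants
    # (centroid 0, RMS 1, cross-moment 0) hold exactly on the output
    c50 = raw_pts.mean(axis=0)
    R = compute_scaling_factor(raw_pts)
    p = (raw_pts - c50) / R
    Md = p.T @ p / p.shape[0]
    if degenerate:
        theta_d = 0.0
    else:
        theta_d = _principal_angle(Md)
    p = p @ _rot(-theta_d).T
    skew_d = float(np.mean(p[:, 0] ** 3))
    flipped = False
    if skew_d < -1e-12:
        p = -p
        flipped = True

    total_rotation = float(theta_d + (np.pi if flipped else 0.0))
    return RegisteredShape(
        points=p,
        R=R,
        rotation_applied=total_rotation,
        centroid_original=c50,
        compartment=trace.compartment,
        cell_id=trace.cell_id,
        sample_id=trace.sample_id,
        degenerate_axis=bool(degenerate),
    )


def register_traces(traces, n_points: int = 50) -> list[RegisteredShape]:
    """Register a collection of traces, skipping degenerate ones with a warning."""
    out = []
    for t in traces:
        try:
            out.append(register_shape(t, n_points=n_points))
        except DegenerateShapeError as e:
            logger.warning("dropping degenerate trace cell=%s compartment=%s: %s",
                           t.cell_id, t.compartment, e)
    return out


def feature_matrix(shapes) -> np.ndarray:
    """Stack registered shapes into an (n, 2*n_points) feature matrix."""
    return np.array([s.feature_vector for s in shapes])


def registered_table(shapes) -> pd.DataFrame:
    """Registered-shape table: ids, R, rotation, then x1..xn, y1..yn columns."""
    if not shapes:
        return pd.DataFrame()
    n = shapes[0].points.shape[0]
    cols = [f"x{i+1}" for i in range(n)] + [f"y{i+1}" for i in range(n)]
    feats = feature_matrix(shapes)
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in shapes],
        "cell_id": [s.cell_id for s in shapes],
        "compartment": [s.compartment for s in shapes],
        "R": [s.R for s in shapes],
        "rotation": [s.rotation_applied for s in shapes],
    })
    return pd.concat([df, pd.DataFrame(feats, columns=cols)], axis=1)
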