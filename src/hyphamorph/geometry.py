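"""Planar polyline geometry: traces, arc length, turn angles, kink detection.

All coordinates are in micrometres with image conventions: x is the column
direction, y is the row direction (y increases downward). Angles are turn
(deflection) magnitudes in degrees, in [0, 180]; 0 means a collinear
continuation. Because sin(180 - a) = sin(a), deformity values computed from
deflection angles are numerically identical to the interior-angle convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import approximate_polygon

from .exceptions import InvalidGeometryError, InvalidTraceError

__all__ = [
    "PolylineTrace",
    "arc_length",
    "deflection_angle",
    "junction_angle",
    "simplify_trace",
    "detect_kinks",
]

TRACE_ROLES = ("body_axis", "hypha", "bud_path", "medial_path")


@dataclass(frozen=True)
class PolylineTrace:
    """An ordered planar polyline (medial-axis segment) in micrometres.

    Parameters
    ----------
    points:
        Array of shape (n, 2) with columns (x_um, y_um), n >= 2. Consecutive
        points must be distinct. Self-intersection is allowed: buckled hyphae
        may loop over themselves.
    role:
        One of ``body_axis``, ``hypha``, ``bud_path`` or ``medial_path``
        (the concatenated pole-to-tip path).
    """

    points: np.ndarray
    role: str = "hypha"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidTraceError(
                f"trace needs >=2 planar points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidTraceError("trace contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise InvalidTraceError("consecutive trace points must be distinct")
        if self.role not in TRACE_ROLES:
            raise InvalidTraceError(f"unknown trace role {self.role!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def length_um(self) -> float:
        return arc_length(self)

    def transformed(self, matrix: np.ndarray | None = None,
                    offset: Sequence[float] = (0.0, 0.0)) -> "PolylineTrace":
        """Return the trace under an affine map p -> p @ matrix.T + offset."""
        pts = self.points
        if matrix is not None:
            pts = pts @ np.asarray(matrix, dtype=float).T
        return PolylineTrace(pts + np.asarray(offset, dtype=float), role=self.role)


def arc_length(trace: PolylineTrace | np.ndarray) -> float:
    """Total Euclidean length of a polyline, in micrometres."""
    pts = trace.points if isinstance(trace, PolylineTrace) else np.asarray(trace, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidTraceError("arc_length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _turn_deg(v_in: np.ndarray, v_out: np.ndarray) -> float:
    # atan2 of |cross| / dot is stable near 0 and 180 degrees, unlike arccos
    cross = v_in[0] * v_out[1] - v_in[1] * v_out[0]
    dot = float(np.dot(v_in, v_out))
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def deflection_angle(p_prev: Sequence[float], p_vertex: Sequence[float],
                     p_next: Sequence[float]) -> float:
    """Turn magnitude at a vertex, in degrees in [0, 180].

    The angle between the incoming direction (p_prev -> p_vertex) and the
    outgoing direction (p_vertex -> p_next); 0 means collinear continuation,
    180 a full reversal.
    """
    a = np.asarray(p_prev, float)
    b = np.asarray(p_vertex, float)
    c = np.asarray(p_next, float)
    v_in = b - a
    v_out = c - b
    if np.linalg.norm(v_in) == 0.0 or np.linalg.norm(v_out) == 0.0:
        raise InvalidGeometryError("coincident points give no direction")
    return _turn_deg(v_in, v_out)


def simplify_trace(points: np.ndarray, tol_um: float) -> np.ndarray:
    """Recursive maximum-perpendicular-deviation (Douglas-Peucker) simplification.

    With ``tol_um == 0`` only exactly collinear interior vertices are removed.
    """
    pts = np.asarray(points, dtype=float)
    if tol_um < 0:
        raise InvalidGeometryError("simplification tolerance must be >= 0")
    out = approximate_polygon(pts, tolerance=tol_um)
    if out.shape[0] < 2:  # degenerate closed-ish input; keep endpoints
        out = pts[[0, -1]]
    return out


def junction_angle(body_axis: PolylineTrace, hypha: PolylineTrace,
                   simplify_tol_um: float = 0.1,
                   min_body_len_um: float = 0.1) -> float:
    """Angle between the cell-body long axis and the emerging hypha, degrees.

    The body long-axis direction is taken pole-to-pole, pointing toward the
    pole nearest the hypha's first point (the attachment). The hypha direction
    is its first simplified segment. 0 means the hypha emerges collinear with
    the long axis.
    """
    b = body_axis.points
    axis_vec = b[-1] - b[0]
    axis_len = float(np.linalg.norm(axis_vec))
    if axis_len < min_body_len_um:
        raise InvalidGeometryError(
            f"body axis length {axis_len:.3g} um below resolution "
            f"{min_body_len_um:.3g} um"
        )
    attach = hypha.points[0]
    # orient the axis toward the hyphal pole
    if np.linalg.norm(attach - b[-1]) > np.linalg.norm(attach - b[0]):
        axis_vec = -axis_vec
    h = simplify_trace(hypha.points, simplify_tol_um)
    hy_vec = h[1] - h[0]
    return _turn_deg(axis_vec, hy_vec)


def detect_kinks(trace: PolylineTrace, simplify_tol_um: float = 0.1,
                 min_kink_deg: float = 10.0) -> list[tuple[int, float]]:
    """Find kinks along a trace as (vertex_index, deflection_deg) pairs.

    The trace is first simplified with the recursive maximum-deviation method
    at tolerance ``simplify_tol_um`` (collapsing pixel-level jitter), then
    every interior vertex of the simplified polyline whose deflection is
    >= ``min_kink_deg`` is reported, ordered from attachment to tip. Vertex
    indices refer to the simplified polyline. An empty result is a valid
    outcome: a straight hypha.
    """
    if simplify_tol_um < 0:
        raise InvalidGeometryError("simplify_tol_um must be >= 0")
    if not (0.0 <= min_kink_deg < 180.0):
        raise InvalidGeometryError("min_kink_deg must be in [0, 180)")
    simp = simplify_trace(trace.points, simplify_tol_um)
    kinks: list[tuple[int, float]] = []
    for i in range(1, simp.shape[0] - 1):
        ang = deflection_angle(simp[i - 1], simp[i], simp[i + 1])
        if ang >= min_kink_deg and ang > 0.0:
            kinks.append((i, ang))
    return kinks
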