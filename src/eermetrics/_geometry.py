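"""Quadratic Bezier lid-arc geometry in chord coordinates.

A lid arc is a quadratic Bezier whose control point lies on the
perpendicular bisector of the chord between the two commissures.  In the
chord frame (u along the chord, v along the outward normal) such a curve
is always the parabola ``v(t) = 2 t (1 - t) s`` with ``u(t) = t L``, where
``s`` is the (signed) distance of the control point from the chord
midpoint and ``L`` the chord length.  This makes the minimal control-point
displacement that clears a set of points available in closed form, and the
curve apex (t = 1/2) sits exactly halfway between chord midpoint and
control point.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "chord_frame",
    "quad_bezier",
    "min_clearance",
    "sample_arc",
]


def chord_frame(p0, p2, orientation: str):
    """Return (origin, unit chord vector, outward unit normal, chord length).

    ``orientation`` is "upper" (outward normal points toward smaller y,
    image-up) or "lower" (toward larger y).  Coordinates are (x, y) with
    the origin at the top-left corner and y growing downward.
    """
    p0 = np.asarray(p0, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    chord = p2 - p0
    length = float(np.hypot(*chord))
    if length == 0.0:
        raise ValueError("chord endpoints coincide")
    u = chord / length
    # Rotate u by 90 degrees; pick the sign whose y-component matches the
    # requested orientation (y down: "upper" means negative y).
    n = np.array([u[1], -u[0]])
    if orientation == "upper":
        if n[1] > 0:
            n = -n
    elif orientation == "lower":
        if n[1] < 0:
            n = -n
    else:
        raise ValueError(f"orientation must be 'upper' or 'lower', got {orientation!r}")
    return p0, u, n, length


def quad_bezier(p0, p1, p2, t):
    """Evaluate a quadratic Bezier at parameter values ``t`` (shape (m, 2))."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    t = np.asarray(t, dtype=float)[:, None]
    return (1.0 - t) ** 2 * p0 + 2.0 * t * (1.0 - t) * p1 + t**2 * p2


def min_clearance(p0, p2, points, orientation: str, t_band=(0.0, 1.0)) -> float:
    """Minimal control-point displacement ``s >= 0`` clearing ``points``.

    Each point with a positive outward offset ``v`` at chord fraction
    ``t in (0, 1)`` requires ``s >= v / (2 t (1 - t))``; points behind the
    chord or beyond its ends impose no constraint.  ``t_band`` optionally
    restricts which chord fractions contribute (the constraint is
    ill-conditioned for points almost on top of an endpoint).
    """
    origin, u, n, length = chord_frame(p0, p2, orientation)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return 0.0
    w = pts - origin
    tpar = (w @ u) / length
    v = w @ n
    eps = 1e-9
    lo, hi = max(t_band[0], eps), min(t_band[1], 1.0 - eps)
    inside = (tpar > lo) & (tpar < hi) & (v > 0.0)
    if not np.any(inside):
        return 0.0
    tpar = tpar[inside]
    v = v[inside]
    return float(np.max(v / (2.0 * tpar * (1.0 - tpar))))


def fit_clearance(p0, p2, points, orientation: str, t_band=(0.02, 0.98)) -> float:
    """Least-squares displacement ``s >= 0`` through points lying ON the arc.

    For points sampled from the arc itself, ``v = 2 t (1 - t) s`` holds
    exactly, so a least-squares fit of ``s`` recovers the arc robustly
    even when the chord endpoints are estimated a pixel or two off
    (where the pointwise minimal-clearance ratio is ill-conditioned).
    """
    origin, u, n, length = chord_frame(p0, p2, orientation)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return 0.0
    w = pts - origin
    tpar = (w @ u) / length
    v = w @ n
    sel = (tpar > t_band[0]) & (tpar < t_band[1])
    if not np.any(sel):
        return 0.0
    basis = 2.0 * tpar[sel] * (1.0 - tpar[sel])
    denom = float(basis @ basis)
    if denom == 0.0:
        return 0.0
    return max(0.0, float(basis @ v[sel]) / denom)


def control_point(p0, p2, s: float, orientation: str):
    """Control point at displacement ``s`` along the outward normal."""
    origin, u, n, length = chord_frame(p0, p2, orientation)
    mid = (np.asarray(p0, dtype=float) + np.asarray(p2, dtype=float)) / 2.0
    return mid + s * n


def sample_arc(p0, p2, s: float, orientation: str, n_samples: int | None = None):
    """Densely sampled (x, y) polyline of the arc with displacement ``s``."""
    _, _, _, length = chord_frame(p0, p2, orientation)
    if n_samples is None:
        n_samples = max(int(4 * length), 32)
    p1 = control_point(p0, p2, s, orientation)
    t = np.linspace(0.0, 1.0, n_samples)
    return quad_bezier(np.asarray(p0, float), p1, np.asarray(p2, float), t)


def fill_between_arcs(shape, p0, p2, s_upper: float, s_lower: float, n_samples: int = 2048):
    """Boolean raster of the region between the upper and lower arcs.

    Both arcs share the commissure chord (p0, p2), which is assumed
    near-horizontal so each arc is function-like in x; the region is
    filled column-wise with both boundary rows included.  Generator and
    analyzer share this routine so their area conventions agree exactly.
    """
    up = sample_arc(p0, p2, s_upper, "upper", n_samples)
    lo = sample_arc(p0, p2, s_lower, "lower", n_samples)
    h, w = shape
    xs = np.arange(w, dtype=float)

    def curve_y(pts, fill):
        order = np.argsort(pts[:, 0])
        y = np.interp(xs, pts[order, 0], pts[order, 1], left=np.nan, right=np.nan)
        return np.where(np.isnan(y), fill, y)

    yu = curve_y(up, np.inf)
    yl = curve_y(lo, -np.inf)
    yy = np.arange(h, dtype=float)[:, None]
    return (yy >= yu[None, :]) & (yy <= yl[None, :])
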