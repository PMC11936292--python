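"""Canny edge detection and Hough circle voting for pupil/iris localization.

The edge detector follows the classic five-stage recipe: Gaussian
smoothing, Sobel gradients, non-maximum suppression along the quantized
gradient direction, double thresholding, and hysteresis keeping weak
edges 8-connected to strong ones.  The circle transform votes, for every
edge pixel (x, y) and candidate radius r, at centers
``a = x - r cos(theta)``, ``b = y - r sin(theta)`` with theta stepped in
1-degree increments over [0, 360).

Coordinates are (x right, y down) with the origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DetectionError, ValidationError
from .segmentation import IRIS, PUPIL

__all__ = ["EdgeMap", "Circle", "canny_edges", "hough_circles", "detect_pupil_iris"]


@dataclass
class EdgeMap:
    edges: np.ndarray  # bool
    gradient_magnitude: np.ndarray
    gradient_angle: np.ndarray


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float
    votes: int = 0

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "r": self.r, "votes": self.votes}

    def center_distance(self, other: "Circle") -> float:
        return float(np.hypot(self.cx - other.cx, self.cy - other.cy))


def _shift(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with zero fill (neighbour lookup at borders sees 0)."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    yt = slice(max(0, -dy), min(h, h - dy))
    xt = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = arr[yt, xt]
    return out


def canny_edges(
    image: np.ndarray,
    gaussian_sigma: float = 1.4,
    t_low: float = 0.10,
    t_high: float = 0.20,
) -> EdgeMap:
    """Canny edges; ``t_low``/``t_high`` are fractions of the max gradient.

    Raises on color input: callers convert to grayscale explicitly so the
    conversion convention stays in one place.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError(
            "canny_edges expects a grayscale 2-D raster; convert color images first"
        )
    if not t_low < t_high:
        raise ValidationError(f"need t_low < t_high, got {t_low} >= {t_high}")
    smoothed = ndimage.gaussian_filter(image.astype(float), gaussian_sigma)
    gx = ndimage.sobel(smoothed, axis=1)
    gy = ndimage.sobel(smoothed, axis=0)
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)

    # Non-maximum suppression along the quantized gradient direction.
    angle = np.rad2deg(theta) % 180.0
    offsets = {  # direction bin -> (dy, dx) of the "positive" neighbour
        0: (0, 1),
        45: (1, 1),
        90: (1, 0),
        135: (1, -1),
    }
    dir_bin = np.zeros_like(angle)
    dir_bin[(angle >= 22.5) & (angle < 67.5)] = 45
    dir_bin[(angle >= 67.5) & (angle < 112.5)] = 90
    dir_bin[(angle >= 112.5) & (angle < 157.5)] = 135
    suppressed = np.zeros_like(mag)
    for d, (dy, dx) in offsets.items():
        sel = dir_bin == d
        pos = _shift(mag, -dy, -dx)  # neighbour at +(dy, dx)
        neg = _shift(mag, dy, dx)
        # strict vs non-strict split breaks plateau ties to one pixel
        keep = sel & (mag > pos) & (mag >= neg)
        suppressed[keep] = mag[keep]

    peak = suppressed.max()
    if peak == 0:
        empty = np.zeros(image.shape, dtype=bool)
        return EdgeMap(empty, mag, theta)
    hi = t_high * peak
    lo = t_low * peak
    strong = suppressed > hi
    weak = (suppressed > lo) & ~strong
    candidates = strong | weak
    comp, _ = ndimage.label(candidates, structure=np.ones((3, 3), dtype=bool))
    strong_ids = np.unique(comp[strong])
    edges = candidates & np.isin(comp, strong_ids[strong_ids > 0])
    return EdgeMap(edges, mag, theta)


def _vote_plane(ys, xs, r: float, shape, n_angles: int) -> np.ndarray:
    """Accumulator plane for one radius (vectorized over edge pixels)."""
    h, w = shape
    ang = np.deg2rad(np.arange(n_angles) * (360.0 / n_angles))
    dx = np.round(r * np.cos(ang)).astype(np.int64)
    dy = np.round(r * np.sin(ang)).astype(np.int64)
    a = xs[:, None] - dx[None, :]
    b = ys[:, None] - dy[None, :]
    ok = (a >= 0) & (a < w) & (b >= 0) & (b < h)
    flat = (b[ok] * w + a[ok]).ravel()
    return np.bincount(flat, minlength=h * w).reshape(h, w)


def hough_accumulator(edges: np.ndarray, radii, n_angles: int = 360) -> np.ndarray:
    """Full (radius, y, x) vote accumulator (exposed for verification)."""
    edges = np.asarray(edges, dtype=bool)
    ys, xs = np.nonzero(edges)
    return np.stack([_vote_plane(ys, xs, float(r), edges.shape, n_angles) for r in radii])


def hough_circles(
    edge_map,
    r_min: float,
    r_max: float,
    r_step: float = 1.0,
    max_circles: int = 2,
    min_center_distance: float = 10.0,
    n_angles: int = 360,
    vote_floor_frac: float = 0.3,
) -> list[Circle]:
    """Peak circles from Hough voting, in descending vote order.

    Ties break toward smaller radius, then row-major center order.  A
    candidate within ``min_center_distance`` of an accepted center is
    suppressed; additionally near-duplicates of an accepted circle (center
    within 5 px and radius within 5 px) are suppressed so that
    ``min_center_distance=0`` admits genuinely concentric circles without
    returning +-1 px radius ghosts.
    """
    if not (0 < r_min <= r_max):
        raise ValidationError(f"need 0 < r_min <= r_max, got {r_min}, {r_max}")
    edges = edge_map.edges if isinstance(edge_map, EdgeMap) else np.asarray(edge_map, bool)
    ys, xs = np.nonzero(edges)
    if ys.size == 0:
        return []
    radii = np.arange(r_min, r_max + 0.5 * r_step, r_step, dtype=float)
    acc = hough_accumulator(edges, radii, n_angles)
    top = acc.max()
    if top == 0:
        return []
    floor = max(3, int(vote_floor_frac * top))
    ri, by, bx = np.nonzero(acc >= floor)
    votes = acc[ri, by, bx]
    # votes desc, then smaller radius, then row-major (y, x)
    order = np.lexsort((bx, by, radii[ri], -votes))
    chosen: list[Circle] = []
    for idx in order:
        cand = Circle(float(bx[idx]), float(by[idx]), float(radii[ri[idx]]), int(votes[idx]))
        ok = True
        for c in chosen:
            d = c.center_distance(cand)
            if d < min_center_distance:
                ok = False
                break
            if d < 5.0 and abs(c.r - cand.r) < 5.0:
                ok = False
                break
        if ok:
            chosen.append(cand)
            if len(chosen) >= max_circles:
                break
    return chosen


def class_boundaries(labels: np.ndarray, classes) -> np.ndarray:
    """Pixels of the given classes that are 4-adjacent to any other class."""
    member = np.isin(labels, list(classes))
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(member, structure=cross, border_value=0)
    return member & ~interior


def _region_radius_bounds(member: np.ndarray, r_min: float, r_max: float):
    ys, xs = np.nonzero(member)
    extent = max(ys.max() - ys.min(), xs.max() - xs.min()) + 1
    lo = float(np.floor(max(r_min, extent / 4.0 - 2.0, 3.0)))
    hi = float(np.ceil(min(r_max, extent / 2.0 + 3.0)))
    return lo, max(hi, lo)


def detect_pupil_iris(
    label_mask: np.ndarray | None,
    fallback_image: np.ndarray | None = None,
    r_min: float = 5.0,
    r_max: float = 160.0,
    r_step: float = 1.0,
    concentricity_tol: float = 5.0,
    canny_sigma: float = 1.4,
    t_low: float = 0.10,
    t_high: float = 0.20,
) -> tuple[Circle, Circle]:
    """Locate the pupil and iris as a concentric circle pair.

    Primary route: Hough voting on the class-boundary rasters of the
    label mask (pupil boundary; outer boundary of iris+pupil), with the
    radius search narrowed to the class region's bounding-box scale.
    Fallback: Canny on the raw image when the mask route is unavailable.
    Among admissible pairs (pupil.r < iris.r, center separation within
    ``concentricity_tol``) the pair with maximal summed votes wins.
    """
    pupil_cands: list[Circle] = []
    iris_cands: list[Circle] = []
    if label_mask is not None:
        labels = np.asarray(label_mask)
        pupil_member = labels == PUPIL
        iris_member = (labels == IRIS) | (labels == PUPIL)
        if pupil_member.any():
            lo, hi = _region_radius_bounds(pupil_member, r_min, r_max)
            pupil_cands = hough_circles(
                class_boundaries(labels, [PUPIL]), lo, hi, r_step, 4, 0.0
            )
        if iris_member.any():
            lo, hi = _region_radius_bounds(iris_member, r_min, r_max)
            iris_cands = hough_circles(
                class_boundaries(labels, [IRIS, PUPIL]), lo, hi, r_step, 4, 0.0
            )
    if (not pupil_cands or not iris_cands) and fallback_image is not None:
        em = canny_edges(np.asarray(fallback_image, dtype=float), canny_sigma, t_low, t_high)
        cands = hough_circles(em, r_min, r_max, r_step, 8, 0.0)
        if not pupil_cands:
            pupil_cands = cands
        if not iris_cands:
            iris_cands = cands
    if not pupil_cands or not iris_cands:
        missing = "pupil" if not pupil_cands else "iris"
        raise DetectionError(f"no {missing} circle could be detected", missing=missing)
    best: tuple[Circle, Circle] | None = None
    best_votes = -1
    for p in pupil_cands:
        for i in iris_cands:
            if p.r < i.r and p.center_distance(i) <= concentricity_tol:
                if p.votes + i.votes > best_votes:
                    best = (p, i)
                    best_votes = p.votes + i.votes
    if best is None:
        raise DetectionError(
            "no admissible concentric pupil/iris pair "
            f"(concentricity_tol={concentricity_tol})",
            missing="pair",
        )
    return best
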