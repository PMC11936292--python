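"""Boolean mask algebra and the exposure-metric family (CER/MWR/LWR/EEA/EER).

From a 6-class label mask and the detected pupil/iris circles this module
builds the mask set:

* ``full_iris`` — the disk implied by the detected iris circle,
* ``exposed_eye`` — union of white-area, iris and pupil class pixels,
* ``cornea`` — ``full_iris AND exposed_eye``,
* ``exposure_area`` — cornea plus exposed white area,
* ``whole_area`` — region enclosed by two quadratic Bezier lid arcs
  through the fissure corners, pushed out just enough to encompass the
  protruding rims of the full iris and the white area,

and computes, as percentages of pixel counts:

* CER = 100 |cornea| / |full_iris|
* MWR = 100 |white_medial| / (|white| + |cornea|)
* LWR = 100 |white_lateral| / (|white| + |cornea|)
* EEA = |exposure_area| (pixels, and mm^2 via calibration)
* EER = 100 |exposure_area| / |whole_area|

Pixel-to-millimetre calibration treats the detected iris diameter as the
inter-limbal (white-to-white) distance, conventionally 11.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from .circles import Circle, detect_pupil_iris
from .errors import (
    DegenerateEyeError,
    InvalidParameterError,
    PipelineStageError,
    ValidationError,
)
from .segmentation import (
    CARUNCLE,
    IRIS,
    PUPIL,
    WHITE_AREA,
    segment,
    validate_label_mask,
)

INTERLIMBAL_MM = 11.5  # conventional white-to-white corneal diameter

__all__ = ["MaskSet", "EyeMetrics", "LidArc", "lid_arc", "build_masks", "compute_metrics", "measure_eye"]


@dataclass
class LidArc:
    """A quadratic Bezier lid arc with its rasterized polyline."""

    p0: np.ndarray
    p1: np.ndarray  # control point on the perpendicular bisector
    p2: np.ndarray
    orientation: str

    def sample(self, n_samples: int | None = None) -> np.ndarray:
        _, _, _, length = geom.chord_frame(self.p0, self.p2, self.orientation)
        if n_samples is None:
            n_samples = max(int(4 * length), 32)
        t = np.linspace(0.0, 1.0, n_samples)
        return geom.quad_bezier(self.p0, self.p1, self.p2, t)

    @property
    def polyline(self) -> np.ndarray:
        """Integer pixel polyline (x, y), consecutive duplicates removed."""
        pts = np.round(self.sample()).astype(int)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        return pts[keep]

    @property
    def apex(self) -> np.ndarray:
        return geom.quad_bezier(self.p0, self.p1, self.p2, np.array([0.5]))[0]


def lid_arc(endpoints, encompass, orientation: str) -> LidArc:
    """Minimal-displacement quadratic Bezier through ``endpoints``.

    The control point sits on the perpendicular bisector of the chord at
    the smallest displacement such that every ``encompass`` point lies on
    or below (upper arc) / on or above (lower arc) the curve.  An empty
    ``encompass`` yields the straight chord.
    """
    p0, p2 = (np.asarray(p, dtype=float) for p in endpoints)
    if np.array_equal(p0, p2):
        raise InvalidParameterError("lid_arc endpoints must be distinct")
    pts = np.atleast_2d(np.asarray(list(encompass), dtype=float)) if len(encompass) else np.empty((0, 2))
    s = geom.min_clearance(p0, p2, pts, orientation) if pts.size else 0.0
    p1 = geom.control_point(p0, p2, s, orientation)
    return LidArc(p0, np.asarray(p1), p2, orientation)


@dataclass
class MaskSet:
    cornea: np.ndarray
    exposed_eye: np.ndarray
    full_iris: np.ndarray
    exposure_area: np.ndarray
    whole_area: np.ndarray
    white_medial: np.ndarray
    white_lateral: np.ndarray
    side: str
    pupil: Circle
    iris: Circle


@dataclass
class EyeMetrics:
    cer: float
    mwr: float
    lwr: float
    eea_px: int
    eea_mm2: float
    eer: float
    mm_per_px: float
    pupil: Circle
    iris: Circle

    def to_dict(self) -> dict:
        return {
            "cer": self.cer,
            "mwr": self.mwr,
            "lwr": self.lwr,
            "eea_px": self.eea_px,
            "eea_mm2": self.eea_mm2,
            "eer": self.eer,
            "mm_per_px": self.mm_per_px,
            "pupil": self.pupil.to_dict(),
            "iris": self.iris.to_dict(),
        }


def _column_rims(region: np.ndarray):
    """Topmost and bottommost (x, y) rim points per occupied column."""
    ys, xs = np.nonzero(region)
    order = np.lexsort((ys, xs))
    xs, ys = xs[order], ys[order]
    cols, starts = np.unique(xs, return_index=True)
    top = ys[starts]
    ends = np.r_[starts[1:], len(ys)] - 1
    bot = ys[ends]
    upper = np.column_stack([cols, top]).astype(float)
    lower = np.column_stack([cols, bot]).astype(float)
    return upper, lower


def build_masks(
    label_mask: np.ndarray,
    pupil: Circle,
    iris: Circle,
    side: str,
    include_caruncle: bool = False,
) -> MaskSet:
    """Assemble the mask set from class labels and detected circles."""
    labels = validate_label_mask(label_mask)
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    h, w = labels.shape
    yy, xx = np.ogrid[:h, :w]
    full_iris = (xx - iris.cx) ** 2 + (yy - iris.cy) ** 2 <= iris.r**2
    if not full_iris.any():
        raise DegenerateEyeError("full-iris mask is empty (circle outside frame?)")
    white = labels == WHITE_AREA
    caruncle = labels == CARUNCLE
    exposed_eye = white | (labels == IRIS) | (labels == PUPIL)
    cornea = full_iris & exposed_eye
    exposure = cornea | white
    if include_caruncle:
        exposure = exposure | caruncle

    split_x = int(round(pupil.cx))
    medial_is_left = side == "left"
    if medial_is_left:
        medial_cols = xx <= split_x
    else:
        medial_cols = xx >= split_x
    white_medial = white & medial_cols
    white_lateral = white & ~medial_cols

    # Whole-eye reconstruction: chord endpoints at the extreme-x pixels of
    # the exposed region (plus caruncle), arcs encompassing the protruding
    # rims of full-iris and white area.
    anchor = exposed_eye | caruncle
    if not anchor.any():
        raise DegenerateEyeError("no exposed pixels; aperture appears closed")
    ays, axs = np.nonzero(anchor)
    xl, xr = axs.min(), axs.max()
    yl = int(np.median(ays[axs == xl]))
    yr = int(np.median(ays[axs == xr]))
    if xl == xr:
        raise DegenerateEyeError("exposed region has no horizontal extent")
    # The exposed rim lies on the lid arcs themselves, so the arc
    # displacement is recovered by least squares over the rim (stable
    # against the 1-2 px endpoint estimation error); the detected iris
    # circle adds a hard clearance constraint where the full disk
    # protrudes past the lids.
    upper_rim, lower_rim = _column_rims(anchor)
    ang = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    circle_rim = np.column_stack(
        [iris.cx + iris.r * np.cos(ang), iris.cy + iris.r * np.sin(ang)]
    )
    p0 = np.array([xl, yl], dtype=float)
    p2 = np.array([xr, yr], dtype=float)
    arcs = {}
    for orient, rim in (("upper", upper_rim), ("lower", lower_rim)):
        s = max(
            geom.fit_clearance(p0, p2, rim, orient),
            geom.min_clearance(p0, p2, circle_rim, orient, t_band=(0.03, 0.97)),
        )
        arcs[orient] = (s, LidArc(p0, np.asarray(geom.control_point(p0, p2, s, orient)), p2, orient))
    whole = geom.fill_between_arcs(labels.shape, p0, p2, arcs["upper"][0], arcs["lower"][0])
    whole |= exposure  # rasterization guard: exposure is inside by definition

    return MaskSet(
        cornea=cornea,
        exposed_eye=exposed_eye,
        full_iris=full_iris,
        exposure_area=exposure,
        whole_area=whole,
        white_medial=white_medial,
        white_lateral=white_lateral,
        side=side,
        pupil=pupil,
        iris=iris,
    )


def compute_metrics(mask_set: MaskSet, interlimbal_mm: float = INTERLIMBAL_MM) -> EyeMetrics:
    """Pixel-count ratios of the mask set, with mm calibration."""
    n_full_iris = int(np.count_nonzero(mask_set.full_iris))
    if n_full_iris == 0:
        raise DegenerateEyeError("full-iris mask is empty")
    n_whole = int(np.count_nonzero(mask_set.whole_area))
    if n_whole == 0:
        raise DegenerateEyeError("whole-area mask is empty")
    n_cornea = int(np.count_nonzero(mask_set.cornea))
    n_med = int(np.count_nonzero(mask_set.white_medial))
    n_lat = int(np.count_nonzero(mask_set.white_lateral))
    n_white_total = n_med + n_lat + n_cornea
    n_exposure = int(np.count_nonzero(mask_set.exposure_area))
    cer = 100.0 * n_cornea / n_full_iris
    mwr = 100.0 * n_med / n_white_total if n_white_total else 0.0
    lwr = 100.0 * n_lat / n_white_total if n_white_total else 0.0
    eer = 100.0 * n_exposure / n_whole
    mm_per_px = interlimbal_mm / (2.0 * mask_set.iris.r)
    return EyeMetrics(
        cer=cer,
        mwr=mwr,
        lwr=lwr,
        eea_px=n_exposure,
        eea_mm2=n_exposure * mm_per_px**2,
        eer=eer,
        mm_per_px=mm_per_px,
        pupil=mask_set.pupil,
        iris=mask_set.iris,
    )


def measure_eye(
    image: np.ndarray | None = None,
    label_mask: np.ndarray | None = None,
    side: str = "left",
    config=None,
) -> EyeMetrics:
    """End-to-end measurement: segment, detect circles, build masks, score.

    Either a grayscale image (segmented by the reference backend) or a
    ready label mask must be provided.  Deterministic for fixed input and
    configuration; stage failures are re-raised with the stage name.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if image is None and label_mask is None:
        raise ValidationError("measure_eye needs an image or a label mask")
    if label_mask is None:
        try:
            label_mask = segment(image, backend="reference")
        except Exception as e:  # pragma: no cover - segment raises ValidationError
            raise PipelineStageError("segment", e) from e
    else:
        label_mask = validate_label_mask(label_mask)
    try:
        pupil, iris = detect_pupil_iris(
            label_mask,
            fallback_image=image,
            r_min=cfg.hough_r_min,
            r_max=cfg.hough_r_max,
            r_step=cfg.hough_r_step,
            concentricity_tol=cfg.concentricity_tol,
            canny_sigma=cfg.canny_sigma,
            t_low=cfg.canny_t_low,
            t_high=cfg.canny_t_high,
        )
    except Exception as e:
        raise PipelineStageError("detect", e) from e
    try:
        ms = build_masks(label_mask, pupil, iris, side, include_caruncle=cfg.include_caruncle)
        return compute_metrics(ms, interlimbal_mm=cfg.interlimbal_mm)
    except Exception as e:
        raise PipelineStageError("metrics", e) from e
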