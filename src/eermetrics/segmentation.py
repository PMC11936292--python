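"""Six-class periocular label schema, cropping, reference segmentation, mIoU.

The label alphabet is fixed: 0 background, 1 eyelid, 2 white area,
3 caruncle, 4 iris, 5 pupil.  Real photographs are segmented upstream by
an external model and enter through the ``external`` backend; the
``reference`` backend is an intensity-band classifier scoped to synthetic
scenes whose class intensities are known and well separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError

BACKGROUND, EYELID, WHITE_AREA, CARUNCLE, IRIS, PUPIL = range(6)
N_CLASSES = 6
CLASS_NAMES = ("background", "eyelid", "white_area", "caruncle", "iris", "pupil")

#: Default gray level rendered for each class by the synthetic generator.
DEFAULT_INTENSITIES = {
    BACKGROUND: 30,
    EYELID: 70,
    WHITE_AREA: 220,
    CARUNCLE: 160,
    IRIS: 110,
    PUPIL: 15,
}

DEFAULT_FRAME_SIZE = 512

_EIGHT = np.ones((3, 3), dtype=bool)


def validate_label_mask(labels: np.ndarray) -> np.ndarray:
    """Check the label alphabet and return the mask as uint8."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValidationError(f"label mask must be 2-D, got shape {labels.shape}")
    vals = np.unique(labels)
    if vals.min() < 0 or vals.max() >= N_CLASSES:
        bad = [int(v) for v in vals if v < 0 or v >= N_CLASSES]
        raise ValidationError(f"label mask contains unknown class values {bad}")
    return labels.astype(np.uint8)


def class_pixel_counts(labels: np.ndarray) -> dict[int, int]:
    counts = np.bincount(labels.ravel(), minlength=N_CLASSES)
    return {c: int(counts[c]) for c in range(N_CLASSES)}


def crop_eye_region(image: np.ndarray, center, frame_size: int = DEFAULT_FRAME_SIZE):
    """Crop a ``frame_size`` square centered on ``center`` = (x, y).

    The output is always exactly frame-sized; where the requested window
    exceeds the source, it is zero-padded and the padding extents are
    reported as ``{"left", "right", "top", "bottom"}``.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValidationError("expected a 2-D (or 2-D multichannel) raster")
    h, w = image.shape[:2]
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError(f"crop center ({cx}, {cy}) outside image of shape {(h, w)}")
    half = frame_size // 2
    x0, y0 = int(round(cx)) - half, int(round(cy)) - half
    x1, y1 = x0 + frame_size, y0 + frame_size
    pad = {
        "left": max(0, -x0),
        "top": max(0, -y0),
        "right": max(0, x1 - w),
        "bottom": max(0, y1 - h),
    }
    out_shape = (frame_size, frame_size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    sy = slice(max(0, y0), min(h, y1))
    sx = slice(max(0, x0), min(w, x1))
    out[pad["top"] : frame_size - pad["bottom"], pad["left"] : frame_size - pad["right"]] = image[sy, sx]
    return out, pad


def _nearest_intensity_labels(image: np.ndarray, intensities: dict[int, float]) -> np.ndarray:
    classes = np.array(sorted(intensities), dtype=np.uint8)
    levels = np.array([intensities[c] for c in classes], dtype=float)
    order = np.argsort(levels)
    classes, levels = classes[order], levels[order]
    cuts = (levels[:-1] + levels[1:]) / 2.0  # intensity band edges
    idx = np.searchsorted(cuts, image.astype(float))
    return classes[idx]


def _cleanup(labels: np.ndarray, min_component_px: int = 16) -> np.ndarray:
    """Drop sub-threshold connected components per class; re-label them.

    Noise speckle forms tiny components (and tiny holes inside other
    classes); anatomical regions are orders of magnitude larger.  A size
    threshold is used rather than keeping only the largest component
    because the white area legitimately splits into medial and lateral
    parts on either side of the iris.  Dropped pixels are re-assigned
    iteratively to the modal label of their resolved 8-neighbours.
    """
    labels = labels.copy()
    pending = np.zeros(labels.shape, dtype=bool)
    for c in range(N_CLASSES):
        member = labels == c
        if not member.any():
            continue
        comp, n = ndimage.label(member, structure=_EIGHT)
        if n <= 1:
            continue
        sizes = np.bincount(comp.ravel())
        small = sizes < min_component_px
        small[0] = False
        if small.any():
            pending |= small[comp]
    while pending.any():
        ys, xs = np.nonzero(pending)
        progressed = False
        h, w = labels.shape
        for y, x in zip(ys, xs):
            y0, y1 = max(0, y - 1), min(h, y + 2)
            x0, x1 = max(0, x - 1), min(w, x + 2)
            nbr_lab = labels[y0:y1, x0:x1][~pending[y0:y1, x0:x1]]
            if nbr_lab.size == 0:
                continue
            labels[y, x] = np.bincount(nbr_lab).argmax()
            pending[y, x] = False
            progressed = True
        if not progressed:  # isolated pending blob: background it
            labels[pending] = BACKGROUND
            break
    return labels


def segment(
    image: np.ndarray,
    backend: str = "reference",
    external_mask: np.ndarray | None = None,
    intensities: dict[int, float] | None = None,
) -> np.ndarray:
    """Produce a 6-class label mask for an image.

    backend "reference": nearest-intensity-band classification followed by
    largest-component cleanup.  backend "external": validate and pass
    through an externally produced mask (e.g. from a trained network).
    """
    image = np.asarray(image)
    if backend == "external":
        if external_mask is None:
            raise ValidationError("external backend requires external_mask")
        mask = validate_label_mask(external_mask)
        if mask.shape != image.shape[:2]:
            raise ValidationError(
                f"external mask shape {mask.shape} != image shape {image.shape[:2]}"
            )
        return mask
    if backend != "reference":
        raise ValidationError(f"unknown segmentation backend {backend!r}")
    if image.ndim == 3:
        image = image.mean(axis=2)
    labels = _nearest_intensity_labels(image, intensities or DEFAULT_INTENSITIES)
    return _cleanup(labels)


@dataclass
class SegEvalResult:
    """Dataset-level IoU accumulation result."""

    per_class_iou: dict[int, float]
    miou: float
    total_intersection: np.ndarray
    total_union: np.ndarray
    excluded_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "miou": self.miou,
            "per_class_iou": {CLASS_NAMES[c]: v for c, v in self.per_class_iou.items()},
            "excluded_classes": [CLASS_NAMES[c] for c in self.excluded_classes],
            "total_intersection": self.total_intersection.tolist(),
            "total_union": self.total_union.tolist(),
        }


def mean_iou(pred_masks, gt_masks, n_classes: int = N_CLASSES) -> SegEvalResult:
    """Mean intersection-over-union accumulated over the whole dataset.

    Intersections and unions are summed per class across all images first
    and divided once at the end (not averaged per image).  Classes whose
    accumulated union is zero are excluded from the mean and reported.
    """
    pred_masks = list(pred_masks)
    gt_masks = list(gt_masks)
    if len(pred_masks) == 0:
        raise ValidationError("mean_iou requires at least one mask pair")
    if len(pred_masks) != len(gt_masks):
        raise ValidationError("pred and gt sequences differ in length")
    total_i = np.zeros(n_classes, dtype=np.int64)
    total_u = np.zeros(n_classes, dtype=np.int64)
    for pred, gt in zip(pred_masks, gt_masks):
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValidationError(f"mask shape mismatch {pred.shape} vs {gt.shape}")
        for c in range(n_classes):
            p = pred == c
            g = gt == c
            total_i[c] += int(np.count_nonzero(p & g))
            total_u[c] += int(np.count_nonzero(p | g))
    per_class: dict[int, float] = {}
    excluded: list[int] = []
    for c in range(n_classes):
        if total_u[c] == 0:
            excluded.append(c)
        else:
            per_class[c] = float(total_i[c] / total_u[c])
    if not per_class:
        raise ValidationError("no class has nonzero union across the dataset")
    miou = float(np.mean(list(per_class.values())))
    return SegEvalResult(per_class, miou, total_i, total_u, excluded)
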