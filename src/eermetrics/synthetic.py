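"""Procedural frontal eye scenes with exact ground truth, plus cohort simulation.

A scene is a palpebral-fissure aperture bounded by two quadratic Bezier
lid arcs through the commissures, containing concentric iris and pupil
disks (possibly occluded by the lids), a medial caruncle blob and an
exposed white (scleral) region, each rendered at a distinct gray level
with optional Gaussian pixel noise.  The ground truth carries the exact
label raster, the true circles, and analytic pixel counts, so every
downstream stage can be validated without any external data.

The cohort simulator draws per-eye pre/post exposure rates from the
severity-stratified normal distributions reported for real ptosis
cohorts (mild 65.45 +- 6.96 -> 74.87 +- 8.06; moderate-to-severe
51.98 +- 7.11 -> 75.87 +- 7.47, in percent), truncated to [0, 100] by
resampling.  The "manual" method is the automated value plus
observer jitter; a second automated run is an exact copy of the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _geometry as geom
from .circles import Circle
from .errors import InvalidParameterError
from .segmentation import (
    BACKGROUND,
    CARUNCLE,
    DEFAULT_INTENSITIES,
    EYELID,
    IRIS,
    N_CLASSES,
    PUPIL,
    WHITE_AREA,
    class_pixel_counts,
)

__all__ = [
    "EyeSceneParams",
    "GroundTruth",
    "generate_scene",
    "random_scene_params",
    "make_cohort",
    "write_scene",
    "DEFAULT_GROUP_N",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "DEFAULT_MANUAL_JITTER_SD",
]

#: Severity-stratified cohort defaults (percent EER), mild / moderate-severe.
DEFAULT_GROUP_N = {"mild": 51, "moderate_severe": 49}
DEFAULT_GROUP_MEANS = {
    ("mild", "pre"): 65.45,
    ("mild", "post"): 74.87,
    ("moderate_severe", "pre"): 51.98,
    ("moderate_severe", "post"): 75.87,
}
DEFAULT_GROUP_SDS = {
    ("mild", "pre"): 6.96,
    ("mild", "post"): 8.06,
    ("moderate_severe", "pre"): 7.11,
    ("moderate_severe", "post"): 7.47,
}
#: Observer jitter of the simulated manual method, in EER percentage points;
#: chosen so that simulated manual-vs-automated limits of agreement match the
#: +-(1.96 * 1.75) ~ 3.4-point band seen in real method comparisons.
DEFAULT_MANUAL_JITTER_SD = 1.75


@dataclass(frozen=True)
class EyeSceneParams:
    """Geometry, appearance and randomness of one synthetic eye scene."""

    image_size: int = 512
    commissure_left: tuple[float, float] = (48.0, 256.0)
    commissure_right: tuple[float, float] = (464.0, 256.0)
    upper_apex_y: float = 176.0
    lower_apex_y: float = 328.0
    iris_center: tuple[float, float] = (256.0, 256.0)
    iris_radius: float = 88.0
    pupil_radius: float = 34.0
    caruncle_radius: float = 18.0
    side: str = "left"
    region_intensities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sd: float = 4.0
    lid_band_px: float = 48.0
    seed: int = 0

    def validate(self) -> None:
        s = self.image_size
        if s < 32:
            raise InvalidParameterError("image_size must be >= 32")
        if self.side not in ("left", "right"):
            raise InvalidParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0 < self.pupil_radius < self.iris_radius:
            raise InvalidParameterError("need 0 < pupil_radius < iris_radius")
        if self.caruncle_radius <= 0 or self.noise_sd < 0:
            raise InvalidParameterError("caruncle_radius must be > 0 and noise_sd >= 0")
        if tuple(self.commissure_left) == tuple(self.commissure_right):
            raise InvalidParameterError("commissures must be distinct")
        if self.commissure_left[0] >= self.commissure_right[0]:
            raise InvalidParameterError("commissure_left must lie left of commissure_right")
        if not self.upper_apex_y < self.lower_apex_y:
            raise InvalidParameterError("upper_apex_y must be < lower_apex_y (y grows downward)")
        for x, y in (self.commissure_left, self.commissure_right):
            if not (0 <= x < s and 0 <= y < s):
                raise InvalidParameterError("commissures must lie inside the image")
        mid_y = (self.commissure_left[1] + self.commissure_right[1]) / 2.0
        if self.upper_apex_y > mid_y or self.lower_apex_y < mid_y:
            raise InvalidParameterError(
                "lid apexes must lie on their own side of the commissure chord"
            )
        cx, cy = self.iris_center
        r = self.iris_radius
        if not (r <= cx < s - r and r <= cy < s - r):
            raise InvalidParameterError("iris disk must lie fully inside the image")
        if not (0 <= self.upper_apex_y < s and 0 <= self.lower_apex_y < s):
            raise InvalidParameterError("lid apexes must lie inside the image")
        if sorted(self.region_intensities) != list(range(N_CLASSES)):
            raise InvalidParameterError("region_intensities must map all six classes")


@dataclass
class GroundTruth:
    """Exact labels, geometry and analytic pixel counts for one scene."""

    label_mask: np.ndarray
    true_iris: Circle
    true_pupil: Circle
    class_pixel_counts: dict[int, int]
    aperture_px: int
    whole_area_px: int
    exposed_px: int
    true_eer: float
    whole_mask: np.ndarray
    params: EyeSceneParams

    def to_json_dict(self) -> dict:
        d = {
            "true_iris": self.true_iris.to_dict(),
            "true_pupil": self.true_pupil.to_dict(),
            "class_pixel_counts": {int(k): v for k, v in self.class_pixel_counts.items()},
            "aperture_px": self.aperture_px,
            "whole_area_px": self.whole_area_px,
            "exposed_px": self.exposed_px,
            "true_eer": self.true_eer,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.params).items()
            },
        }
        return d


def _disk(shape, cx, cy, r) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _apex_to_s(p0, p2, apex_y: float, orientation: str) -> float:
    """Control displacement so the t=1/2 apex sits at the requested y."""
    origin, u, n, length = geom.chord_frame(p0, p2, orientation)
    mid_y = (p0[1] + p2[1]) / 2.0
    if n[1] == 0:
        raise InvalidParameterError("degenerate vertical commissure chord")
    s = 2.0 * (apex_y - mid_y) / n[1]
    if s < 0:
        raise InvalidParameterError("lid apex lies on the wrong side of the chord")
    return s


def _fill_between_arcs(shape, p0, p2, s_upper, s_lower) -> np.ndarray:
    return geom.fill_between_arcs(shape, p0, p2, s_upper, s_lower)


def generate_scene(params: EyeSceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; same params (incl. seed) give byte-identical output."""
    params.validate()
    size = params.image_size
    shape = (size, size)
    p0 = np.asarray(params.commissure_left, dtype=float)
    p2 = np.asarray(params.commissure_right, dtype=float)
    s_up = _apex_to_s(p0, p2, params.upper_apex_y, "upper")
    s_lo = _apex_to_s(p0, p2, params.lower_apex_y, "lower")
    aperture = _fill_between_arcs(shape, p0, p2, s_up, s_lo)
    if not aperture.any():
        raise InvalidParameterError("aperture is empty; widen the lid arcs")

    cx, cy = params.iris_center
    iris_disk = _disk(shape, cx, cy, params.iris_radius)
    pupil_disk = _disk(shape, cx, cy, params.pupil_radius)

    # Medial corner: image-left for left eyes, image-right for right eyes.
    medial_is_left = params.side == "left"
    corner = p0 if medial_is_left else p2
    direction = 1.0 if medial_is_left else -1.0
    car_x = corner[0] + direction * 1.2 * params.caruncle_radius
    # vertical midpoint of the aperture at the caruncle column
    up_pts = geom.sample_arc(p0, p2, s_up, "upper")
    lo_pts = geom.sample_arc(p0, p2, s_lo, "lower")
    car_y_up = np.interp(car_x, up_pts[:, 0], up_pts[:, 1])
    car_y_lo = np.interp(car_x, lo_pts[:, 0], lo_pts[:, 1])
    car_disk = _disk(shape, car_x, (car_y_up + car_y_lo) / 2.0, params.caruncle_radius)
    # The canthal tissue fills the whole medial corner: extend the caruncle
    # label to the aperture tip beyond its center so no isolated white
    # sliver is left between caruncle and commissure.
    xx_cols = np.arange(size)[None, :]
    medial_tip = xx_cols <= car_x if medial_is_left else xx_cols >= car_x
    car_disk = car_disk | (aperture & medial_tip)

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    dist_out = ndimage.distance_transform_edt(~aperture)
    labels[(~aperture) & (dist_out <= params.lid_band_px)] = EYELID
    labels[iris_disk & ~aperture] = EYELID  # occluded iris belongs to the lid
    labels[aperture] = WHITE_AREA
    labels[car_disk & aperture & ~iris_disk] = CARUNCLE
    labels[iris_disk & aperture] = IRIS
    labels[pupil_disk & aperture] = PUPIL

    levels = params.region_intensities
    image = np.zeros(shape, dtype=float)
    for c in range(N_CLASSES):
        image[labels == c] = levels[c]
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    # Whole-eye area: the lid arcs pushed out just enough to encompass the
    # full iris disk (sampled analytically on its rim).
    ang = np.linspace(0.0, 2.0 * np.pi, 1440, endpoint=False)
    rim = np.column_stack(
        [cx + params.iris_radius * np.cos(ang), cy + params.iris_radius * np.sin(ang)]
    )
    s_up_w = max(s_up, geom.min_clearance(p0, p2, rim, "upper"))
    s_lo_w = max(s_lo, geom.min_clearance(p0, p2, rim, "lower"))
    whole = _fill_between_arcs(shape, p0, p2, s_up_w, s_lo_w) | aperture

    counts = class_pixel_counts(labels)
    exposed = counts[WHITE_AREA] + counts[IRIS] + counts[PUPIL]
    whole_px = int(np.count_nonzero(whole))
    gt = GroundTruth(
        label_mask=labels,
        true_iris=Circle(float(cx), float(cy), float(params.iris_radius)),
        true_pupil=Circle(float(cx), float(cy), float(params.pupil_radius)),
        class_pixel_counts=counts,
        aperture_px=int(np.count_nonzero(aperture)),
        whole_area_px=whole_px,
        exposed_px=int(exposed),
        true_eer=100.0 * exposed / whole_px,
        whole_mask=whole,
        params=params,
    )
    return image, gt


def random_scene_params(seed: int, image_size: int = 512, side: str | None = None) -> EyeSceneParams:
    """Plausible randomized scene geometry for sweeps and fixtures."""
    rng = np.random.default_rng(seed)
    s = image_size
    if side is None:
        side = "left" if rng.random() < 0.5 else "right"
    cy = s / 2.0 + rng.uniform(-0.03, 0.03) * s
    cx = s / 2.0 + rng.uniform(-0.04, 0.04) * s
    iris_r = rng.uniform(0.14, 0.19) * s
    pupil_r = rng.uniform(0.30, 0.50) * iris_r
    margin = 0.08 * s
    comm_y = cy + rng.uniform(-0.02, 0.02) * s
    p0 = (margin + rng.uniform(0, 0.02) * s, comm_y)
    p2 = (s - margin - rng.uniform(0, 0.02) * s, comm_y)
    # Upper lid from mildly droopy (covering ~1/3 of the iris) to fully clear.
    upper_apex = cy - rng.uniform(0.55, 1.35) * iris_r
    lower_apex = cy + rng.uniform(0.95, 1.30) * iris_r
    upper_apex = max(upper_apex, 2.0)
    lower_apex = min(lower_apex, s - 3.0)
    return EyeSceneParams(
        image_size=s,
        commissure_left=p0,
        commissure_right=p2,
        upper_apex_y=float(upper_apex),
        lower_apex_y=float(lower_apex),
        iris_center=(float(cx), float(cy)),
        iris_radius=float(iris_r),
        pupil_radius=float(pupil_r),
        caruncle_radius=float(0.035 * s),
        side=side,
        noise_sd=4.0,
        seed=int(seed),
    )


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated to [0, 100] by resampling (no boundary mass)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out < 0) | (out > 100)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < 0) | (out > 100)
    return out


def make_cohort(
    n_eyes_per_group: dict[str, int] | None = None,
    group_means: dict[tuple[str, str], float] | None = None,
    group_sds: dict[tuple[str, str], float] | None = None,
    manual_jitter_sd: float = DEFAULT_MANUAL_JITTER_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format measurement table of per-eye exposure rates.

    Columns: patient_id, eye, severity, method, phase, eer.  Methods are
    "ai1" (automated), "ai2" (exact repeat of ai1) and "manual" (ai1 plus
    zero-mean normal jitter).
    """
    ns = dict(DEFAULT_GROUP_N if n_eyes_per_group is None else n_eyes_per_group)
    means = dict(DEFAULT_GROUP_MEANS if group_means is None else group_means)
    sds = dict(DEFAULT_GROUP_SDS if group_sds is None else group_sds)
    if any(v < 0 for v in sds.values()) or manual_jitter_sd < 0:
        raise InvalidParameterError("standard deviations must be >= 0")
    if any(n < 2 for n in ns.values()):
        raise InvalidParameterError("need at least 2 eyes per group")
    rng = np.random.default_rng(seed)
    rows = []
    eye_idx = 0
    for severity in ns:
        n = ns[severity]
        draws = {
            phase: _truncated_normal(rng, means[(severity, phase)], sds[(severity, phase)], n)
            for phase in ("pre", "post")
        }
        jitter = {phase: rng.normal(0.0, manual_jitter_sd, n) for phase in ("pre", "post")}
        for i in range(n):
            patient = f"P{eye_idx // 2 + 1:03d}"
            eye = "L" if eye_idx % 2 == 0 else "R"
            for phase in ("pre", "post"):
                ai = float(draws[phase][i])
                manual = float(np.clip(ai + jitter[phase][i], 0.0, 100.0))
                rows.append((patient, eye, severity, "ai1", phase, ai))
                rows.append((patient, eye, severity, "ai2", phase, ai))
                rows.append((patient, eye, severity, "manual", phase, manual))
            eye_idx += 1
    return pd.DataFrame(
        rows, columns=["patient_id", "eye", "severity", "method", "phase", "eer"]
    )


def write_scene(outdir, stem: str, image: np.ndarray, gt: GroundTruth) -> dict[str, Path]:
    """Write image PNG, label-mask PNG and ground-truth JSON sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}.png",
        "mask": outdir / f"{stem}_mask.png",
        "gt": outdir / f"{stem}_gt.json",
    }
    iio.imwrite(paths["image"], image)
    iio.imwrite(paths["mask"], gt.label_mask)
    paths["gt"].write_text(json.dumps(gt.to_json_dict(), indent=1, sort_keys=True))
    return paths
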