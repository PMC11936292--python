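"""Run configuration: pipeline thresholds, calibration and reproducibility."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import InvalidParameterError


@dataclass(frozen=True)
class RunConfig:
    """All tunable pipeline knobs with their defaults.

    frame_size: analysis frame side in pixels.
    canny_*: Gaussian sigma and hysteresis thresholds (fractions of the
        maximum gradient magnitude).
    hough_*: circle-search radius range/step in pixels.
    concentricity_tol: max pupil-iris center separation in pixels.
    interlimbal_mm: white-to-white corneal diameter used for calibration.
    include_caruncle: count caruncle pixels as exposed area.
    icc_model: ICC form used by the stats stage.
    """

    frame_size: int = 512
    canny_sigma: float = 1.4
    canny_t_low: float = 0.10
    canny_t_high: float = 0.20
    hough_r_min: float = 5.0
    hough_r_max: float = 160.0
    hough_r_step: float = 1.0
    concentricity_tol: float = 5.0
    interlimbal_mm: float = 11.5
    include_caruncle: bool = False
    icc_model: str = "twoway_random_agreement"
    seed: int = 0

    def __post_init__(self):
        if self.frame_size <= 0 or self.canny_sigma <= 0:
            raise InvalidParameterError("frame_size and canny_sigma must be positive")
        if not 0 < self.canny_t_low < self.canny_t_high:
            raise InvalidParameterError("need 0 < canny_t_low < canny_t_high")
        if not 0 < self.hough_r_min <= self.hough_r_max:
            raise InvalidParameterError("need 0 < hough_r_min <= hough_r_max")
        if self.hough_r_step <= 0 or self.concentricity_tol < 0:
            raise InvalidParameterError("hough_r_step must be > 0, concentricity_tol >= 0")
        if self.interlimbal_mm <= 0:
            raise InvalidParameterError("interlimbal_mm must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load flat ``key = value`` lines; ``#`` starts a comment."""
        values: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip().strip("\"'")
            if key not in valid:
                raise InvalidParameterError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
        values.update(overrides)
        return cls(**values)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def config_hash(self) -> str:
        payload = ";".join(f"{k}={v}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _coerce(key: str, raw: str):
    if key in ("frame_size", "seed"):
        return int(raw)
    if key == "include_caruncle":
        return raw.lower() in ("1", "true", "yes", "on")
    if key == "icc_model":
        return raw
    return float(raw)
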