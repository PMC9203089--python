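"""Arc-shaped spatial-offset regions of interest.

An arc ROI is an annular segment around the illumination-spot centre,
parameterized by its mid-arc radius, radial width, angular centre theta and
fixed angular span (all in the adapter's mm coordinate frame, theta = 0
pointing from the spot centre toward the FOV).  The estimator's features
are the mean calibrated reflectance of each ROI's colour channel over
unsaturated pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .capture import CalibratedReflectanceImage
from .exceptions import DegenerateROIError, InvalidParameterError, MaskedROIError

CHANNELS = ("red", "green", "blue")

#: fixed angular span of every arc, degrees
DEFAULT_SPAN = 90.0


@dataclass(frozen=True)
class ArcROI:
    channel: str
    radius: float  # mm, mid-arc radius from the illumination-spot centre
    width: float  # mm, radial extent
    theta: float = 0.0  # degrees, angular centre
    span: float = DEFAULT_SPAN  # degrees, angular extent

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InvalidParameterError(f"unknown channel {self.channel!r}")
        if self.width <= 0:
            raise InvalidParameterError(f"width must be > 0, got {self.width}")
        if self.radius - self.width / 2 <= 0:
            raise InvalidParameterError(
                f"inner radius must be > 0 (radius={self.radius}, width={self.width})"
            )
        if not 0 < self.span <= 360:
            raise InvalidParameterError(f"span must be in (0, 360], got {self.span}")


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints on the free per-ROI parameters (radius, width, theta)."""

    radius: tuple[float, float] = (2.0, 13.0)
    width: tuple[float, float] = (0.5, 4.0)
    theta: tuple[float, float] = (-60.0, 60.0)

    def clip(self, roi: ArcROI) -> ArcROI:
        return replace(
            roi,
            radius=float(np.clip(roi.radius, *self.radius)),
            width=float(np.clip(roi.width, *self.width)),
            theta=float(np.clip(roi.theta, *self.theta)),
        )


@dataclass(frozen=True)
class ROISet:
    """Ordered arc ROIs; the default composition is 4 blue, 3 green, 2 red."""

    rois: tuple[ArcROI, ...]
    bounds: ParameterBounds = ParameterBounds()

    def __post_init__(self) -> None:
        if not self.rois:
            raise InvalidParameterError("ROISet needs at least one ROI")

    def __len__(self) -> int:
        return len(self.rois)

    def composition(self) -> dict[str, int]:
        counts = {c: 0 for c in CHANNELS}
        for r in self.rois:
            counts[r.channel] += 1
        return counts

    # -- flat-vector view used by the pattern-search optimizer ------------
    def to_vector(self) -> np.ndarray:
        return np.array(
            [v for r in self.rois for v in (r.radius, r.width, r.theta)], dtype=float
        )

    def with_vector(self, vec: np.ndarray) -> "ROISet":
        vec = np.asarray(vec, dtype=float)
        if vec.size != 3 * len(self.rois):
            raise InvalidParameterError("parameter vector length mismatch")
        rois = tuple(
            replace(r, radius=float(vec[3 * i]), width=float(vec[3 * i + 1]),
                    theta=float(vec[3 * i + 2]))
            for i, r in enumerate(self.rois)
        )
        return replace(self, rois=rois)

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for _ in self.rois:
            lo += [self.bounds.radius[0], self.bounds.width[0], self.bounds.theta[0]]
            hi += [self.bounds.radius[1], self.bounds.width[1], self.bounds.theta[1]]
        return np.array(lo), np.array(hi)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "rois": [
                {
                    "channel": r.channel,
                    "radius_mm": r.radius,
                    "width_mm": r.width,
                    "theta_deg": r.theta,
                    "span_deg": r.span,
                }
                for r in self.rois
            ],
            "bounds": {
                "radius_mm": list(self.bounds.radius),
                "width_mm": list(self.bounds.width),
                "theta_deg": list(self.bounds.theta),
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ROISet":
        payload = json.loads(text)
        rois = tuple(
            ArcROI(
                channel=d["channel"],
                radius=d["radius_mm"],
                width=d["width_mm"],
                theta=d["theta_deg"],
                span=d.get("span_deg", DEFAULT_SPAN),
            )
            for d in payload["rois"]
        )
        b = payload.get("bounds")
        bounds = (
            ParameterBounds(
                radius=tuple(b["radius_mm"]),
                width=tuple(b["width_mm"]),
                theta=tuple(b["theta_deg"]),
            )
            if b
            else ParameterBounds()
        )
        return cls(rois=rois, bounds=bounds)


def default_roi_set(composition: dict[str, int] | None = None) -> ROISet:
    """Initial ROI placement: evenly spaced radii per channel, blue nearest.

    The blue channel has the largest unsaturated area near the source (its
    reflectance is weakest), so blue arcs start closest; red arcs sit
    farthest out where the bright red channel is unsaturated.
    """
    composition = composition or {"blue": 4, "green": 3, "red": 2}
    start = {"blue": 3.5, "green": 4.5, "red": 6.5}
    stop = {"blue": 10.0, "green": 10.5, "red": 11.0}
    rois = []
    for channel in ("blue", "green", "red"):
        n = composition.get(channel, 0)
        radii = np.linspace(start[channel], stop[channel], n) if n else []
        for r in radii:
            rois.append(ArcROI(channel=channel, radius=float(r), width=1.5, theta=0.0))
    return ROISet(rois=tuple(rois))


def arc_roi_mask(
    roi: ArcROI,
    image_shape: tuple[int, int],
    mm_per_px: float,
    origin: tuple[float, float],
) -> np.ndarray:
    """Boolean pixel mask of the arc over an image in the adapter frame.

    A pixel belongs to the arc iff its centre's radial distance from the
    spot centre lies in ``[radius - width/2, radius + width/2]`` and its
    angle is within ``span/2`` of ``theta`` (angles wrap).  Raises
    :class:`DegenerateROIError` when the arc misses the image entirely.
    """
    h, w = image_shape[:2]
    x = origin[0] + np.arange(w) * mm_per_px
    y = origin[1] + np.arange(h) * mm_per_px
    xx, yy = np.meshgrid(x, y)
    rr = np.hypot(xx, yy)
    ang = np.degrees(np.arctan2(yy, xx))
    dang = np.abs((ang - roi.theta + 180.0) % 360.0 - 180.0)
    mask = (
        (rr >= roi.radius - roi.width / 2)
        & (rr <= roi.radius + roi.width / 2)
        & (dang <= roi.span / 2)
    )
    if not mask.any():
        raise DegenerateROIError(
            f"arc (channel={roi.channel}, r={roi.radius:.2f} mm) misses the FOV"
        )
    return mask


def extract_features(image: CalibratedReflectanceImage, rois: ROISet) -> np.ndarray:
    """Mean calibrated reflectance per ROI over unsaturated pixels, ROISet order."""
    feats = np.empty(len(rois))
    for i, roi in enumerate(rois.rois):
        mask = arc_roi_mask(roi, image.rgb.shape[:2], image.mm_per_px, image.origin)
        valid = mask & image.saturation_mask
        if not valid.any():
            raise MaskedROIError(
                f"ROI {i} (channel={roi.channel}, r={roi.radius:.2f} mm) "
                "is fully saturated"
            )
        feats[i] = image.channel(roi.channel)[valid].mean()
    return feats


class ArcROIFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: calibrated images -> ROI-mean feature matrix.

    Stateless apart from its parameters; ``fit`` records the feature count.
    """

    def __init__(self, roi_set: ROISet | None = None):
        self.roi_set = roi_set

    def _resolved(self) -> ROISet:
        return self.roi_set if self.roi_set is not None else default_roi_set()

    def fit(self, X, y=None):
        self.n_features_out_ = len(self._resolved())
        return self

    def transform(self, X) -> np.ndarray:
        rois = self._resolved()
        return np.stack([extract_features(img, rois) for img in X])
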