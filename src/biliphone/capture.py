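"""Raw capture sets -> one calibrated RGB reflectance image per patient.

Each measurement consists of 3 flash-on and 3 flash-off 16-bit frames of the
tissue plus a paired set for the HDPE calibration standard.  The chain is:
demosaic (bilinear, RGGB default) -> quarter-area resize (2x2 block mean) ->
kNN-distance outlier-frame rejection -> averaging -> background subtraction
and normalization by the calibration standard:

    R = (tissue_on - tissue_off) / (cal_on - cal_off)

Saturated raw pixels (>= 0.98 of full scale in any flash-on frame) are
propagated into a boolean validity mask, as are pixels whose calibration
denominator falls below a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidMosaicError,
    InvalidParameterError,
)

FULL_SCALE = 65535
#: raw intensities at or above this fraction of full scale count as saturated
SATURATION_FRACTION = 0.98
#: calibration denominators below this fraction of their median are masked
DENOMINATOR_FLOOR = 1e-6 * FULL_SCALE


class Mosaic(str, Enum):
    bayer_rggb = "bayer_rggb"
    rgb_planar = "rgb_planar"


@dataclass
class RawFrame:
    """One 16-bit raw sensor frame.

    ``pixels`` is (H, W) uint16 for ``bayer_rggb`` or (H, W, 3) for
    ``rgb_planar``.
    """

    pixels: np.ndarray
    mosaic: Mosaic = Mosaic.bayer_rggb
    exposure_ms: float = 400.0
    iso: int = 4500
    flash: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        self.mosaic = Mosaic(self.mosaic)
        if px.min() < 0 or px.max() > FULL_SCALE:
            raise InvalidParameterError("raw pixel values must lie in [0, 65535]")
        if self.mosaic is Mosaic.bayer_rggb:
            if px.ndim != 2 or px.shape[0] % 2 or px.shape[1] % 2:
                raise InvalidMosaicError(
                    f"bayer_rggb frames need even 2-D dimensions, got {px.shape}"
                )
        elif px.ndim != 3 or px.shape[2] != 3:
            raise InvalidMosaicError(f"rgb_planar frames need (H, W, 3), got {px.shape}")
        self.pixels = px


@dataclass
class CaptureSet:
    """All frames for one patient: tissue and calibration, flash on and off."""

    tissue_on: list[RawFrame]
    tissue_off: list[RawFrame]
    cal_on: list[RawFrame]
    cal_off: list[RawFrame]
    patient_id: str = ""


@dataclass
class CalibratedReflectanceImage:
    """Background-subtracted, standard-normalized RGB reflectance map.

    ``rgb`` is (H, W, 3) float (channel order R, G, B as stored, accessed by
    name through :meth:`channel`); ``saturation_mask`` is True where the
    pixel is usable.  ``origin`` is the mm coordinate of the centre of pixel
    (0, 0) in the adapter frame (x toward the FOV, origin at the
    illumination-spot centre); ``mm_per_px`` the pixel pitch after
    downsampling.
    """

    rgb: np.ndarray
    saturation_mask: np.ndarray
    mm_per_px: float
    origin: tuple[float, float]
    provenance: dict[str, int] = field(default_factory=dict)

    _CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

    def channel(self, name: str) -> np.ndarray:
        return self.rgb[..., self._CHANNEL_INDEX[name]]

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_mm, y_mm) grids of pixel centres in the adapter frame."""
        h, w = self.rgb.shape[:2]
        x = self.origin[0] + np.arange(w) * self.mm_per_px
        y = self.origin[1] + np.arange(h) * self.mm_per_px
        return np.meshgrid(x, y)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_KERNEL_RB = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float)
_KERNEL_G = np.array([[0, 1, 0], [1, 4, 1], [0, 1, 0]], dtype=float)


def demosaic(frame: RawFrame) -> np.ndarray:
    """Bilinear per-plane demosaic of an RGGB Bayer frame to (H, W, 3) float.

    Each colour plane is interpolated from its mosaic sites by normalized
    convolution (sum of weighted known neighbours over sum of weights),
    which reduces to classic bilinear interpolation away from borders and
    degrades gracefully at them.  ``rgb_planar`` frames pass through as
    float unchanged.
    """
    if frame.mosaic is Mosaic.rgb_planar:
        return frame.pixels.astype(float)
    px = frame.pixels.astype(float)
    h, w = px.shape
    out = np.empty((h, w, 3))
    site = {
        "red": np.zeros((h, w), dtype=bool),
        "green": np.zeros((h, w), dtype=bool),
        "blue": np.zeros((h, w), dtype=bool),
    }
    site["red"][0::2, 0::2] = True
    site["green"][0::2, 1::2] = True
    site["green"][1::2, 0::2] = True
    site["blue"][1::2, 1::2] = True
    for idx, (name, kern) in enumerate(
        [("red", _KERNEL_RB), ("green", _KERNEL_G), ("blue", _KERNEL_RB)]
    ):
        mask = site[name]
        num = ndimage.convolve(np.where(mask, px, 0.0), kern, mode="constant")
        den = ndimage.convolve(mask.astype(float), kern, mode="constant")
        out[..., idx] = num / den
    return out


def quarter_downsample(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Quarter-area resize: ``factor`` x ``factor`` block mean per channel.

    Dimensions not divisible by the factor are trimmed (with a warning) to
    the largest divisible size.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    th, tw = h - h % factor, w - w % factor
    if (th, tw) != (h, w):
        import warnings

        warnings.warn(
            f"image {h}x{w} not divisible by {factor}; trimming to {th}x{tw}",
            stacklevel=2,
        )
        img = img[:th, :tw]
    newshape = (th // factor, factor, tw // factor, factor) + img.shape[2:]
    axes = (1, 3)
    return img.reshape(newshape).mean(axis=axes)


def _frame_features(frames: list[np.ndarray]) -> np.ndarray:
    """Per-frame summary features: per-channel mean and standard deviation."""
    feats = []
    for f in frames:
        f = np.asarray(f, dtype=float)
        if f.ndim == 2:
            f = f[..., None]
        feats.append(
            np.concatenate([f.mean(axis=(0, 1)), f.std(axis=(0, 1))])
        )
    return np.stack(feats)


def flag_outlier_frames(
    frames: list[np.ndarray], k: int = 1, threshold_mads: float = 3.0
) -> np.ndarray:
    """Keep-mask over frames via kNN-distance outlier detection.

    Each frame is summarized by its per-channel mean and standard deviation;
    a frame is flagged when its mean Euclidean distance to its ``k`` nearest
    neighbours exceeds ``median + threshold_mads * MAD`` of all such
    distances.  The minimum-distance frame is always retained.
    """
    if len(frames) < 2:
        raise InsufficientDataError("outlier rejection needs at least 2 frames")
    if k >= len(frames):
        raise InvalidParameterError(f"k={k} must be < number of frames {len(frames)}")
    feats = _frame_features(frames)
    # feature scales differ (means vs stds); normalize by per-feature spread
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    z = feats / scale
    d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    knn = np.sort(d, axis=1)[:, :k].mean(axis=1)
    med = np.median(knn)
    mad = np.median(np.abs(knn - med))
    if mad > 0:
        tol = med + threshold_mads * mad
    else:
        # degenerate spread (e.g. two identical frames): fall back to a
        # relative margin around the median distance
        tol = med * (1.0 + 0.1 * threshold_mads) + 1e-12
    keep = knn <= tol
    keep[np.argmin(knn)] = True  # always retain the most central frame
    return keep


def average_frames(frames: list[np.ndarray], keep: np.ndarray | None = None) -> np.ndarray:
    """Pixelwise mean over kept frames."""
    if keep is None:
        keep = np.ones(len(frames), dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    kept = [np.asarray(f, dtype=float) for f, k in zip(frames, keep) if k]
    if not kept:
        raise InsufficientDataError("no frames left after outlier rejection")
    return np.mean(kept, axis=0)


def compute_saturation_mask(
    frames: list[RawFrame], limit: float | None = None
) -> np.ndarray:
    """True where no flash-on raw frame reaches the saturation limit.

    Operates at raw resolution on the mosaic (or planar) data; a pixel is
    unusable if any flash-on frame saturates there in any plane.
    """
    if limit is None:
        limit = SATURATION_FRACTION * FULL_SCALE
    mask = None
    for f in frames:
        if not f.flash:
            continue
        px = f.pixels
        sat = px >= limit
        if sat.ndim == 3:
            sat = sat.any(axis=2)
        mask = sat if mask is None else (mask | sat)
    if mask is None:
        shape = frames[0].pixels.shape[:2]
        return np.ones(shape, dtype=bool)
    return ~mask


def _shrink_mask(mask: np.ndarray, bayer: bool, factor: int = 2) -> np.ndarray:
    """Carry a raw-resolution validity mask through demosaic + downsample.

    Bilinear demosaic spreads a saturated site into its 3x3 neighbourhood,
    so the invalid region is dilated by one pixel first; block resize then
    requires every contributing pixel to be valid (block AND).
    """
    invalid = ~mask
    if bayer:
        invalid = ndimage.binary_dilation(invalid, structure=np.ones((3, 3), bool))
    h, w = invalid.shape
    th, tw = h - h % factor, w - w % factor
    invalid = invalid[:th, :tw]
    blocks = invalid.reshape(th // factor, factor, tw // factor, factor)
    return ~blocks.any(axis=(1, 3))


def calibrate_reflectance(
    tissue_on: np.ndarray,
    tissue_off: np.ndarray,
    cal_on: np.ndarray,
    cal_off: np.ndarray,
    saturation_mask: np.ndarray | None = None,
    mm_per_px: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    provenance: dict[str, int] | None = None,
) -> CalibratedReflectanceImage:
    """(tissue_on - tissue_off) / (cal_on - cal_off), with denominator floor.

    All four inputs are averaged demosaiced images of identical shape.
    Pixels whose calibration denominator is <= the floor are masked invalid
    rather than clipped; a wholly non-positive denominator raises
    :class:`CalibrationError`.
    """
    shapes = {np.asarray(a).shape for a in (tissue_on, tissue_off, cal_on, cal_off)}
    if len(shapes) != 1:
        raise InvalidParameterError(f"calibration inputs differ in shape: {shapes}")
    denom = np.asarray(cal_on, float) - np.asarray(cal_off, float)
    if not (denom > DENOMINATOR_FLOOR).any():
        raise CalibrationError("calibration denominator non-positive everywhere")
    numer = np.asarray(tissue_on, float) - np.asarray(tissue_off, float)
    valid_denom = denom > DENOMINATOR_FLOOR
    if valid_denom.ndim == 3:
        valid_denom = valid_denom.all(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rgb = np.where(denom > DENOMINATOR_FLOOR, numer / denom, np.nan)
    mask = valid_denom
    if saturation_mask is not None:
        mask = mask & np.asarray(saturation_mask, dtype=bool)
    return CalibratedReflectanceImage(
        rgb=rgb,
        saturation_mask=mask,
        mm_per_px=mm_per_px,
        origin=origin,
        provenance=provenance or {},
    )


def process_capture_set(
    capture: CaptureSet,
    fov_x0_mm: float = 1.5,
    fov_height_mm: float = 9.0,
    fov_width_mm: float = 12.0,
    k: int = 1,
    threshold_mads: float = 3.0,
    downsample_factor: int = 2,
) -> CalibratedReflectanceImage:
    """Full chain from a raw capture set to one calibrated reflectance image.

    ``fov_x0_mm`` is the mm x-coordinate of the proximal FOV edge
    (``spot_radius + edge_offset`` of the adapter); the pixel pitch is
    declared as FOV width over image width after downsampling.
    """
    lists = {
        "tissue_on": capture.tissue_on,
        "tissue_off": capture.tissue_off,
        "cal_on": capture.cal_on,
        "cal_off": capture.cal_off,
    }
    averaged: dict[str, np.ndarray] = {}
    provenance: dict[str, int] = {}
    for name, frames in lists.items():
        if not frames:
            raise InsufficientDataError(f"capture list {name!r} is empty")
        images = [quarter_downsample(demosaic(f), downsample_factor) for f in frames]
        keep = (
            flag_outlier_frames(images, k=k, threshold_mads=threshold_mads)
            if len(images) >= 2
            else np.ones(1, bool)
        )
        averaged[name] = average_frames(images, keep)
        provenance[name] = int(keep.sum())

    bayer = capture.tissue_on[0].mosaic is Mosaic.bayer_rggb
    raw_mask = compute_saturation_mask(capture.tissue_on + capture.cal_on)
    mask = _shrink_mask(raw_mask, bayer=bayer, factor=downsample_factor)

    width_px = averaged["tissue_on"].shape[1]
    mm_per_px = fov_width_mm / width_px
    origin = (fov_x0_mm + mm_per_px / 2, -fov_height_mm / 2 + mm_per_px / 2)
    return calibrate_reflectance(
        averaged["tissue_on"],
        averaged["tissue_off"],
        averaged["cal_on"],
        averaged["cal_off"],
        saturation_mask=mask,
        mm_per_px=mm_per_px,
        origin=origin,
        provenance=provenance,
    )
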