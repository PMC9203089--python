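import numpy as np
import pytest

from biliphone import (
    ArcROI,
    ArcROIFeatureExtractor,
    CalibratedReflectanceImage,
    ROISet,
    arc_roi_mask,
    default_roi_set,
    extract_features,
)
from biliphone.exceptions import (
    DegenerateROIError,
    InvalidParameterError,
    MaskedROIError,
)

SHAPE = (64, 64)
MM_PER_PX = 0.25
# centred symmetric grid: pixel (0,0) at (-7.875, -7.875) mm
ORIGIN = (-(SHAPE[1] - 1) / 2 * MM_PER_PX, -(SHAPE[0] - 1) / 2 * MM_PER_PX)


def brute_force_mask(roi, shape=SHAPE, mm_per_px=MM_PER_PX, origin=ORIGIN):
    mask = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            x = origin[0] + j * mm_per_px
            y = origin[1] + i * mm_per_px
            r = np.hypot(x, y)
            ang = np.degrees(np.arctan2(y, x))
            dang = abs((ang - roi.theta + 180.0) % 360.0 - 180.0)
            mask[i, j] = (
                roi.radius - roi.width / 2 <= r <= roi.radius + roi.width / 2
                and dang <= roi.span / 2
            )
    return mask


def make_image(rgb, mask=None):
    if mask is None:
        mask = np.ones(rgb.shape[:2], dtype=bool)
    return CalibratedReflectanceImage(
        rgb=rgb, saturation_mask=mask, mm_per_px=MM_PER_PX, origin=ORIGIN
    )


def test_full_annulus_matches_brute_force_membership():
    roi = ArcROI("blue", radius=4.0, width=3.0, span=360.0)
    fast = arc_roi_mask(roi, SHAPE, MM_PER_PX, ORIGIN)
    assert np.array_equal(fast, brute_force_mask(roi))


def test_partial_arc_matches_brute_force_membership():
    roi = ArcROI("green", radius=5.0, width=1.5, theta=30.0, span=90.0)
    fast = arc_roi_mask(roi, SHAPE, MM_PER_PX, ORIGIN)
    assert np.array_equal(fast, brute_force_mask(roi))


def test_arc_beyond_the_image_is_degenerate():
    roi = ArcROI("red", radius=40.0, width=1.0)
    with pytest.raises(DegenerateROIError):
        arc_roi_mask(roi, SHAPE, MM_PER_PX, ORIGIN)


def test_opposite_arcs_are_disjoint_and_equal_on_symmetric_grid():
    a = ArcROI("red", radius=4.0, width=2.0, theta=0.0, span=90.0)
    b = ArcROI("red", radius=4.0, width=2.0, theta=180.0, span=90.0)
    ma = arc_roi_mask(a, SHAPE, MM_PER_PX, ORIGIN)
    mb = arc_roi_mask(b, SHAPE, MM_PER_PX, ORIGIN)
    assert not (ma & mb).any()
    assert ma.sum() == mb.sum()


def test_invalid_arc_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        ArcROI("blue", radius=1.0, width=3.0)  # inner radius <= 0
    with pytest.raises(InvalidParameterError):
        ArcROI("blue", radius=5.0, width=0.0)
    with pytest.raises(InvalidParameterError):
        ArcROI("cyan", radius=5.0, width=1.0)
    with pytest.raises(InvalidParameterError):
        ArcROI("blue", radius=5.0, width=1.0, span=400.0)


def test_features_constant_image():
    rois = ROISet(rois=(ArcROI("red", 4.0, 2.0), ArcROI("blue", 5.0, 1.0)))
    rgb = np.stack([np.full(SHAPE, c) for c in (3.0, 2.0, 1.0)], axis=-1)
    feats = extract_features(make_image(rgb), rois)
    assert np.allclose(feats, [3.0, 1.0])


def test_features_match_brute_force_mean_on_radial_ramp():
    roi = ArcROI("green", radius=4.5, width=2.0, span=360.0)
    x = (np.arange(SHAPE[1]) * MM_PER_PX) + ORIGIN[0]
    y = (np.arange(SHAPE[0]) * MM_PER_PX) + ORIGIN[1]
    xx, yy = np.meshgrid(x, y)
    ramp = np.hypot(xx, yy)
    rgb = np.stack([ramp, ramp, ramp], axis=-1)
    feats = extract_features(make_image(rgb), ROISet(rois=(roi,)))
    assert feats[0] == pytest.approx(ramp[brute_force_mask(roi)].mean())


def test_saturated_half_excluded_from_the_mean():
    roi = ArcROI("red", radius=4.0, width=2.0, span=360.0)
    rgb = np.zeros(SHAPE + (3,))
    rgb[..., 0] = 2.0
    mask = np.ones(SHAPE, dtype=bool)
    mask[:, : SHAPE[1] // 2] = False  # left half saturated
    rgb[:, : SHAPE[1] // 2, 0] = 99.0  # garbage under the mask
    feats = extract_features(make_image(rgb, mask), ROISet(rois=(roi,)))
    assert feats[0] == pytest.approx(2.0)


def test_fully_saturated_roi_raises_named_error():
    roi = ArcROI("red", radius=4.0, width=2.0)
    img = make_image(np.ones(SHAPE + (3,)), mask=np.zeros(SHAPE, dtype=bool))
    with pytest.raises(MaskedROIError, match="channel=red"):
        extract_features(img, ROISet(rois=(roi,)))


def test_default_composition_and_json_round_trip():
    rois = default_roi_set()
    assert len(rois) == 9
    assert rois.composition() == {"blue": 4, "green": 3, "red": 2}
    restored = ROISet.from_json(rois.to_json())
    assert restored == rois


def test_vector_round_trip_and_bounds():
    rois = default_roi_set()
    vec = rois.to_vector()
    assert vec.size == 27
    assert rois.with_vector(vec) == rois
    lo, hi = rois.vector_bounds()
    assert np.all(lo < hi)


def test_transformer_stacks_features(small_noiseless_cohort):
    patients, _captures, images, _truth = small_noiseless_cohort
    extractor = ArcROIFeatureExtractor().fit([])
    mat = extractor.transform([images[p] for p in patients["patient_id"][:4]])
    assert mat.shape == (4, 9)
    assert np.all(np.isfinite(mat))
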