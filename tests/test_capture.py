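import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biliphone import (
    RawFrame,
    average_frames,
    calibrate_reflectance,
    compute_saturation_mask,
    demosaic,
    flag_outlier_frames,
    quarter_downsample,
)
from biliphone.capture import FULL_SCALE, Mosaic
from biliphone.exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidMosaicError,
    InvalidParameterError,
)


def bayer(values):
    return RawFrame(pixels=np.asarray(values, dtype=np.uint16))


# ---------------------------------------------------------------------------
# demosaic
# ---------------------------------------------------------------------------


def test_demosaic_constant_field_stays_constant():
    frame = bayer(np.full((6, 6), 1234))
    rgb = demosaic(frame)
    assert rgb.shape == (6, 6, 3)
    assert np.allclose(rgb, 1234.0)


def test_demosaic_per_plane_constants():
    """R-sites 100, G-sites 200, B-sites 300 -> channel means 100/200/300."""
    px = np.zeros((8, 8))
    px[0::2, 0::2] = 100
    px[0::2, 1::2] = 200
    px[1::2, 0::2] = 200
    px[1::2, 1::2] = 300
    rgb = demosaic(bayer(px))
    assert np.allclose(rgb[..., 0], 100)
    assert np.allclose(rgb[..., 1], 200)
    assert np.allclose(rgb[..., 2], 300)


def test_demosaic_hot_green_pixel_bilinear_weights():
    """A single hot G site spreads with hand-computed bilinear weights."""
    px = np.zeros((4, 4))
    px[1, 2] = 400  # green site (odd row, even col)
    rgb = demosaic(bayer(px))
    g = rgb[..., 1]
    assert g[1, 2] == pytest.approx(400.0)  # at the site itself
    # horizontal/vertical neighbours are green-interpolated from the cross
    # kernel [0,1,0;1,4,1;0,1,0]: each has the hot site as one of 4 weighted
    # contributors -> 400 * 1 / 4
    assert g[1, 1] == pytest.approx(100.0)
    assert g[1, 3] == pytest.approx(400.0 / 3)  # border: only 3 kernel taps
    assert g[0, 2] == pytest.approx(400.0 / 3)  # border row: 3 taps as well
    assert g[2, 2] == pytest.approx(100.0)  # interior R site: 4 green taps


def test_demosaic_rejects_odd_dimensions():
    with pytest.raises(InvalidMosaicError):
        RawFrame(pixels=np.zeros((5, 6), dtype=np.uint16))


def test_planar_frames_pass_through():
    px = np.random.default_rng(0).integers(0, 1000, (4, 4, 3)).astype(np.uint16)
    frame = RawFrame(pixels=px, mosaic=Mosaic.rgb_planar)
    assert np.array_equal(demosaic(frame), px.astype(float))


# ---------------------------------------------------------------------------
# downsample
# ---------------------------------------------------------------------------


def test_downsample_constant_and_single_block():
    assert np.allclose(quarter_downsample(np.full((4, 6, 3), 7.0)), 7.0)
    block = np.array([[1.0, 2.0], [3.0, 5.0]])
    assert quarter_downsample(block)[0, 0] == pytest.approx(2.75)


def test_downsample_matches_brute_force_block_means(rng):
    img = rng.random((8, 8, 3))
    out = quarter_downsample(img)
    assert out.shape == (4, 4, 3)
    for i in range(4):
        for j in range(4):
            expected = img[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].mean(axis=(0, 1))
            assert np.allclose(out[i, j], expected)


def test_downsample_trims_with_warning(rng):
    img = rng.random((5, 7))
    with pytest.warns(UserWarning, match="trimming"):
        out = quarter_downsample(img)
    assert out.shape == (2, 3)


# ---------------------------------------------------------------------------
# outlier rejection and averaging
# ---------------------------------------------------------------------------


def test_identical_frames_all_kept():
    frames = [np.full((4, 4, 3), 5.0)] * 3
    assert flag_outlier_frames(frames).tolist() == [True, True, True]


def test_doubled_frame_flagged():
    base = np.full((4, 4, 3), 100.0)
    keep = flag_outlier_frames([base, base, 2 * base], k=1, threshold_mads=3.0)
    assert keep.tolist() == [True, True, False]


def test_near_dark_frame_flagged(rng):
    signal = 1000.0 + rng.normal(0, 5.0, (8, 8, 3))
    frames = [signal + rng.normal(0, 5.0, signal.shape) for _ in range(2)]
    frames.append(0.02 * signal)  # non-contact: flash signal collapsed
    keep = flag_outlier_frames(frames, k=1, threshold_mads=3.0)
    assert keep.tolist() == [True, True, False]


def test_outlier_rejection_validates_inputs():
    with pytest.raises(InsufficientDataError):
        flag_outlier_frames([np.zeros((2, 2, 3))])
    with pytest.raises(InvalidParameterError):
        flag_outlier_frames([np.zeros((2, 2, 3))] * 3, k=3)


def test_average_frames_mean_and_mask():
    frames = [np.full((2, 2), v) for v in (1.0, 2.0, 9.0)]
    assert np.allclose(average_frames(frames), 4.0)
    assert np.allclose(average_frames(frames, np.array([True, True, False])), 1.5)
    assert np.allclose(average_frames(frames[:1]), 1.0)
    with pytest.raises(InsufficientDataError):
        average_frames(frames, np.zeros(3, bool))


def test_average_is_order_invariant(rng):
    frames = [rng.random((4, 4, 3)) for _ in range(3)]
    keep = np.array([True, False, True])
    perm = [2, 0, 1]
    direct = average_frames(frames, keep)
    permuted = average_frames([frames[i] for i in perm], keep[perm])
    assert np.allclose(direct, permuted)


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------


def test_saturation_mask_flags_hot_pixels():
    frames = [bayer(np.zeros((4, 4))), bayer(np.zeros((4, 4)))]
    assert compute_saturation_mask(frames).all()
    hot = np.zeros((4, 4))
    hot[1, 2] = FULL_SCALE
    frames.append(bayer(hot))
    mask = compute_saturation_mask(frames)
    assert not mask[1, 2]
    assert mask.sum() == 15


def test_flash_off_frames_ignored_for_saturation():
    hot = np.full((4, 4), FULL_SCALE)
    off = RawFrame(pixels=hot.astype(np.uint16), flash=False)
    assert compute_saturation_mask([off, bayer(np.zeros((4, 4)))]).all()


def test_raising_the_limit_never_shrinks_the_valid_area(rng):
    frames = [bayer(rng.integers(0, FULL_SCALE, (6, 6)).astype(np.uint16))]
    areas = [
        compute_saturation_mask(frames, limit=l).sum()
        for l in (0.5 * FULL_SCALE, 0.8 * FULL_SCALE, FULL_SCALE)
    ]
    assert areas == sorted(areas)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_self_calibration_identity(rng):
    on = rng.random((4, 4, 3)) * 1000 + 500
    off = rng.random((4, 4, 3)) * 50
    img = calibrate_reflectance(on, off, on, off)
    assert np.allclose(img.rgb[img.saturation_mask], 1.0, atol=1e-12)


def test_calibration_linearity(rng):
    off = rng.random((4, 4, 3)) * 50
    cal_on = off + rng.random((4, 4, 3)) * 1000 + 100
    tissue_on = off + 2.0 * (cal_on - off)
    img = calibrate_reflectance(tissue_on, off, cal_on, off)
    assert np.allclose(img.rgb[img.saturation_mask], 2.0)


def test_wholly_nonpositive_denominator_raises():
    zero = np.zeros((2, 2, 3))
    with pytest.raises(CalibrationError):
        calibrate_reflectance(zero, zero, zero, zero + 1.0)


def test_shape_mismatch_rejected():
    with pytest.raises(InvalidParameterError):
        calibrate_reflectance(
            np.zeros((2, 2, 3)), np.zeros((2, 2, 3)), np.ones((4, 4, 3)),
            np.zeros((4, 4, 3)),
        )


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    gain=st.floats(min_value=0.1, max_value=50.0),
    offset=st.floats(min_value=0.0, max_value=5000.0),
)
def test_gain_and_dark_offset_invariance(gain, offset):
    """Scaling all frames or shifting all frames leaves the calibration fixed."""
    rng = np.random.default_rng(7)
    off = rng.random((4, 4, 3)) * 50
    cal_on = off + rng.random((4, 4, 3)) * 1000 + 100
    tissue_on = off + rng.random((4, 4, 3)) * 400 + 50
    base = calibrate_reflectance(tissue_on, off, cal_on, off).rgb
    scaled = calibrate_reflectance(
        gain * tissue_on + offset, gain * off + offset,
        gain * cal_on + offset, gain * off + offset,
    ).rgb
    assert np.allclose(base, scaled, rtol=1e-9, atol=1e-9)
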