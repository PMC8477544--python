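import numpy as np
import pytest
from scipy import ndimage

from licseg import (
    BinaryMask,
    DegenerateInputError,
    FCMConfig,
    build_rejection_region,
    detect_landmarks,
    detect_vessels,
    make_vessel_subwindow,
    otsu_threshold,
    restrict_roi,
    select_body_roi,
)
from licseg.roi import LandmarkSet, largest_component


def exhaustive_otsu(image, nbins=256):
    """Independent oracle: scan every histogram bin edge for the threshold
    maximising between-class variance."""
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, centers[k - 1]
    return best_t


def test_otsu_separates_two_levels_exactly(rng):
    image = np.where(rng.random((64, 64)) < 0.5, 0.0, 100.0)
    t = otsu_threshold(image)
    assert np.array_equal(image > t, image == 100.0)
    assert np.array_equal(image > exhaustive_otsu(image), image > t)


def test_otsu_on_two_gaussians_misclassifies_below_0p1_percent(rng):
    lo = rng.normal(20.0, 5.0, 5000)
    hi = rng.normal(200.0, 5.0, 5000)
    image = np.concatenate([lo, hi]).reshape(100, 100)
    t = otsu_threshold(image)
    labels = image > t
    truth = np.concatenate([np.zeros(5000, bool), np.ones(5000, bool)]).reshape(100, 100)
    assert np.mean(labels != truth) < 0.001


def test_otsu_rejects_constant_image():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full((32, 32), 3.0))


def test_body_roi_discards_detached_blob_and_fills_holes():
    img = np.zeros((128, 128))
    rr, cc = np.mgrid[0:128, 0:128]
    ellipse = ((rr - 64) / 40.0) ** 2 + ((cc - 64) / 50.0) ** 2 <= 1
    img[ellipse] = 300.0
    hole = ((rr - 80) / 6.0) ** 2 + ((cc - 64) / 6.0) ** 2 <= 1  # dark spine
    img[hole] = 0.0
    img[5:10, 5:10] = 400.0  # detached calibration blob
    body = select_body_roi(img)
    assert np.array_equal(body.pixels, ellipse)  # blob dropped, hole filled
    labels, n = ndimage.label(body.pixels, structure=np.ones((3, 3)))
    assert n == 1
    assert not ndimage.binary_fill_holes(body.pixels).sum() > body.pixels.sum()


def test_body_roi_tie_break_keeps_first_component_in_scan_order():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:10, 5:10] = True
    mask[20:25, 20:25] = True
    kept = largest_component(mask)
    assert kept[5, 5] and not kept[20, 20]


def test_body_roi_errors_on_flat_image():
    with pytest.raises(DegenerateInputError):
        select_body_roi(np.zeros((64, 64)))


def test_subwindow_arithmetic_matches_stated_rule():
    body = np.zeros((256, 256), dtype=bool)
    body[78:178, 28:228] = True  # bbox 100 x 200, centroid (127.5, 127.5)
    win = make_vessel_subwindow(BinaryMask(body), fraction=0.2)
    assert win == (108, 148, 88, 168)


def test_subwindow_clamps_to_image_bounds():
    body = np.zeros((64, 64), dtype=bool)
    body[0:20, 0:20] = True
    r0, r1, c0, c1 = make_vessel_subwindow(BinaryMask(body), fraction=0.5)
    assert r0 >= 0 and c0 >= 0 and r1 <= 63 and c1 <= 63


def test_subwindow_fraction_half_contains_bounding_box():
    body = np.zeros((100, 100), dtype=bool)
    body[30:70, 25:75] = True
    r0, r1, c0, c1 = make_vessel_subwindow(BinaryMask(body), fraction=0.5)
    assert r0 <= 30 and r1 >= 69 and c0 <= 25 and c1 >= 74


def test_vessels_detected_on_phantom_within_two_pixels(default_case, default_result):
    _, truth = default_case
    lm = default_result.landmarks
    assert lm.detection_ok
    assert np.hypot(*(np.subtract(lm.aorta_rc, truth.aorta_rc))) <= 2.0
    assert np.hypot(*(np.subtract(lm.ivc_rc, truth.ivc_rc))) <= 2.0


def test_single_bright_blob_flags_detection_failure():
    img = np.full((64, 64), 10.0)
    img += np.linspace(0, 1, 64)[None, :]  # break constancy
    body = np.zeros((64, 64), dtype=bool)
    body[8:56, 8:56] = True
    img[30:34, 30:34] = 500.0
    aorta, ivc, ok = detect_vessels(img, BinaryMask(body), (8, 55, 8, 55), fcm_cfg=FCMConfig(6))
    assert not ok and aorta is None and ivc is None


def test_rejection_region_matches_brute_force_signed_side(default_case, default_result):
    _, truth = default_case
    lm = default_result.landmarks
    body = default_result.body
    ar, ac = lm.aorta_rc
    pr, pc = lm.anterior_point_rc
    dr, dc = pr - ar, pc - ac
    edge_rows = np.nonzero(body.pixels[:, int(lm.patient_left_edge_col)])[0]
    ref_r = 0.5 * (edge_rows.min() + edge_rows.max())
    ref = np.sign(dr * (lm.patient_left_edge_col - ac) - dc * (ref_r - ar))
    expected = np.zeros_like(body.pixels)
    for r, c in zip(*np.nonzero(body.pixels)):
        expected[r, c] = (dr * (c - ac) - dc * (r - ar)) * ref > 0
    assert np.array_equal(lm.rejection.pixels, expected)


def test_rejection_spares_the_liver_and_stays_inside_body(default_case, default_result):
    _, truth = default_case
    rej = default_result.landmarks.rejection
    body = default_result.body
    assert rej.is_subset_of(body)
    overlap = (rej.pixels & truth.entire_liver.pixels).sum() / truth.entire_liver.area_px
    assert overlap < 0.02
    restricted = default_result.restricted
    retained = (restricted.pixels & truth.entire_liver.pixels).sum() / truth.entire_liver.area_px
    assert retained >= 0.98


def test_landmark_geometry_ordering(default_result):
    lm = default_result.landmarks
    assert lm.midline_col < lm.midclavicular_col < lm.patient_left_edge_col


def test_restrict_roi_identity_and_fallback():
    body = BinaryMask(np.ones((32, 32), dtype=bool))
    empty = BinaryMask(np.zeros((32, 32), dtype=bool))
    restricted, fell_back = restrict_roi(body, empty)
    assert np.array_equal(restricted.pixels, body.pixels) and not fell_back
    restricted, fell_back = restrict_roi(body, body)
    assert np.array_equal(restricted.pixels, body.pixels) and fell_back


def test_build_rejection_requires_successful_detection():
    body = BinaryMask(np.ones((32, 32), dtype=bool))
    from licseg import ValidationError

    with pytest.raises(ValidationError):
        build_rejection_region(LandmarkSet(detection_ok=False), body)
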