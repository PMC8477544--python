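import numpy as np
import pytest
from scipy import special

from licseg import (
    EvalReport,
    MetricUndefinedError,
    ValidationError,
    bland_altman,
    evaluate_clinical,
    grade_output,
    hausdorff_mm,
    paired_t_test,
    percent_cv,
    percent_dsc,
    percent_fn,
    percent_fp,
    percent_jc,
    r_squared,
)
from licseg.metrics import boundary_pixels


def random_blob_pair(rng, shape=(32, 32)):
    a = rng.random(shape) < 0.3
    b = rng.random(shape) < 0.3
    return a, b


def make_report(fp, fn2, fn1=0.0):
    return EvalReport(90.0, 82.0, 10.0, fp, fn1, fn2)


def test_overlap_metric_examples():
    a = np.zeros((8, 8), dtype=bool)
    b = np.zeros((8, 8), dtype=bool)
    a[0, :4] = True
    b[0, 2:6] = True  # |A|=|B|=4, overlap 2, union 6
    assert percent_dsc(a, b) == pytest.approx(50.0)
    assert percent_jc(a, b) == pytest.approx(100.0 * 2 / 6)
    assert percent_dsc(a, a) == 100.0
    assert percent_jc(a, a) == 100.0
    assert percent_dsc(a, np.roll(a, 4, axis=0)) == 0.0
    with pytest.raises(MetricUndefinedError):
        percent_dsc(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


def test_dice_jaccard_identity_on_random_masks(rng):
    for _ in range(200):
        a, b = random_blob_pair(rng)
        if not (a.any() or b.any()):
            continue
        dsc = percent_dsc(a, b)
        jc = percent_jc(a, b)
        assert jc <= dsc + 1e-12
        assert jc == pytest.approx(dsc / (200.0 - dsc) * 100.0, abs=1e-9)


def brute_force_hausdorff(a, b, spacing):
    pa = np.argwhere(boundary_pixels(a)) * spacing
    pb = np.argwhere(boundary_pixels(b)) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def test_hausdorff_examples_and_anisotropic_spacing():
    a = np.zeros((16, 16), dtype=bool)
    b = np.zeros((16, 16), dtype=bool)
    a[5, 5] = True
    b[5, 8] = True  # 3 columns apart
    assert hausdorff_mm(a, b, (1.0, 1.0)) == pytest.approx(3.0)
    assert hausdorff_mm(a, b, (1.6, 3.1)) == pytest.approx(3 * 3.1)
    assert hausdorff_mm(a, a, (1.6, 3.1)) == 0.0
    with pytest.raises(MetricUndefinedError):
        hausdorff_mm(a, np.zeros((16, 16), bool))


def test_hausdorff_matches_brute_force_and_is_symmetric(rng):
    spacing = np.array([1.6, 3.1])
    for _ in range(100):
        a, b = random_blob_pair(rng)
        if not a.any() or not b.any():
            continue
        h = hausdorff_mm(a, b, tuple(spacing))
        assert h == pytest.approx(brute_force_hausdorff(a, b, spacing), abs=1e-9)
        assert h == hausdorff_mm(b, a, tuple(spacing))


def test_fp_fn_inverted_semantics():
    manual = np.zeros((8, 8), dtype=bool)
    manual[0, :] = True
    manual[1, :2] = True  # 10 px total
    auto = manual.copy()
    auto[0, :3] = False  # covers 7 of 10
    assert percent_fp(auto, manual) == pytest.approx(30.0)
    assert percent_fp(manual, manual) == 0.0
    assert percent_fp(np.zeros_like(manual), manual) == 100.0

    ref = np.zeros((8, 8), dtype=bool)
    ref[2:4, 0:5] = True  # 10 px
    protruding = ref.copy()
    protruding[4, 0:5] = True  # 5 px outside
    assert percent_fn(protruding, ref) == pytest.approx(50.0)
    assert percent_fn(ref, ref) == 0.0


def test_fn_type_one_positive_while_type_two_zero():
    entire = np.zeros((16, 16), dtype=bool)
    entire[2:14, 2:14] = True
    manual_clinical = np.zeros_like(entire)
    manual_clinical[4:12, 4:12] = True
    auto = np.zeros_like(entire)
    auto[3:11, 3:11] = True  # inside entire, protrudes past manual clinical
    assert percent_fn(auto, manual_clinical) > 0.0
    assert percent_fn(auto, entire) == 0.0


@pytest.mark.parametrize(
    "fp, fn2, expected",
    [(8.0, 0.0, "I"), (15.0, 0.6, "II"), (55.0, 0.6, "III"), (45.0, 0.0, "III"), (10.0, 7.0, "III")],
)
def test_grading_rule(fp, fn2, expected):
    assert grade_output(make_report(fp, fn2)) == expected


def test_grade_is_total_on_random_reports(rng):
    for _ in range(200):
        rep = make_report(rng.uniform(0, 120), rng.uniform(0, 20))
        assert grade_output(rep) in {"I", "II", "III"}


def test_evaluate_clinical_bundles_metrics(default_case, default_result):
    _, truth = default_case
    rep = evaluate_clinical(
        default_result.liver_clinical, truth.clinical_liver, truth.entire_liver, (1.6, 3.1)
    )
    assert rep.grade in {"I", "II", "III"}
    assert rep.jc_pct <= rep.dsc_pct
    assert np.isfinite(rep.hausdorff_mm)


def test_bland_altman_closed_forms():
    x = np.array([1.0, 2.0, 3.0])
    assert bland_altman(x, x) == (0.0, 0.0, 0.0)
    bias, lo, hi = bland_altman(x + 1.0, x)
    assert (bias, lo, hi) == (1.0, 1.0, 1.0)
    bias, lo, hi = bland_altman(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
    assert bias == 0.0
    assert hi == pytest.approx(1.96 * np.sqrt(2.0))


def test_percent_cv_closed_form_and_scale_invariance():
    x = np.array([10.0, 10.0])
    y = np.array([12.0, 8.0])
    assert percent_cv(x, x) == 0.0
    assert percent_cv(x, y) == pytest.approx(20.0)
    assert percent_cv(3.7 * x, 3.7 * y) == pytest.approx(percent_cv(x, y))
    with pytest.raises(ValidationError):
        percent_cv(-x, -y)


def test_r_squared_identities(rng):
    x = rng.normal(size=100)
    assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)
    y = rng.normal(size=100) + 0.5 * x
    # equals 1 - SSres/SStot of the least-squares line
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert r_squared(x, y) == pytest.approx(1.0 - ss_res / ss_tot, abs=1e-9)
    big = np.random.default_rng(0).normal(size=(2, 10_000))
    assert r_squared(big[0], big[1]) < 0.01
    with pytest.raises(ValidationError):
        r_squared(np.ones(10), x[:10])


def test_paired_t_examples_and_betainc_oracle(rng):
    t, p = paired_t_test(np.array([1.0, -1.0, 1.0, -1.0]), np.zeros(4))
    assert t == 0.0 and p == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        paired_t_test(np.ones(5), np.zeros(5))
    for _ in range(20):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        t, p = paired_t_test(x, y)
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        df = 11
        p_expected = special.betainc(df / 2.0, 0.5, df / (df + t_expected**2))
        assert t == pytest.approx(t_expected, abs=1e-9)
        assert p == pytest.approx(p_expected, abs=1e-6)
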