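import numpy as np
import pytest

from lvseg.evaluation import (ContourPair, VolumeSet, agreement_stats,
                              average_perpendicular_distance, cavity_volume,
                              dice, dice_contours, ejection_fraction,
                              good_contour, lv_mass, percent_good)
from lvseg.imaging_io import Contour


def circle(radius, center=(60.0, 60.0), n=360):
    theta = 2 * np.pi * np.arange(n) / n
    return Contour(np.column_stack([center[0] + radius * np.cos(theta),
                                    center[1] + radius * np.sin(theta)]))


def brute_force_apd(auto_pts, manual_pts):
    """Quadratic all-pairs point-to-segment oracle (plain loops)."""
    total = 0.0
    m = len(manual_pts)
    for p in auto_pts:
        best = np.inf
        for i in range(m):
            a = manual_pts[i]
            b = manual_pts[(i + 1) % m]
            ab = b - a
            denom = ab @ ab
            t = 0.0 if denom == 0 else np.clip((p - a) @ ab / denom, 0.0, 1.0)
            best = min(best, float(np.linalg.norm(p - (a + t * ab))))
        total += best
    return total / len(auto_pts)


class TestAPD:
    def test_identical_contours_zero(self):
        c = circle(50)
        assert average_perpendicular_distance(ContourPair(c, c, 1.0)) == 0.0

    def test_concentric_circles_gap(self):
        pair = ContourPair(circle(52), circle(50), 1.0)
        assert average_perpendicular_distance(pair) == pytest.approx(2.0,
                                                                     abs=0.05)

    def test_matches_quadratic_oracle_on_shifted_square(self):
        sq = Contour(np.array([[10, 10], [30, 10], [30, 30], [10, 30]], float))
        shifted = sq.translated(1.0, 0.0)
        pair = ContourPair(shifted, sq, 1.5)
        expected = 1.5 * brute_force_apd(shifted.points, sq.points)
        assert average_perpendicular_distance(pair) == pytest.approx(
            expected, abs=1e-9)

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            a = circle(rng.uniform(20, 40), n=40)
            pts = a.points + rng.normal(0, 2.0, a.points.shape)
            b = Contour(pts, orient=False)
            pair = ContourPair(b, a, 1.0)
            assert average_perpendicular_distance(pair) == pytest.approx(
                brute_force_apd(b.points, a.points), abs=1e-9)

    def test_one_directional_by_default(self):
        # auto is a small arc-like subset near manual: asymmetric distances
        a = circle(50, n=8)
        b = circle(55, n=360)
        d_ab = average_perpendicular_distance(ContourPair(a, b, 1.0))
        d_sym = average_perpendicular_distance(ContourPair(a, b, 1.0),
                                               symmetric=True)
        assert d_ab != pytest.approx(d_sym)


class TestGoodContours:
    def test_percentage_of_good_contours(self):
        pairs = [ContourPair(circle(50 + g), circle(50), 1.0)
                 for g in (2.0, 6.0, 3.0)]
        assert [good_contour(p) for p in pairs] == [True, False, True]
        assert percent_good(pairs) == pytest.approx(66.67, abs=0.1)

    def test_exactly_five_mm_is_not_good(self):
        # every auto point is exactly 5 mm from the manual polyline
        manual = Contour(np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float))
        # collinear auto polyline hovering 5 px above the manual top edge
        auto = Contour(np.array([[0, 15], [5, 15], [10, 15]], float),
                       orient=False)
        pair = ContourPair(auto, manual, 1.0)
        assert average_perpendicular_distance(pair) == 5.0
        assert not good_contour(pair)

    def test_identical_pairs_all_good(self):
        pairs = [ContourPair(circle(40), circle(40), 1.0)] * 4
        assert percent_good(pairs) == 100.0

    def test_order_invariant(self):
        pairs = [ContourPair(circle(50 + g), circle(50), 1.0)
                 for g in (1.0, 7.0, 2.0, 9.0)]
        assert percent_good(pairs) == percent_good(pairs[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            percent_good([])


class TestDice:
    def test_identical_regions(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        assert dice(a, a) == 1.0

    def test_disjoint_regions(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert dice(a, b) == 0.0

    def test_two_by_two_squares_half_overlap(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # overlap 2 px -> 2*2/(4+4)
        assert dice(a, b) == 0.5

    def test_symmetric(self, rng):
        a = rng.random((20, 20)) < 0.3
        b = rng.random((20, 20)) < 0.3
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((5, 5), bool), np.zeros((5, 5), bool))


class TestVolumes:
    def test_single_slice_cylinder(self):
        v = cavity_volume([circle(20)], (1.0, 1.0), 8.0)
        assert v == pytest.approx(np.pi * 400 * 8 / 1000.0, rel=0.02)

    def test_two_identical_slices_additive(self):
        one = cavity_volume([circle(20)], (1.0, 1.0), 8.0)
        two = cavity_volume([circle(20), circle(20)], (1.0, 1.0), 8.0)
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_linear_in_slice_spacing(self):
        contours = [circle(20), circle(15)]
        v1 = cavity_volume(contours, (1.0, 1.0), 5.0)
        v2 = cavity_volume(contours, (1.0, 1.0), 10.0)
        assert v2 == pytest.approx(2 * v1, abs=1e-12)

    def test_phantom_truth_volume_close_to_closed_form(self, phantom_default):
        study, truth = phantom_default
        sl = study.get_phase("ED")[0]
        v = cavity_volume(truth.endo_contours["ED"], sl.pixel_spacing,
                          sl.slice_spacing_mm)
        assert v == pytest.approx(truth.analytic_endo_ml["ED"], rel=0.03)

    def test_missing_spacing_rejected(self):
        with pytest.raises(ValueError):
            cavity_volume([circle(20)], (0.0, 1.0), 8.0)


class TestClinicalIndices:
    @pytest.mark.parametrize("edv, esv, expected", [
        (120.0, 60.0, 50.0),
        (80.0, 80.0, 0.0),
        (100.0, 35.0, 65.0),
    ])
    def test_ejection_fraction(self, edv, esv, expected):
        assert ejection_fraction(VolumeSet(edv, edv + 50, esv)) == expected

    def test_lv_mass(self):
        assert lv_mass(VolumeSet(100.0, 200.0, 50.0)) == pytest.approx(105.0)
        assert lv_mass(VolumeSet(100.0, 100.0, 50.0)) == 0.0
        assert lv_mass(VolumeSet(100.0, 214.57, 50.0), 1.0) == pytest.approx(
            114.57)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            VolumeSet(200.0, 100.0, 50.0)  # epi < endo
        with pytest.raises(ValueError):
            ejection_fraction(VolumeSet(0.0, 10.0, 0.0))


class TestAgreement:
    def test_perfect_agreement(self):
        e = np.array([10.0, 20.0, 30.0, 40.0])
        s = agreement_stats(e, e)
        assert s["slope"] == pytest.approx(1.0)
        assert s["r_squared"] == pytest.approx(1.0)
        assert s["bias"] == pytest.approx(0.0)

    def test_constant_offset(self):
        e = np.array([10.0, 20.0, 30.0, 40.0])
        s = agreement_stats(e + 3.0, e)
        assert s["slope"] == pytest.approx(1.0)
        assert s["bias"] == pytest.approx(3.0)
        lo, hi = s["limits_of_agreement"]
        assert lo == pytest.approx(3.0) and hi == pytest.approx(3.0)

    def test_matches_closed_form_ols_oracle(self, rng):
        e = np.linspace(50, 150, 10)
        a = 1.1 * e - 4.0 + rng.normal(0, 5.0, 10)
        s = agreement_stats(a, e)
        # normal equations solved independently
        X = np.column_stack([e, np.ones(10)])
        beta = np.linalg.solve(X.T @ X, X.T @ a)
        assert s["slope"] == pytest.approx(beta[0], abs=1e-9)
        assert s["intercept"] == pytest.approx(beta[1], abs=1e-9)
        resid = a - X @ beta
        r2 = 1 - resid @ resid / np.sum((a - a.mean()) ** 2)
        assert s["r_squared"] == pytest.approx(r2, abs=1e-9)
        diff = a - e
        assert s["bias"] == pytest.approx(diff.mean(), abs=1e-12)
        assert s["limits_of_agreement"][1] == pytest.approx(
            diff.mean() + 1.96 * diff.std(ddof=1), abs=1e-9)

    def test_zero_expert_variance_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_dice_contours_rasterizes_filled_regions():
    a = circle(20, (30, 30), n=90)
    assert dice_contours(a, a, (64, 64)) == 1.0
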