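import numpy as np
import pytest

from helpers_dp import brute_force_closed_path, random_dp_instance
from lvseg.epicardium import (CostMap, DPParams, EdgeFeature, SearchMask,
                              build_search_mask, dp_optimal_path, edge_feature,
                              epicardial_contour, polar_transform)
from lvseg.errors import SegmentationError
from lvseg.evaluation import dice
from lvseg.imaging_io import contour_to_mask


def annulus_image(shape=(101, 101), center=(50, 50), r_in=16, r_out=28,
                  pool=200.0, myo=60.0, bg=80.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    rad = np.hypot(rr - center[0], cc - center[1])
    img = np.full(shape, bg)
    img[rad <= r_out] = myo
    img[rad <= r_in] = pool
    return img, rad


class TestPolarTransform:
    def test_constant_image_gives_constant_map(self):
        p = polar_transform(np.full((50, 50), 7.0), (25, 25), 20, 21, 36)
        np.testing.assert_allclose(p.values, 7.0)

    def test_centered_disk_is_radial_step_per_column(self):
        img, _ = annulus_image(r_in=12, r_out=12)  # disk of 200 within 12
        img[img == 60.0] = 0.0
        img[img == 80.0] = 0.0
        p = polar_transform(img, (50, 50), 30, 31, 72)
        for j in range(72):
            col = p.values[:, j]
            inside = col > 100
            # step occurs at row ~ R / radial_step = 12
            assert abs(int(inside.sum()) - 13) <= 1

    def test_off_center_pixel_maps_to_predicted_cell(self):
        img = np.zeros((60, 60))
        img[35, 30] = 100.0  # 5 px below the pole -> theta = pi/2, r = 5
        p = polar_transform(img, (30, 30), 20, 21, 72)
        hot_rows, hot_cols = np.nonzero(p.values > 1.0)
        assert np.all(np.abs(hot_rows - 5) <= 1)
        theta_deg = hot_cols * 360.0 / 72
        assert np.all(np.abs(theta_deg - 90.0) <= 20.0)

    def test_pole_outside_roi_rejected(self):
        with pytest.raises(ValueError):
            polar_transform(np.zeros((40, 40)), (50, 20), 10, 11, 36)


class TestEdgeFeature:
    def test_radial_step_edge_single_row_per_column(self):
        img, _ = annulus_image()
        p = polar_transform(img, (50, 50), 40, 41, 90)
        F = edge_feature(p, smooth_sigma=0.0).F
        # strongest edge: pool -> myocardium at radius 16
        for j in range(90):
            nz = np.nonzero(F[:, j] > 0.5)[0]
            assert len(nz) == 1
            assert abs(nz[0] - 16) <= 1

    def test_constant_map_gives_zero_feature(self):
        p = polar_transform(np.full((50, 50), 3.0), (25, 25), 20, 21, 36)
        np.testing.assert_array_equal(edge_feature(p).F, 0.0)

    def test_linear_ramp_fully_suppressed(self):
        from lvseg.epicardium import PolarMap
        values = np.tile(np.arange(26.0)[:, None], (1, 72))  # linear in radius
        p = PolarMap(values, (0.0, 0.0), 25.0)
        F = edge_feature(p, smooth_sigma=0.0).F
        # constant gradient has no strict local maxima anywhere
        assert F.max() == 0.0

    def test_values_normalized_to_unit_interval(self):
        img, _ = annulus_image()
        p = polar_transform(img, (50, 50), 40, 41, 90)
        F = edge_feature(p).F
        assert F.min() >= 0.0 and F.max() == 1.0


class TestSearchMask:
    def test_rows_beyond_endo_radius(self):
        B = build_search_mask((30, 40), np.full(40, 10.0), margin=1).B
        assert not B[:11].any()
        assert B[11:].all()

    def test_bright_band_excluded(self):
        bright = np.zeros((30, 40), bool)
        bright[20:26, 0:10] = True
        B = build_search_mask((30, 40), np.full(40, 10.0), bright).B
        assert not B[20:26, 0:10].any()
        assert B[20:26, 10:].all()

    def test_previous_annulus_dilated_bound(self):
        prev = np.zeros((30, 40), bool)
        prev[12:19, :] = True  # annulus rows 12-18
        B = build_search_mask((30, 40), np.full(40, 5.0), None, prev,
                              margin=1, prev_dilation=2).B
        rows = np.nonzero(B.any(axis=1))[0]
        assert rows.min() >= 10 and rows.max() <= 20

    def test_blocked_column_reopened_near_endo(self):
        bright = np.ones((30, 40), bool)  # everything bright
        B = build_search_mask((30, 40), np.full(40, 10.0), bright).B
        assert B.any(axis=0).all()
        rows = np.nonzero(B[:, 0])[0]
        assert set(rows) <= {11, 12}


class TestDP:
    def test_perfect_ridge_is_followed_at_zero_cost(self):
        F = np.zeros((3, 4))
        F[2, :] = 1.0
        cm = dp_optimal_path(EdgeFeature(F), SearchMask(np.ones((3, 4), bool)),
                             DPParams(delta=1, w=1.0, gamma=0.0))
        np.testing.assert_array_equal(cm.path, [2, 2, 2, 2])
        assert cm.total_cost == 0.0

    def test_flat_feature_tie_breaks_to_smallest_admissible_row(self):
        F = np.full((5, 6), 0.25)
        B = np.ones((5, 6), bool)
        B[0, :] = False  # smallest admissible row is 1
        cm = dp_optimal_path(EdgeFeature(F), SearchMask(B),
                             DPParams(delta=1, w=1.0, gamma=0.5))
        np.testing.assert_array_equal(cm.path, np.full(6, 1))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            F, B, delta, gamma = random_dp_instance(rng)
            expected = brute_force_closed_path(F, B, delta, 1.0, gamma)
            if expected is None:
                with pytest.raises(SegmentationError):
                    dp_optimal_path(EdgeFeature(F), SearchMask(B),
                                    DPParams(delta, 1.0, gamma))
                continue
            cm = dp_optimal_path(EdgeFeature(F), SearchMask(B),
                                 DPParams(delta, 1.0, gamma))
            assert cm.total_cost == expected[1]
            np.testing.assert_array_equal(cm.path, expected[0])

    def test_cost_non_increasing_in_delta(self):
        rng = np.random.default_rng(5)
        F = rng.integers(0, 65, (8, 9)) / 64.0
        B = np.ones((8, 9), bool)
        costs = [dp_optimal_path(EdgeFeature(F), SearchMask(B),
                                 DPParams(d, 1.0, 0.5)).total_cost
                 for d in (1, 2, 3)]
        assert costs[0] >= costs[1] >= costs[2]

    def test_large_gamma_forces_exact_closure(self):
        rng = np.random.default_rng(11)
        F = rng.integers(0, 65, (7, 8)) / 64.0
        B = np.ones((7, 8), bool)
        cm = dp_optimal_path(EdgeFeature(F), SearchMask(B),
                             DPParams(2, 1.0, 1e9))
        assert cm.path[-1] == cm.path[0]

    def test_infeasible_mask_raises(self):
        F = np.zeros((4, 5))
        B = np.zeros((4, 5), bool)
        B[0, 0] = True  # no admissible cells beyond the first column
        with pytest.raises(SegmentationError, match="infeasible"):
            dp_optimal_path(EdgeFeature(F), SearchMask(B), DPParams(1, 1.0, 0.0))

    def test_path_respects_jump_and_closure_limits(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            F, B, delta, gamma = random_dp_instance(rng)
            try:
                cm = dp_optimal_path(EdgeFeature(F), SearchMask(B),
                                     DPParams(delta, 1.0, gamma))
            except SegmentationError:
                continue
            assert np.all(np.abs(np.diff(cm.path)) <= delta)
            assert abs(cm.path[-1] - cm.path[0]) <= delta


class TestEpicardialContour:
    def test_constant_path_maps_to_circle(self):
        img = np.zeros((81, 81))
        p = polar_transform(img, (40, 40), 30, 31, 90)
        cm = CostMap(C=np.zeros((31, 90)), predecessor=np.zeros((31, 90), int),
                     path=np.full(90, 20), start_row=20, total_cost=0.0)
        c = epicardial_contour(cm, p)
        d = np.hypot(c.points[:, 0] - 40, c.points[:, 1] - 40)
        assert np.max(np.abs(d - 20.0)) < 1.0

    def test_phantom_annulus_recovered(self):
        img, rad = annulus_image()
        p = polar_transform(img, (50, 50), 40, 41, 180)
        F = edge_feature(p)
        # search beyond the endocardial radius; no bright exclusions needed
        B = build_search_mask(F.F.shape, np.full(180, 16.0), margin=2)
        cm = dp_optimal_path(F, B, DPParams(2, 1.0, 0.1))
        c = epicardial_contour(cm, p)
        epi_mask = rad <= 28
        assert dice(contour_to_mask(c, img.shape), epi_mask) >= 0.95

    def test_round_trip_radii_within_one_row(self):
        img, rad = annulus_image()
        p = polar_transform(img, (50, 50), 40, 41, 180)
        F = edge_feature(p)
        B = build_search_mask(F.F.shape, np.full(180, 16.0), margin=2)
        cm = dp_optimal_path(F, B, DPParams(2, 1.0, 0.1))
        c = epicardial_contour(cm, p)
        d = np.hypot(c.points[:, 0] - 50, c.points[:, 1] - 50)
        rows = d / p.radial_step
        assert np.all(np.abs(rows - cm.path) <= 1.0)
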