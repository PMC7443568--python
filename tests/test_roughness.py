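"""Windowed polynomial-detrended roughness and R90 group statistics."""

import numpy as np
import pandas as pd
import pytest

from topofcs import (
    ReferencePoint,
    compare_groups,
    distance_groups,
    group_r90,
    holm_adjust,
    make_flat,
    roughness_map,
)


def seven_point_residual_rms(y):
    """Independent oracle: degree-5 LS fit to 7 points, RMS of residuals."""
    x = np.arange(-3.0, 4.0)
    coef = np.polyfit(x, y, 5)
    resid = y - np.polyval(coef, x)
    return np.sqrt(np.mean(resid**2))


class TestRoughnessMap:
    def test_zero_on_polynomial_surfaces(self):
        """Any surface polynomial of degree <= 5 along the fast axis detrends to nothing."""
        hmap = make_flat(32, 16, 125.0)
        x = np.arange(32.0)
        hmap.heights = (
            5.0 - 2.0 * x + 0.3 * x**2 - 0.01 * x**3 + 2e-4 * x**4 - 1e-6 * x**5
        )[None, :] * np.ones((16, 1))
        rough = roughness_map(hmap)
        assert np.all(np.abs(rough.values()) < 1e-6)

    def test_vertical_translation_invariance(self):
        rng = np.random.default_rng(2)
        hmap = make_flat(64, 16, 125.0)
        hmap.heights = rng.normal(size=(16, 64)) * 40.0
        shifted = hmap.copy()
        shifted.heights = shifted.heights + 5000.0
        np.testing.assert_allclose(
            roughness_map(hmap).roughness, roughness_map(shifted).roughness, atol=1e-8
        )

    def test_gaussian_noise_mean_square_is_sigma2_over_7(self):
        """7 points minus a 6-parameter fit leave one residual degree of freedom."""
        rng = np.random.default_rng(42)
        sigma = 10.0
        hmap = make_flat(2048, 40, 125.0)  # > 10^4 windows
        hmap.heights = rng.normal(0, sigma, size=(40, 2048))
        msq = np.mean(roughness_map(hmap).values() ** 2)
        assert abs(msq - sigma**2 / 7.0) / (sigma**2 / 7.0) < 0.05

    def test_step_edge_matches_seven_point_oracle(self):
        hmap = make_flat(32, 8, 125.0)
        hmap.heights[:, 16:] = 100.0  # step edge
        rough = roughness_map(hmap)
        for center in (14, 15, 16, 17):
            window = hmap.heights[0, center - 3 : center + 4]
            expected = seven_point_residual_rms(window)
            assert rough.roughness[0, center] == pytest.approx(expected, abs=1e-8)

    def test_line_scope_also_kills_degree5_shapes(self):
        hmap = make_flat(64, 8, 125.0)
        x = np.arange(64.0)
        hmap.heights = (0.5 * x**2 - 3 * x)[None, :] * np.ones((8, 1))
        rough = roughness_map(hmap, detrend_scope="line")
        assert np.all(np.abs(rough.values()) < 1e-6)

    def test_border_pixels_invalid(self):
        rough = roughness_map(make_flat(16, 8, 125.0))
        assert not rough.valid[:, :3].any() and not rough.valid[:, -3:].any()

    @pytest.mark.parametrize("window,degree", [(6, 5), (5, 5), (7, 6)])
    def test_bad_window_rejected(self, window, degree):
        with pytest.raises(ValueError):
            roughness_map(make_flat(32, 8, 125.0), window=window, detrend_degree=degree)


class TestDistanceGroups:
    def test_partition_and_boundary_groups(self):
        mask = np.ones((40, 60), bool)
        ref = ReferencePoint(10, 20)
        grouping = distance_groups(mask, ref, 125.0)
        inside = grouping.group_index[mask]
        assert inside.min() >= 1 and inside.max() == 10
        assert grouping.group_index[10, 20] == 1  # the reference pixel
        dist = np.hypot(*(np.indices(mask.shape) - np.array([[[10]], [[20]]])))
        far = np.unravel_index(np.argmax(dist), mask.shape)
        assert grouping.group_index[far] == 10  # the farthest pixel

    def test_disc_counts_match_annulus_areas(self):
        n = 301
        r, c = np.indices((n, n))
        center = n // 2
        radius = 140
        mask = np.hypot(r - center, c - center) <= radius
        grouping = distance_groups(mask, ReferencePoint(center, center), 125.0)
        counts = np.array([(grouping.group_index == k).sum() for k in range(1, 11)])
        # annulus areas: pi R^2 ((k/10)^2 - ((k-1)/10)^2)
        expected = np.pi * radius**2 * (np.arange(1, 11) ** 2 - np.arange(0, 10) ** 2) / 100.0
        np.testing.assert_allclose(counts, expected, rtol=0.03)

    def test_single_pixel_mask_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        with pytest.raises(ValueError, match="single pixel"):
            distance_groups(mask, ReferencePoint(3, 3), 125.0)


class TestGroupR90:
    @staticmethod
    def _uniform_roughness_map(values_by_group, grouping):
        from topofcs.roughness import RoughnessMap

        rough = np.zeros(grouping.group_index.shape)
        for k, v in values_by_group.items():
            rough[grouping.group_index == k] = v
        valid = grouping.group_index > 0
        return RoughnessMap(rough, valid, None)

    @pytest.fixture
    def grouping(self):
        mask = np.ones((50, 50), bool)
        return distance_groups(mask, ReferencePoint(25, 25), 125.0)

    def test_constant_group_gives_r90_equal_constant(self, grouping):
        rmap = self._uniform_roughness_map({k: float(k) for k in range(1, 11)}, grouping)
        r90 = group_r90(rmap, grouping)
        for k in range(1, 11):
            assert r90[k] == pytest.approx(float(k))

    def test_percentile_convention_linear_interpolation(self):
        # values 1..100: the 90th percentile interpolates to 90.1
        assert np.percentile(np.arange(1.0, 101.0), 90) == pytest.approx(90.1)
        from topofcs.roughness import RoughnessMap

        mask = np.ones((10, 10), bool)
        rough = np.arange(1.0, 101.0).reshape(10, 10)
        rmap = RoughnessMap(rough, mask, None)
        grouping = distance_groups(mask, ReferencePoint(0, 0), 125.0, n_groups=1)
        assert group_r90(rmap, grouping)[1] == pytest.approx(90.1)

    def test_all_invalid_group_missing(self, grouping):
        rmap = self._uniform_roughness_map({k: 1.0 for k in range(1, 11)}, grouping)
        rmap.valid[grouping.group_index == 4] = False
        r90 = group_r90(rmap, grouping)
        assert np.isnan(r90[4]) and not np.isnan(r90[5])

    def test_monotone_under_pointwise_increase(self, grouping, rng):
        from topofcs.roughness import RoughnessMap

        rough = rng.exponential(10.0, size=grouping.group_index.shape)
        valid = grouping.group_index > 0
        base = group_r90(RoughnessMap(rough, valid, None), grouping)
        more = group_r90(RoughnessMap(rough + rng.uniform(0, 5, rough.shape), valid, None), grouping)
        assert (more.values >= base.values).all()


def brute_force_holm(p):
    """Step-down Holm adjustment, literal implementation."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestCompareGroups:
    def test_holm_equals_brute_force(self, rng):
        p = rng.uniform(0, 1, size=9)
        np.testing.assert_allclose(holm_adjust(p), brute_force_holm(p), atol=1e-12)
        assert (holm_adjust(p) >= p - 1e-15).all()

    def test_degenerate_differences_non_significant(self):
        # identical groups (zero shift) and constant shifts both leave the
        # paired t statistic undefined; either way the report is p = 1
        same = pd.DataFrame({k: np.full(5, 10.0) for k in range(1, 11)})
        assert (compare_groups(same)["p_raw"] == 1.0).all()
        shifted = pd.DataFrame({k: np.full(5, 10.0 * k) for k in range(1, 11)})
        assert (compare_groups(shifted)["p_raw"] == 1.0).all()

    def test_planted_shift_in_groups_4_to_9_detected(self):
        """31 synthetic cells with a +0.3 log10 shift in groups 4-9: those groups
        come out Holm-significant, groups 2-3 do not."""
        rng = np.random.default_rng(2024)
        n_cells = 31
        base = rng.normal(1.0, 0.1, size=(n_cells, 10))
        logv = base.copy()
        logv[:, 3:9] += 0.3  # groups 4..9 (0-based cols 3..8)
        table = pd.DataFrame(10.0**logv, columns=range(1, 11))
        out = compare_groups(table)
        assert (out.loc[4:9, "p_holm"] < 0.05).all()
        assert (out.loc[2:3, "p_holm"] > 0.05).all()

    def test_non_positive_r90_rejected(self):
        table = pd.DataFrame({1: [1.0, 2.0], 2: [0.0, 3.0]})
        with pytest.raises(ValueError, match="positive"):
            compare_groups(table)

    def test_adjusted_never_below_raw(self, rng):
        table = pd.DataFrame(10.0 ** rng.normal(1, 0.2, size=(12, 10)), columns=range(1, 11))
        out = compare_groups(table)
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()
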