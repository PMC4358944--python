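"""Point-grid stereology and area fractions."""

import numpy as np
import pandas as pd
import pytest

from airwayquant.io import SectionLabelMap
from airwayquant.stereology import (
    area_fraction,
    classify_points,
    make_grid,
    stereology_result,
    subject_summaries,
    volume_fractions,
)


class TestMakeGrid:
    def test_systematic_grid_tiling_arithmetic(self):
        # 9x9 grid on a 900x900 image, centred: points at 50 + 100 i
        grid = make_grid((900, 900), 81, offset_mode="centered")
        expected = 50.0 + 100.0 * np.arange(9)
        assert np.allclose(sorted(set(grid.ys.tolist())), expected)
        assert np.allclose(sorted(set(grid.xs.tolist())), expected)
        assert grid.n_points == 81

    def test_single_point_is_the_image_center(self):
        grid = make_grid((100, 60), 1, offset_mode="centered")
        assert grid.ys[0] == 50.0 and grid.xs[0] == 30.0

    def test_random_offset_is_reproducible(self):
        g1 = make_grid((100, 100), 81, offset_mode="random", rng=42)
        g2 = make_grid((100, 100), 81, offset_mode="random", rng=42)
        assert np.array_equal(g1.ys, g2.ys) and np.array_equal(g1.xs, g2.xs)

    def test_random_offset_stays_inside_the_image(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            grid = make_grid((37, 53), 81, offset_mode="random", rng=rng)
            assert grid.ys.min() >= 0 and grid.ys.max() < 37
            assert grid.xs.min() >= 0 and grid.xs.max() < 53

    def test_non_square_count_rejected(self):
        with pytest.raises(ValueError, match="perfect square"):
            make_grid((100, 100), 80)

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_grid((5, 100), 81)


class TestClassifyPoints:
    def test_uniform_gland_map_counts_everything_as_gland(self):
        labelmap = SectionLabelMap(labels=np.full((90, 90), 2, dtype=np.uint8))
        counts = classify_points(make_grid((90, 90)), labelmap)
        assert counts[2] == 81

    def test_half_split_matches_pixel_lookup_oracle(self):
        labels = np.full((90, 90), 1, dtype=np.uint8)
        labels[:, :45] = 2  # left half gland
        labelmap = SectionLabelMap(labels=labels)
        grid = make_grid((90, 90))
        counts = classify_points(grid, labelmap)
        # oracle: classify all 81 points by direct pixel lookup
        expected = {c: 0 for c in labelmap.legend}
        for y, x in zip(grid.ys, grid.xs):
            expected[int(labels[int(np.floor(y)), int(np.floor(x))])] += 1
        assert counts == expected
        # column centres at x = 5, 15, ..., 85; those below 45 (4 columns) hit gland
        assert counts[2] == 36

    def test_counts_sum_to_n_points(self, rng):
        labels = rng.integers(0, 6, size=(64, 64)).astype(np.uint8)
        labelmap = SectionLabelMap(labels=labels)
        for mode in ("centered", "random"):
            counts = classify_points(make_grid((64, 64), 81, mode, rng=rng), labelmap)
            assert sum(counts.values()) == 81


class TestVolumeFractions:
    def test_worked_ratio_arithmetic(self):
        counts = {0: 0, 1: 81 - 27, 2: 27 - 9, 3: 9, 4: 0, 5: 0}
        g_vf, v_vf = volume_fractions(counts)
        assert g_vf == pytest.approx(1 / 3)
        assert v_vf == pytest.approx(1 / 3)

    def test_all_points_positive_gland(self):
        g_vf, v_vf = volume_fractions({3: 81})
        assert g_vf == 1.0 and v_vf == 1.0

    def test_zero_gland_points_reports_missing_not_zero(self):
        with pytest.warns(UserWarning, match="V_vf"):
            g_vf, v_vf = volume_fractions({1: 81})
        assert g_vf == 0.0
        assert v_vf is None

    def test_zero_tissue_points_reports_both_missing(self):
        with pytest.warns(UserWarning):
            g_vf, v_vf = volume_fractions({0: 81})
        assert g_vf is None and v_vf is None


class TestAreaFraction:
    def test_unit_conversion_to_mm2(self):
        labels = np.zeros((200, 200), dtype=np.uint8)
        labels.ravel()[:10_000] = 2  # 10^4 gland pixels at 1 um/pixel
        area, pct = area_fraction(SectionLabelMap(labels=labels, pixel_size=1.0))
        assert area == pytest.approx(0.01)
        assert pct == 0.0

    def test_fully_positive_gland_is_100_percent(self):
        labels = np.full((50, 50), 3, dtype=np.uint8)
        area, pct = area_fraction(SectionLabelMap(labels=labels, pixel_size=2.0))
        assert pct == 100.0
        assert area == pytest.approx(50 * 50 * 4 / 1e6)

    def test_empty_map_has_zero_area_and_missing_percent(self):
        with pytest.warns(UserWarning, match="gland"):
            area, pct = area_fraction(SectionLabelMap(labels=np.zeros((20, 20), np.uint8)))
        assert area == 0.0 and pct is None


class TestUnbiasedness:
    def test_random_offset_point_fraction_estimates_area_fraction(self, rng):
        """Mean point-count gland fraction over random offsets tracks the pixel fraction."""
        labels = np.full((128, 128), 1, dtype=np.uint8)
        blob = (
            (np.arange(128)[:, None] - 60) ** 2 + (np.arange(128)[None, :] - 70) ** 2
        ) < 40**2
        labels[blob] = 2
        labelmap = SectionLabelMap(labels=labels)
        exact = blob.mean()
        fractions = []
        for _ in range(2000):
            counts = classify_points(make_grid((128, 128), 81, "random", rng), labelmap)
            fractions.append(counts[2] / 81)
        assert abs(np.mean(fractions) - exact) < 0.01


class TestSubjectSummaries:
    def test_median_across_images(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s1"] * 3 + ["s2"],
                "group": ["HC"] * 4,
                "g_vf": [0.1, 0.3, 0.5, 0.2],
                "v_vf": [0.1, 0.3, 0.5, 0.2],
                "gland_area_mm2": [1.0, 1.0, 1.0, 2.0],
                "percent_gland_positive": [10.0, 30.0, 50.0, 20.0],
            }
        )
        out = subject_summaries(df)
        s1 = out[out.subject_id == "s1"].iloc[0]
        assert s1.g_vf == pytest.approx(0.3)
        assert s1.percent_gland_positive == pytest.approx(30.0)
        assert len(out) == 2

    def test_single_image_median_is_that_value(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s1"],
                "group": ["HC"],
                "g_vf": [0.42],
                "v_vf": [0.1],
                "gland_area_mm2": [0.5],
                "percent_gland_positive": [5.0],
            }
        )
        assert subject_summaries(df).iloc[0].g_vf == 0.42

    def test_order_invariance(self, rng):
        df = pd.DataFrame(
            {
                "subject_id": rng.permutation(["s1", "s2"] * 4),
                "group": ["HC"] * 8,
                "g_vf": rng.uniform(size=8),
                "v_vf": rng.uniform(size=8),
                "gland_area_mm2": rng.uniform(size=8),
                "percent_gland_positive": rng.uniform(size=8),
            }
        )
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(subject_summaries(df), subject_summaries(shuffled))


def test_stereology_result_uses_default_81_point_grid(rng):
    labels = rng.integers(1, 4, size=(96, 96)).astype(np.uint8)
    res = stereology_result(SectionLabelMap(labels=labels))
    assert res.p_tissue == 81
    assert res.p_positive <= res.p_gland <= res.p_tissue
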