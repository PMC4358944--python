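"""Pearson and Manders colocalization coefficients."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from airwayquant.colocalization import (
    ConstantChannelError,
    coloc_map,
    coloc_result,
    compare_groups_coloc,
    manders_coeffs,
    pearson_coloc,
)
from airwayquant.io import DualChannelStack

from _oracles import naive_manders, naive_pearson


def stack_from(green, red):
    g = np.asarray(green, dtype=np.uint8).reshape(1, 1, -1)
    r = np.asarray(red, dtype=np.uint8).reshape(1, 1, -1)
    return DualChannelStack(green=g, red=r)


class TestPearson:
    def test_identical_channels_give_one(self, rng):
        g = rng.integers(0, 256, size=(3, 5, 5), dtype=np.uint8)
        assert pearson_coloc(DualChannelStack(green=g, red=g.copy())) == pytest.approx(1.0)

    def test_inverted_channel_gives_minus_one(self, rng):
        g = rng.integers(0, 256, size=(3, 5, 5), dtype=np.uint8)
        assert pearson_coloc(DualChannelStack(green=g, red=255 - g)) == pytest.approx(-1.0)

    def test_orthogonal_pattern_gives_zero(self):
        # G = [0,0,1,1], R = [0,1,0,1]: covariance vanishes by hand computation
        assert pearson_coloc(stack_from([0, 0, 1, 1], [0, 1, 0, 1])) == pytest.approx(0.0)

    def test_constant_channel_raises_explicitly(self):
        with pytest.raises(ConstantChannelError):
            pearson_coloc(stack_from([5, 5, 5, 5], [0, 1, 2, 3]))

    @given(
        a=st.floats(0.1, 3.0),
        b=st.floats(0.0, 50.0),
    )
    def test_affine_rescaling_invariance(self, a, b):
        """R_p is unchanged by gain/offset (affine) changes to either channel."""
        rng = np.random.default_rng(7)
        g = rng.integers(0, 200, size=64).astype(float)
        r = rng.integers(0, 200, size=64).astype(float)
        base = naive_pearson(g, r)
        gd = g.reshape(1, 8, 8)
        rd = (a * r + b).reshape(1, 8, 8)
        stack = DualChannelStack.__new__(DualChannelStack)
        # bypass 8-bit validation: affine image may exceed 255 but R_p must not care
        stack.green, stack.red = gd, rd
        stack.voxel_size, stack.bit_depth = (0.3, 0.1, 0.1), 8
        assert pearson_coloc(stack) == pytest.approx(base, abs=1e-12)


class TestManders:
    def test_hand_worked_example(self):
        # G=[10,0,5], R=[0,0,7], thresholds 0 -> M_G = 5/15, M_R = 7/7
        m_g, m_r = manders_coeffs(stack_from([10, 0, 5], [0, 0, 7]), 0.0, 0.0)
        assert m_g == pytest.approx(5 / 15)
        assert m_r == pytest.approx(1.0)

    def test_full_overlap_gives_one(self):
        m_g, m_r = manders_coeffs(stack_from([9, 8, 0], [3, 4, 0]), 0.0, 0.0)
        assert m_g == 1.0 and m_r == 1.0

    def test_disjoint_supports_give_zero(self):
        m_g, m_r = manders_coeffs(stack_from([9, 8, 0, 0], [0, 0, 3, 4]), 0.0, 0.0)
        assert m_g == 0.0 and m_r == 0.0

    def test_zero_above_threshold_intensity_is_an_error(self):
        with pytest.raises(ValueError, match="zero total"):
            manders_coeffs(stack_from([1, 1, 1], [5, 5, 5]), 200.0, 0.0)

    def test_gain_invariance_with_coscaled_thresholds(self, small_stack):
        m = manders_coeffs(small_stack, 40.0, 60.0)
        scaled = DualChannelStack.__new__(DualChannelStack)
        scaled.green = small_stack.green.astype(float) * 3.0
        scaled.red = small_stack.red.astype(float) * 3.0
        scaled.voxel_size, scaled.bit_depth = small_stack.voxel_size, 8
        m_scaled = manders_coeffs(scaled, 120.0, 180.0)
        assert m_scaled == pytest.approx(m, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            g = rng.integers(0, 256, size=(2, 6, 6), dtype=np.uint8)
            r = rng.integers(0, 256, size=(2, 6, 6), dtype=np.uint8)
            m_g, m_r = manders_coeffs(
                DualChannelStack(green=g, red=r), float(rng.uniform(0, 200)), float(rng.uniform(0, 200))
            )
            assert 0.0 <= m_g <= 1.0 and 0.0 <= m_r <= 1.0


class TestOracleEquivalence:
    def test_coefficients_match_loop_reference(self, rng):
        """Vectorised R_p and Manders equal the naive reference to 1e-12."""
        for _ in range(25):
            shape = tuple(int(d) for d in rng.integers(2, 9, size=3))
            g = rng.integers(0, 256, size=shape, dtype=np.uint8)
            r = rng.integers(0, 256, size=shape, dtype=np.uint8)
            stack = DualChannelStack(green=g, red=r)
            thr_g, thr_r = float(rng.uniform(0, 150)), float(rng.uniform(0, 150))
            assert pearson_coloc(stack) == pytest.approx(
                naive_pearson(g.ravel(), r.ravel()), abs=1e-12
            )
            m = manders_coeffs(stack, thr_g, thr_r)
            expected = naive_manders(g.ravel(), r.ravel(), thr_g, thr_r)
            assert m == pytest.approx(expected, abs=1e-12)


class TestColocMap:
    def test_all_voxels_at_origin(self):
        stack = stack_from([0] * 8, [0] * 8)
        hist, quadrants = coloc_map(stack, 0, 0)
        assert hist[0, 0] == 8
        assert hist.sum() == 8
        assert quadrants["low_low"] == 8  # intensity 0 is not strictly above threshold 0

    def test_grand_total_is_voxel_count(self, small_stack):
        hist, quadrants = coloc_map(small_stack, 100, 100)
        assert hist.sum() == small_stack.n_voxels
        assert sum(quadrants.values()) == small_stack.n_voxels

    def test_equal_channels_put_all_mass_on_diagonal(self, rng):
        g = rng.integers(0, 256, size=(2, 4, 4), dtype=np.uint8)
        hist, _ = coloc_map(DualChannelStack(green=g, red=g.copy()))
        assert hist.sum() == np.trace(hist)


class TestGroupComparison:
    def test_single_subject_single_image(self):
        df = pd.DataFrame(
            {"subject_id": ["s1"], "group": ["HC"], "r_p": [0.5], "m_green": [0.6], "m_red": [0.7]}
        )
        subject, summary = compare_groups_coloc(df)
        row = summary[(summary.group == "HC") & (summary.measure == "r_p")].iloc[0]
        assert row["median"] == 0.5 and row.q1 == 0.5 and row.q3 == 0.5

    def test_subject_medians_before_group_medians(self):
        # subject s1 has images {0.1, 0.2, 0.3} -> median 0.2; s2 has {0.4}
        df = pd.DataFrame(
            {
                "subject_id": ["s1", "s1", "s1", "s2"],
                "group": ["HC"] * 4,
                "r_p": [0.1, 0.2, 0.3, 0.4],
                "m_green": [0.5] * 4,
                "m_red": [0.5] * 4,
            }
        )
        subject, summary = compare_groups_coloc(df)
        assert sorted(subject.r_p) == [0.2, 0.4]
        row = summary[(summary.group == "HC") & (summary.measure == "r_p")].iloc[0]
        assert row["median"] == pytest.approx(0.3)

    def test_quartiles_by_linear_interpolation(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "group": ["HC"] * 3,
                "r_p": [0.1, 0.2, 0.3],
                "m_green": [0.1, 0.2, 0.3],
                "m_red": [0.1, 0.2, 0.3],
            }
        )
        _, summary = compare_groups_coloc(df)
        row = summary[summary.measure == "r_p"].iloc[0]
        assert row["median"] == pytest.approx(0.2)
        assert row.q1 == pytest.approx(0.15)
        assert row.q3 == pytest.approx(0.25)

    def test_identical_groups_summarise_identically(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "group": ["HC", "HC", "COPD", "COPD"],
                "r_p": [0.1, 0.3, 0.1, 0.3],
                "m_green": [0.2, 0.4, 0.2, 0.4],
                "m_red": [0.2, 0.4, 0.2, 0.4],
            }
        )
        _, summary = compare_groups_coloc(df)
        hc = summary[summary.group == "HC"].drop(columns="group").reset_index(drop=True)
        copd = summary[summary.group == "COPD"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(hc, copd)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            compare_groups_coloc(
                pd.DataFrame(columns=["subject_id", "group", "r_p", "m_green", "m_red"])
            )


def test_coloc_result_bundles_consistent_sums(small_stack):
    res = coloc_result(small_stack, 50.0, 50.0)
    assert res.green_colocalized <= res.green_total
    assert res.red_colocalized <= res.red_total
    assert -1.0 <= res.r_p <= 1.0
    assert res.n_voxels == small_stack.n_voxels
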