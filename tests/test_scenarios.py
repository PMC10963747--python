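"""Scenario statistics against independently coded brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallowcast.scenarios import (
    crop_switching_savings,
    fallowing_savings,
    farming_practice_savings,
    run_scenarios,
)


# ---------------------------------------------------------------------------
# Brute-force oracles: plain loops, no shared code with the implementation
# ---------------------------------------------------------------------------

def oracle_crop_switching(et, crop, target="median"):
    crops = sorted(set(crop))
    crop_mean = {c: np.mean([e for e, cc in zip(et, crop) if cc == c]) for c in crops}
    if target == "median":
        M = float(np.median([crop_mean[c] for c in crops]))
    else:
        M = min(crop_mean.values())
    num = sum(min(crop_mean[cc], M) for cc in crop)
    return 1.0 - num / sum(et)


def oracle_farming_practice(et, crop, central="median"):
    crops = sorted(set(crop))
    stat = np.median if central == "median" else np.mean
    level = {c: stat([e for e, cc in zip(et, crop) if cc == c]) for c in crops}
    num = sum(min(e, level[cc]) for e, cc in zip(et, crop))
    return 1.0 - num / sum(et)


def oracle_fallowing(et, percentile=95.0):
    q = np.percentile(et, percentile)
    num = sum(e if e <= q else 0.0 for e in et)
    return 1.0 - num / sum(et)


def random_instance(rng):
    n = int(rng.integers(2, 500))
    n_crops = int(rng.integers(1, 7))
    crop = rng.integers(1, n_crops + 1, size=n)
    kind = rng.integers(0, 3)
    if kind == 0:
        et = rng.uniform(0, 900, size=n)
    elif kind == 1:
        et = rng.lognormal(5.5, 1.0, size=n)
    else:  # include negatives, as model error produces them
        et = rng.normal(400, 300, size=n)
        if et.sum() <= 0:
            et = np.abs(et)
    return et, crop


class TestWorkedExamples:
    def test_crop_switching_three_crop_case(self):
        # crops with means {9, 5, 1}; median 5 -> savings 1 - 11/15
        r = crop_switching_savings(np.array([9.0, 5.0, 1.0]), np.array([1, 2, 3]))
        assert np.isclose(r.savings, 4.0 / 15.0)

    def test_crop_switching_single_crop_is_zero(self):
        r = crop_switching_savings(np.array([3.0, 7.0]), np.array([1, 1]))
        assert np.isclose(r.savings, 0.0)

    def test_crop_switching_equal_means_is_zero(self):
        r = crop_switching_savings(
            np.array([4.0, 4.0, 4.0]), np.array([1, 2, 3])
        )
        assert np.isclose(r.savings, 0.0)

    def test_farming_practice_two_point_median(self):
        r = farming_practice_savings(np.array([2.0, 4.0]), np.array([1, 1]))
        assert np.isclose(r.savings, 1.0 / 6.0)

    def test_farming_practice_mean_variant(self):
        r = farming_practice_savings(
            np.array([0.0, 10.0]), np.array([1, 1]), central="mean"
        )
        assert np.isclose(r.savings, 0.5)

    def test_farming_practice_uniform_pixels_save_nothing(self):
        r = farming_practice_savings(np.full(10, 6.0), np.ones(10, dtype=int))
        assert np.isclose(r.savings, 0.0)

    def test_fallowing_one_to_hundred(self):
        r = fallowing_savings(np.arange(1.0, 101.0))
        assert np.isclose(r.savings, 490.0 / 5050.0)

    def test_fallowing_ties_and_singleton(self):
        assert np.isclose(fallowing_savings(np.full(20, 5.0)).savings, 0.0)
        assert np.isclose(fallowing_savings(np.array([42.0])).savings, 0.0)

    def test_minimum_crop_of_zero_saves_everything(self):
        r = crop_switching_savings(
            np.array([0.0, 0.0, 8.0]), np.array([1, 1, 2]), target="minimum"
        )
        assert np.isclose(r.savings, 1.0)

    def test_non_positive_baseline_is_undefined(self):
        r = fallowing_savings(np.array([-5.0, 2.0]))
        assert np.isnan(r.savings)


class TestOracleEquivalence:
    def test_all_four_statistics_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            et, crop = random_instance(rng)
            assert np.isclose(
                crop_switching_savings(et, crop).savings,
                oracle_crop_switching(et, crop),
                atol=1e-10,
            )
            assert np.isclose(
                crop_switching_savings(et, crop, target="minimum").savings,
                oracle_crop_switching(et, crop, target="minimum"),
                atol=1e-10,
            )
            for central in ("median", "mean"):
                assert np.isclose(
                    farming_practice_savings(et, crop, central=central).savings,
                    oracle_farming_practice(et, crop, central=central),
                    atol=1e-10,
                )
            assert np.isclose(
                fallowing_savings(et).savings, oracle_fallowing(et), atol=1e-10
            )


class TestInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_switching_to_minimum_saves_at_least_median_switch(self, seed):
        rng = np.random.default_rng(seed)
        et = rng.uniform(0, 500, size=int(rng.integers(2, 80)))
        crop = rng.integers(1, 5, size=len(et))
        med = crop_switching_savings(et, crop).savings
        mini = crop_switching_savings(et, crop, target="minimum").savings
        assert mini >= med - 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_fallowing_savings_non_increasing_in_percentile(self, seed):
        rng = np.random.default_rng(seed)
        et = rng.lognormal(5, 1, size=int(rng.integers(2, 80)))
        s = [fallowing_savings(et, percentile=p).savings for p in (80, 90, 95, 99)]
        assert all(a >= b - 1e-12 for a, b in zip(s, s[1:]))

    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_and_order_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        et = rng.uniform(1, 500, size=30)
        crop = rng.integers(1, 4, size=30)
        perm = rng.permutation(30)
        for fn in (
            lambda e, c: crop_switching_savings(e, c).savings,
            lambda e, c: farming_practice_savings(e, c).savings,
            lambda e, c: fallowing_savings(e).savings,
        ):
            base = fn(et, crop)
            assert np.isclose(fn(et * scale, crop), base, atol=1e-9)
            assert np.isclose(fn(et[perm], crop[perm]), base, atol=1e-9)

    def test_savings_fraction_bounds_for_nonnegative_inputs(self, rng):
        for _ in range(50):
            et = rng.uniform(0, 600, size=50)
            crop = rng.integers(1, 5, size=50)
            for s in (
                crop_switching_savings(et, crop).savings,
                farming_practice_savings(et, crop).savings,
                fallowing_savings(et).savings,
            ):
                assert -1e-12 <= s <= 1.0 + 1e-12

    def test_heavy_tail_fallowing_removes_more_than_five_percent(self, rng):
        et = rng.lognormal(5.0, 1.2, size=5000)
        assert fallowing_savings(et).savings > 0.05


class TestRunScenarios:
    def _annual(self, rng, n_basins=4, n=120):
        return pd.DataFrame(
            {
                "pixel_id": np.arange(n),
                "year": 2019,
                "sub_basin": rng.integers(0, n_basins, n),
                "land_cover": rng.integers(1, 5, n),
                "et_ag_ctrl_mm": rng.uniform(1, 800, n),
            }
        )

    def test_homogeneous_sub_basins_aggregate_to_common_value(self):
        # identical pixel sets in each sub-basin -> identical savings
        base = pd.DataFrame(
            {
                "pixel_id": np.arange(6),
                "year": 2019,
                "land_cover": [1, 1, 2, 2, 3, 3],
                "et_ag_ctrl_mm": [9.0, 9.0, 5.0, 5.0, 1.0, 1.0],
            }
        )
        both = pd.concat(
            [base.assign(sub_basin=0), base.assign(sub_basin=1)], ignore_index=True
        )
        table, agg = run_scenarios(both)
        cs = table[table["scenario"] == "crop_switching"]
        assert np.allclose(cs["savings"], cs["savings"].iloc[0])
        agg_cs = agg.loc[agg["scenario"] == "crop_switching"].iloc[0]
        assert np.isclose(agg_cs["savings_et_weighted"], cs["savings"].iloc[0])

    def test_aggregate_is_et_weighted_pooled_numerator(self, rng):
        for _ in range(20):
            annual = self._annual(rng)
            table, agg = run_scenarios(annual)
            for scenario in table["scenario"].unique():
                sub = table[table["scenario"] == scenario]
                num = ((1 - sub["savings"]) * sub["baseline_sum"]).sum()
                expected = 1 - num / sub["baseline_sum"].sum()
                got = agg.loc[agg["scenario"] == scenario, "savings_et_weighted"].iloc[0]
                assert np.isclose(got, expected, atol=1e-10)

    def test_multi_year_input_rejected(self, rng):
        annual = self._annual(rng)
        annual.loc[0, "year"] = 2016
        with pytest.raises(ValueError, match="single year"):
            run_scenarios(annual)

    def test_undefined_sub_basin_excluded_and_counted(self):
        annual = pd.DataFrame(
            {
                "pixel_id": [0, 1, 2],
                "year": 2019,
                "sub_basin": [0, 0, 1],
                "land_cover": [1, 2, 1],
                "et_ag_ctrl_mm": [10.0, 20.0, -5.0],  # basin 1 sums negative
            }
        )
        table, agg = run_scenarios(annual)
        row = agg[agg["scenario"] == "fallowing"].iloc[0]
        assert row["n_undefined"] == 1
        assert row["n_sub_basins"] == 1
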