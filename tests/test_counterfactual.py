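import numpy as np
import pandas as pd
import pytest

from fallowcast import RunConfig
from fallowcast.counterfactual import (
    FEATURES,
    CounterfactualModel,
    allocate_blocks,
    apply_split,
    assemble_training_table,
    block_split,
    clean_fallow_outliers,
    fit_counterfactual,
    validate_annual,
)
from fallowcast.io_geo import FALLOW
from tests.conftest import small_search_space


def _pixel_months(n_pixels=10, fallow=True, years=(2016,), et=10.0):
    rows = []
    for p in range(n_pixels):
        for year in years:
            for m in range(1, 13):
                rows.append(
                    {
                        "pixel_id": p,
                        "x": 35.0 + 70.0 * p,
                        "y": 35.0,
                        "month": m,
                        "year": year,
                        "et_mm": et if np.isscalar(et) else et[p],
                        "land_cover": FALLOW if fallow else 3,
                        "elevation": 100.0,
                        "aspect": 180.0,
                        "slope": 2.0,
                        "twi": 7.0,
                        "soil_quality": 60.0,
                        "pet_mm": 50.0,
                    }
                )
    return pd.DataFrame(rows)


class TestAssembleTrainingTable:
    def test_no_fallow_rows_is_an_error(self):
        with pytest.raises(ValueError, match="fallow"):
            assemble_training_table(_pixel_months(fallow=False))

    def test_only_fallow_rows_survive(self):
        df = pd.concat(
            [_pixel_months(5, fallow=True), _pixel_months(45, fallow=False)],
            ignore_index=True,
        )
        out = assemble_training_table(df)
        assert len(out) == 5 * 12

    def test_missing_feature_rows_dropped(self):
        df = _pixel_months(1)
        df.loc[0, "twi"] = np.nan
        out = assemble_training_table(df)
        assert len(out) == 11


class TestCleanFallowOutliers:
    def _table_with_summer_sums(self, sums):
        """One pixel-year per sum; July-September split the sum evenly."""
        rows = []
        for p, s in enumerate(sums):
            for m in range(1, 13):
                rows.append(
                    {
                        "pixel_id": p,
                        "year": 2016,
                        "month": m,
                        "et_mm": s / 3.0 if m in (7, 8, 9) else 1.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_exactly_top_five_of_hundred_removed(self):
        table = self._table_with_summer_sums(np.arange(1.0, 101.0))
        cleaned, report = clean_fallow_outliers(table)
        removed = set(range(100)) - set(cleaned["pixel_id"])
        assert removed == {95, 96, 97, 98, 99}  # sums 96..100
        assert report["n_removed"] == 5

    def test_all_ties_remove_nothing(self):
        table = self._table_with_summer_sums(np.full(50, 42.0))
        cleaned, report = clean_fallow_outliers(table)
        assert len(cleaned) == len(table)
        assert report["n_removed"] == 0

    def test_single_pixel_year_kept(self):
        table = self._table_with_summer_sums([10.0])
        cleaned, report = clean_fallow_outliers(table)
        assert len(cleaned) == 12 and report["n_removed"] == 0

    def test_incomplete_summer_is_exempt(self):
        table = self._table_with_summer_sums(np.arange(1.0, 21.0))
        table = table[~((table.pixel_id == 0) & (table.month == 8))]
        cleaned, report = clean_fallow_outliers(table)
        assert report["n_exempt"] == 1
        assert 0 in set(cleaned["pixel_id"])

    def test_removal_bounded_by_five_percent_plus_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            table = self._table_with_summer_sums(rng.normal(50, 10, size=n))
            _, report = clean_fallow_outliers(table)
            assert report["n_removed"] <= int(np.ceil(0.05 * n))


class TestBlockSplit:
    def test_paper_scale_block_counts_are_exact(self):
        assignment = allocate_blocks(np.arange(8180), (0.6, 0.1, 0.3), seed=0)
        counts = assignment.value_counts()
        assert counts["train"] == 4908
        assert counts["validation"] == 818
        assert counts["test"] == 2454

    def test_nearby_pixels_share_a_partition(self):
        df = _pixel_months(150)  # 70 m spacing spans several 2 km blocks
        for seed in range(20):
            split = block_split(df, block_m=2000.0, seed=seed)
            out = apply_split(df, split)
            near = out[out["pixel_id"].isin([0, 1])]  # 70 m apart
            assert near["partition"].nunique() == 1

    def test_too_few_blocks_rejected(self):
        df = _pixel_months(2)  # both pixels fall in one 2 km block
        with pytest.raises(ValueError, match="blocks"):
            block_split(df, block_m=2000.0, seed=0)

    def test_partitions_are_block_disjoint(self, small_pixels):
        table = assemble_training_table(small_pixels)
        for seed in (0, 1, 2):
            split = block_split(table, block_m=500.0, seed=seed)
            out = apply_split(table, split)
            per_block = out.groupby("block")["partition"].nunique()
            assert (per_block == 1).all()

    def test_realized_fractions_recorded(self, small_pixels):
        table = assemble_training_table(small_pixels)
        split = block_split(table, block_m=500.0, seed=1)
        assert np.isclose(sum(split.fractions.values()), 1.0)


def _recovery_config(**kw):
    base = dict(
        n_rows=60,
        n_cols=60,
        fallow_fraction=0.25,
        noise_sd_mm=0.0,
        n_search_candidates=2,
        search_subsample=4000,
        search_space=small_search_space(),
        seed=3,
    )
    base.update(kw)
    return RunConfig(**base)


class TestFitCounterfactual:
    def _training_frame(self, target_fn, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "pixel_id": np.arange(n),
                "x": rng.uniform(0, 10000, n),
                "y": rng.uniform(0, 10000, n),
                "month": rng.integers(1, 13, n),
                "year": rng.choice([2016, 2018, 2019], n),
                "elevation": rng.uniform(0, 500, n),
                "aspect": rng.uniform(0, 360, n),
                "slope": rng.uniform(0, 15, n),
                "twi": rng.uniform(2, 12, n),
                "soil_quality": rng.uniform(20, 100, n),
                "pet_mm": rng.uniform(5, 115, n),
            }
        )
        df["et_mm"] = target_fn(df)
        return df

    def test_constant_target_predicted_everywhere(self):
        df = self._training_frame(lambda d: np.full(len(d), 42.0))
        model = fit_counterfactual(df, None, _recovery_config())
        pred = model.predict(df)
        np.testing.assert_allclose(pred, 42.0, atol=0.5)

    def test_known_function_of_pet_recovered(self):
        df = self._training_frame(lambda d: d["pet_mm"] / 2.0)
        model = fit_counterfactual(df, None, _recovery_config())
        probe = df.iloc[:200].copy()
        probe["pet_mm"] = 100.0
        pred = model.predict(probe)
        np.testing.assert_allclose(pred, 50.0, atol=2.5)

    def test_same_seed_gives_identical_hyperparameters(self):
        df = self._training_frame(lambda d: d["pet_mm"] / 2.0)
        cfg = _recovery_config(n_search_candidates=4)
        m1 = fit_counterfactual(df, None, cfg, seed=9)
        m2 = fit_counterfactual(df, None, cfg, seed=9)
        assert m1.params == m2.params
        np.testing.assert_array_equal(m1.predict(df), m2.predict(df))

    def test_empty_search_space_rejected(self):
        df = self._training_frame(lambda d: d["pet_mm"])
        with pytest.raises(ValueError, match="search space"):
            fit_counterfactual(df, None, _recovery_config(search_space={}))

    def test_min_samples_scale_with_training_size(self):
        df = self._training_frame(lambda d: d["pet_mm"], n=1000)
        cfg = _recovery_config(reference_train_size=2000)
        model = fit_counterfactual(df, None, cfg)
        assert model.min_samples_split == 100  # 200 * (1000/2000)
        assert model.min_samples_leaf == 50


class TestPredictNaturalEt:
    def test_negative_raw_output_clipped_to_zero(self):
        class NegativeStub:
            def predict(self, X):
                return np.full(len(X), -3.0)

        model = CounterfactualModel(
            NegativeStub(), list(FEATURES), {}, "hist", 0, 10, 2, 1
        )
        df = _pixel_months(3)
        assert (model.predict(df) == 0.0).all()

    def test_missing_feature_is_named(self):
        class Stub:
            def predict(self, X):
                return np.zeros(len(X))

        model = CounterfactualModel(Stub(), list(FEATURES), {}, "hist", 0, 10, 2, 1)
        df = _pixel_months(2).drop(columns=["twi"])
        with pytest.raises(ValueError, match="twi"):
            model.predict(df)


class _ColumnStub:
    """Predicts the pet_mm feature verbatim — lets tests set predictions."""

    def predict(self, X):
        return X[:, FEATURES.index("pet_mm")]


def _stub_model():
    return CounterfactualModel(_ColumnStub(), list(FEATURES), {}, "hist", 0, 1, 2, 1)


class TestValidateAnnual:
    def _frame(self, obs_annual, pred_annual):
        frames = []
        for p, (o, pr) in enumerate(zip(obs_annual, pred_annual)):
            f = _pixel_months(1, et=[o / 12.0])
            f["pixel_id"] = p
            f["x"] = 35.0 + 3000.0 * p  # separate blocks
            f["pet_mm"] = pr / 12.0
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_perfect_predictions_score_one(self):
        df = self._frame([120.0, 240.0, 360.0], [120.0, 240.0, 360.0])
        rep = validate_annual(_stub_model(), df)
        assert np.isclose(rep.r2, 1.0) and np.isclose(rep.mae_mm, 0.0)

    def test_mean_prediction_scores_zero(self):
        df = self._frame([120.0, 240.0, 360.0], [240.0, 240.0, 240.0])
        rep = validate_annual(_stub_model(), df)
        assert np.isclose(rep.r2, 0.0)

    def test_hand_computed_case(self):
        # obs {100, 200, 300}, pred {110, 190, 310}: MAE 10,
        # R2 = 1 - 300/20000 = 0.985
        df = self._frame([100.0, 200.0, 300.0], [110.0, 190.0, 310.0])
        rep = validate_annual(_stub_model(), df)
        assert np.isclose(rep.mae_mm, 10.0)
        assert np.isclose(rep.r2, 1.0 - 300.0 / 20000.0)

    def test_incomplete_pixel_years_excluded(self):
        df = self._frame([120.0, 240.0, 360.0], [120.0, 240.0, 360.0])
        df = df[~((df.pixel_id == 0) & (df.month == 5))]
        rep = validate_annual(_stub_model(), df)
        assert rep.n_excluded == 1 and rep.n_pixel_years == 2
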