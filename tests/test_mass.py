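"""Ensemble mass model: splitting, bagging bookkeeping, prediction, baseline."""

import numpy as np
import pandas as pd
import pytest

from ichnostats import synthetic
from ichnostats.mass import (
    evaluate,
    fit_length_regression,
    fit_mass_model,
    predict_mass,
    predict_trackway_mass,
    split_train_test,
)
from ichnostats.schema import MEASUREMENT_COLUMNS
from ichnostats.synthetic import PopulationConfig


def make_table(n, masses=None, seed=0):
    rng = np.random.default_rng(seed)
    masses = rng.uniform(20, 70, n) if masses is None else np.asarray(masses, float)
    df = pd.DataFrame(
        {c: rng.uniform(5, 30, n) for c in MEASUREMENT_COLUMNS}
    )
    df["body_mass_kg"] = masses
    df["subject_or_trackway_id"] = [f"s{i}" for i in range(n)]
    return df


class TestSplitTrainTest:
    def test_row_wise_490_gives_343_147(self, reference_table):
        table = reference_table.head(490) if len(reference_table) >= 490 else None
        if table is None:  # default draw gave < 490 prints; synthesise exactly 490
            table = make_table(490)
        split = split_train_test(table, seed=1, group_by_subject=False)
        assert len(split["train"]) == 343
        assert len(split["test"]) == 147

    def test_partition_disjoint_and_exhaustive(self, reference_table):
        split = split_train_test(reference_table, seed=2, group_by_subject=False)
        ids = pd.concat([split["train"], split["test"]])["footprint_id"]
        assert sorted(ids) == sorted(reference_table["footprint_id"])
        assert set(split["train"].footprint_id).isdisjoint(split["test"].footprint_id)

    def test_subject_wise_split_keeps_subjects_together(self, reference_table):
        split = split_train_test(reference_table, seed=3, group_by_subject=True)
        overlap = set(split["train"]["subject_or_trackway_id"]) & set(
            split["test"]["subject_or_trackway_id"]
        )
        assert overlap == set()

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(make_table(20), fraction=1.0)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(make_table(5))

    def test_same_seed_same_partition(self):
        table = make_table(50)
        a = split_train_test(table, seed=9, group_by_subject=False)
        b = split_train_test(table, seed=9, group_by_subject=False)
        pd.testing.assert_frame_equal(a["train"], b["train"])


class TestFitMassModel:
    def test_inbag_oob_partition_per_tree(self):
        table = make_table(60)
        model = fit_mass_model(table, n_trees=25, bootstrap_seed=4)
        for inbag, oob in zip(model.inbag_indices, model.oob_indices):
            assert len(inbag) > 0
            assert np.intersect1d(inbag, oob).size == 0
            assert len(inbag) + len(oob) == model.n_train

    def test_mean_inbag_unique_matches_bootstrap_theory(self):
        # n * (1 - (1 - 1/n)^n): 217.0 of 343
        table = make_table(343)
        model = fit_mass_model(table, n_trees=500, bootstrap_seed=5)
        expected = 343 * (1 - (1 - 1 / 343) ** 343)
        assert expected == pytest.approx(217.0, abs=0.5)
        assert abs(model.mean_inbag_unique() - 217.0) <= 3.0

    def test_constant_mass_predicts_constant(self):
        table = make_table(40, masses=np.full(40, 55.0))
        model = fit_mass_model(table, n_trees=20, bootstrap_seed=6)
        assert model.rmse_oob == pytest.approx(0.0, abs=1e-12)
        assert predict_mass(model, table.iloc[[0]])[0] == pytest.approx(55.0)

    def test_constant_predictors_rejected(self):
        table = make_table(30)
        for c in MEASUREMENT_COLUMNS:
            table[c] = 7.0
        with pytest.raises(ValueError, match="uninformative"):
            fit_mass_model(table, n_trees=5)

    def test_oob_rmse_improves_with_ensemble_size(self):
        """Averaged over seeds, 500 trees beat a single tree out-of-bag."""
        wins = 0
        for seed in range(20):
            cfg = PopulationConfig(
                n_male=8, n_female=8, n_juvenile=4,
                prints_per_subject=(4, 6), seed=seed,
            )
            df = synthetic.generate_footprints(synthetic.generate_population(cfg), cfg)
            small = fit_mass_model(df, n_trees=1, bootstrap_seed=seed)
            big = fit_mass_model(df, n_trees=500, bootstrap_seed=seed)
            wins += big.rmse_oob <= small.rmse_oob
        assert wins >= 15


class TestPredictMass:
    def test_single_tree_memorizes_training_point(self):
        table = make_table(30)
        model = fit_mass_model(
            table, n_trees=1, bootstrap_seed=8, min_samples_leaf=1, max_features=5
        )
        # pick a point that was in-bag for the single tree
        idx = model.inbag_indices[0][0]
        pred = predict_mass(model, table.iloc[[idx]])[0]
        assert pred == pytest.approx(table["body_mass_kg"].iloc[idx])

    def test_prediction_bounded_by_training_range(self):
        table = make_table(80)
        model = fit_mass_model(table, n_trees=50, bootstrap_seed=9)
        lo, hi = model.training_response_range
        extreme = pd.DataFrame(
            [dict(zip(MEASUREMENT_COLUMNS, [1e6] * 5)),
             dict(zip(MEASUREMENT_COLUMNS, [1e-6] * 5))]
        )
        preds = predict_mass(model, extreme)
        assert np.all(preds >= lo) and np.all(preds <= hi)

    def test_rank_order_preserved_on_monotone_data(self):
        # mass strictly increasing in length, no noise
        n = 200
        lengths = np.linspace(18, 30, n)
        df = pd.DataFrame({c: np.ones(n) for c in MEASUREMENT_COLUMNS})
        df["heel_to_hallux_length_cm"] = lengths
        df["body_mass_kg"] = 2.5 * lengths - 10
        df["subject_or_trackway_id"] = [f"s{i}" for i in range(n)]
        model = fit_mass_model(df, n_trees=100, bootstrap_seed=10, max_features=5)
        test_lengths = np.linspace(19, 29, 25)
        test = pd.DataFrame({c: np.ones(25) for c in MEASUREMENT_COLUMNS})
        test["heel_to_hallux_length_cm"] = test_lengths
        preds = predict_mass(model, test)
        assert np.all(np.diff(preds) >= 0)

    def test_noiseless_rmse_shrinks_with_n(self):
        """Parameter recovery: test RMSE falls toward 0 as training size grows."""
        rmses = {}
        for n in (100, 1000):
            cfg = PopulationConfig(
                n_male=n // 10, n_female=n // 10, n_juvenile=0,
                prints_per_subject=(5, 5), dimension_noise_cv=0.0,
                depth_noise_sd=0.0, substrate_levels=(("moist", 1.0),),
                gait_mix=1.0, seed=n,
            )
            df = synthetic.generate_footprints(synthetic.generate_population(cfg), cfg)
            split = split_train_test(df, seed=n, group_by_subject=True)
            model = fit_mass_model(split["train"], n_trees=200, bootstrap_seed=n)
            y = split["test"]["body_mass_kg"].to_numpy()
            preds = predict_mass(model, split["test"])
            rmses[n] = float(np.sqrt(np.mean((y - preds) ** 2)))
        assert rmses[1000] < rmses[100]
        assert rmses[1000] < 1.0


class TestTrackwayPrediction:
    def test_single_print_trackway_equals_print_prediction(self):
        table = make_table(40)
        model = fit_mass_model(table, n_trees=30, bootstrap_seed=11)
        one = table.iloc[[5]]
        assert predict_trackway_mass(model, one) == pytest.approx(
            predict_mass(model, one)[0]
        )

    def test_identical_prints_equal_single_print(self):
        table = make_table(40)
        model = fit_mass_model(table, n_trees=30, bootstrap_seed=12)
        row = table.iloc[[7]]
        repeated = pd.concat([row] * 5, ignore_index=True)
        assert predict_trackway_mass(model, repeated) == pytest.approx(
            predict_mass(model, row)[0]
        )

    def test_scenario_population_mean_recovered(self, reference_table):
        """Trackway predictions recover the generating population mean mass."""
        split = split_train_test(reference_table, seed=13, group_by_subject=True)
        model = fit_mass_model(split["train"], n_trees=300, bootstrap_seed=13)
        scenario = synthetic.generate_fossil_scenario(
            synthetic.FossilScenarioConfig(
                n_trackways=23, prints_per_trackway=8, seed=13
            )
        )
        preds = [
            predict_trackway_mass(model, g)
            for _, g in scenario["trackways"].groupby("subject_or_trackway_id")
        ]
        truth_mean = scenario["truth"]["body_mass_kg"].mean()
        assert abs(np.mean(preds) - truth_mean) < 2.0


class TestLengthRegression:
    def test_exact_linear_data(self):
        n = 30
        lengths = np.linspace(20, 30, n)
        df = make_table(n, masses=2.0 * lengths + 1.0)
        df["heel_to_hallux_length_cm"] = lengths
        df["body_mass_kg"] = 2.0 * lengths + 1.0
        lin = fit_length_regression(df)
        assert lin.slope == pytest.approx(2.0, abs=1e-10)
        assert lin.intercept == pytest.approx(1.0, abs=1e-8)

    def test_two_points_warns(self):
        df = make_table(2, masses=[40, 60])
        df["heel_to_hallux_length_cm"] = [20.0, 25.0]
        with pytest.warns(UserWarning, match="2 points"):
            lin = fit_length_regression(df)
        np.testing.assert_allclose(lin.predict([20.0, 25.0]), [40, 60])

    def test_constant_length_rejected(self):
        df = make_table(10)
        df["heel_to_hallux_length_cm"] = 22.0
        with pytest.raises(ValueError, match="constant"):
            fit_length_regression(df)


class TestEvaluate:
    def test_perfect_predictions_zero_rmse(self):
        n = 50
        lengths = np.linspace(20, 30, n)
        df = make_table(n)
        df["heel_to_hallux_length_cm"] = lengths
        df["body_mass_kg"] = 3.0 * lengths
        lin = fit_length_regression(df)
        model = fit_mass_model(df, n_trees=10, bootstrap_seed=14)
        ev = evaluate(model, lin, df.iloc[:0 + 1])
        assert ev.rmse_linear_test == pytest.approx(0.0, abs=1e-9)

    def test_single_point_rmse_is_abs_error(self):
        df = make_table(30, masses=np.full(30, 50.0))
        model = fit_mass_model(df, n_trees=10, bootstrap_seed=15)
        lin = fit_length_regression(make_table(30, seed=3))
        test = df.iloc[[0]].copy()
        test["body_mass_kg"] = 53.0  # ensemble predicts 50 -> error 3
        ev = evaluate(model, lin, test)
        assert ev.rmse_test == pytest.approx(3.0, abs=1e-9)

    def test_empty_test_set_rejected(self):
        df = make_table(30)
        model = fit_mass_model(df, n_trees=5, bootstrap_seed=16)
        lin = fit_length_regression(df)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, lin, df.iloc[:0])

    def test_ensemble_beats_curved_linear_fit(self):
        """Allometric (curved) mass-length data favours the ensemble."""
        cfg = PopulationConfig(seed=77)
        df = synthetic.generate_footprints(synthetic.generate_population(cfg), cfg)
        split = split_train_test(df, seed=77, group_by_subject=False)
        model = fit_mass_model(split["train"], n_trees=300, bootstrap_seed=77)
        lin = fit_length_regression(split["train"])
        ev = evaluate(model, lin, split["test"])
        assert ev.rmse_test < ev.rmse_linear_test

    def test_matches_independent_forest_implementation(self, reference_table):
        """Cross-check: accuracy is on par with sklearn's own random forest."""
        from sklearn.ensemble import RandomForestRegressor

        split = split_train_test(reference_table, seed=21, group_by_subject=False)
        model = fit_mass_model(split["train"], n_trees=300, bootstrap_seed=21)
        lin = fit_length_regression(split["train"])
        ev = evaluate(model, lin, split["test"])
        rf = RandomForestRegressor(
            n_estimators=300, max_features=2, min_samples_leaf=5, random_state=21
        )
        rf.fit(
            split["train"][list(MEASUREMENT_COLUMNS)],
            split["train"]["body_mass_kg"],
        )
        y = split["test"]["body_mass_kg"].to_numpy()
        rf_rmse = float(
            np.sqrt(np.mean((y - rf.predict(split["test"][list(MEASUREMENT_COLUMNS)])) ** 2))
        )
        assert ev.rmse_test == pytest.approx(rf_rmse, rel=0.25)
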