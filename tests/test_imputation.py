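import numpy as np
import pandas as pd
import pytest

from missbench.imputation import (
    CHAINED_METHODS,
    SIMPLE_METHODS,
    ImputationError,
    ImputerSpec,
    InsufficientCompleteCases,
    apply,
    bpca_impute,
    chained_impute,
    fit,
    indicator_pattern_columns,
    iterative_rf_impute,
    method_grid,
    record_runtime,
    sample_grid,
)

from conftest import random_incomplete_frame

NA = np.nan


def frame(data):
    df = pd.DataFrame(data, dtype=float)
    df.index = [f"v{i}" for i in range(len(df))]
    return df


ORACLE_FILLS = {
    "zero": lambda obs: 0.0,
    "mean": lambda obs: np.mean(obs),
    "median": lambda obs: np.median(obs),
    "minimum": lambda obs: np.min(obs),
    "maximum": lambda obs: np.max(obs),
    "outlier": lambda obs: abs(np.max(obs) - np.min(obs)) * 10.0,
}


class TestSimpleMethods:
    @pytest.mark.parametrize("method", SIMPLE_METHODS)
    def test_fills_match_bruteforce_oracle(self, method, rng):
        df = random_incomplete_frame(rng)
        fitted = fit(ImputerSpec(method), df)
        completed = apply(fitted, df).tables[0]
        for col in df.columns:
            obs = df[col].dropna().to_numpy()
            expected = ORACLE_FILLS[method](obs)
            missing = df[col].isna()
            assert (completed.loc[missing, col] == expected).all()
            pd.testing.assert_series_equal(completed.loc[~missing, col], df.loc[~missing, col])

    def test_mean_example(self):
        df = frame({"a": [1.0, 2.0, NA, 3.0], "b": [0.0, 0.0, 0.0, 1.0]})
        fitted = fit(ImputerSpec("mean"), df)
        assert fitted.fill_values["a"] == pytest.approx(2.0)

    def test_outlier_formula_and_constant_degeneracy(self):
        df = frame({"a": [-2.0, 3.0, NA], "b": [5.0, 5.0, NA]})
        fitted = fit(ImputerSpec("outlier"), df)
        assert fitted.fill_values["a"] == pytest.approx(50.0)
        assert fitted.fill_values["b"] == 0.0  # constant feature degenerates to 0

    def test_zero_observed_feature_rejected_by_name(self):
        df = frame({"a": [1.0, 2.0], "empty": [NA, NA]})
        with pytest.raises(ImputationError, match="empty"):
            fit(ImputerSpec("mean"), df)


class TestIndicatorAugmentation:
    def test_identical_masks_deduplicate(self):
        df = frame({"a": [NA, 1.0, NA], "b": [NA, 2.0, NA], "c": [1.0, NA, 2.0]})
        kept = indicator_pattern_columns(df)
        assert kept == ["a", "c"]  # b shares a's pattern; first-named kept

    def test_never_missing_feature_gets_no_indicator(self):
        df = frame({"a": [1.0, 2.0], "b": [NA, 1.0]})
        assert indicator_pattern_columns(df) == ["b"]

    def test_pattern_enumeration_on_three_features(self):
        df = frame({"a": [NA, 1.0], "b": [NA, 1.0], "c": [1.0, NA]})
        assert len(indicator_pattern_columns(df)) == 2

    def test_apply_zero_fills_and_appends_indicators(self):
        df = frame({"a": [NA, 1.0], "b": [2.0, NA]})
        fitted = fit(ImputerSpec("indicator_augmentation"), df)
        out = apply(fitted, df).tables[0]
        assert list(out.columns) == ["a", "b", "missing_a", "missing_b"]
        assert out["a"].tolist() == [0.0, 1.0]
        assert out["missing_a"].tolist() == [1.0, 0.0]

    def test_indicator_columns_learned_on_train_reused_on_test(self):
        train = frame({"a": [NA, 1.0], "b": [2.0, 3.0]})
        test = frame({"a": [1.0, 2.0], "b": [NA, 4.0]})
        fitted = fit(ImputerSpec("indicator_augmentation"), train)
        out = apply(fitted, test).tables[0]
        # only 'a' had missingness at fit time, so only its indicator exists
        assert list(out.columns) == ["a", "b", "missing_a"]
        assert out["missing_a"].tolist() == [0.0, 0.0]
        assert out["b"].tolist() == [0.0, 4.0]  # test missing cells still zero-filled


class TestKnn:
    def test_mean_of_all_complete_cases_when_k_covers_them(self):
        df = frame(
            {"x": [1.0, 2.0, 3.0, NA], "y": [10.0, 20.0, 30.0, 25.0]}
        )
        fitted = fit(ImputerSpec("knn", {"k": 3}), df)
        out = apply(fitted, df).tables[0]
        assert out.loc["v3", "x"] == pytest.approx(2.0)

    def test_k1_copies_single_complete_case(self):
        df = frame({"x": [7.0, NA], "y": [1.0, 1.0]})
        fitted = fit(ImputerSpec("knn", {"k": 1}), df)
        out = apply(fitted, df).tables[0]
        assert out.loc["v1", "x"] == 7.0

    def test_equidistant_tie_breaks_to_lower_row_index(self):
        df = frame({"x": [1.0, 3.0, NA], "y": [0.0, 0.0, 0.0], "z": [5.0, 9.0, 2.0]})
        # target row observes only y (and z); make distances tie via y only
        df.loc["v2", "z"] = NA
        fitted = fit(ImputerSpec("knn", {"k": 1}), df)
        out = apply(fitted, df).tables[0]
        assert out.loc["v2", "x"] == 1.0  # v0 and v1 tie on y-distance; v0 wins

    def test_k_exceeding_complete_cases_rejected(self):
        df = frame({"x": [1.0, NA], "y": [1.0, 2.0]})
        with pytest.raises(InsufficientCompleteCases):
            fit(ImputerSpec("knn", {"k": 5}), df)

    def test_full_k_equals_complete_case_mean_imputation(self, rng):
        # Degenerate regime: k = #complete cases reduces to unconditional
        # per-feature mean over complete cases.
        for _ in range(20):
            df = random_incomplete_frame(rng, n_rows=25, n_cols=5)
            complete = df.dropna()
            if len(complete) == 0:
                continue
            fitted = fit(ImputerSpec("knn", {"k": len(complete)}), df)
            out = apply(fitted, df).tables[0]
            for col in df.columns:
                missing = df[col].isna()
                expected = complete[col].mean()
                assert np.allclose(out.loc[missing, col], expected)


class TestChained:
    def test_complete_table_returned_unchanged(self):
        df = frame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        for method in CHAINED_METHODS:
            tables = chained_impute(df, method, {"ntree": 5}, seed=0, m=2)
            for t in tables:
                pd.testing.assert_frame_equal(t, df)

    def test_pmm_fills_are_observed_donor_values(self, rng):
        df = random_incomplete_frame(rng, n_rows=40, n_cols=4)
        tables = chained_impute(df, "pmm", {"donors": 3, "ridge": 1e-5, "matchtype": 1}, seed=1)
        out = tables[0]
        for col in df.columns:
            observed = set(df[col].dropna())
            for v in out.loc[df[col].isna(), col]:
                assert v in observed

    def test_chained_rf_fills_are_observed_donor_values(self, rng):
        df = random_incomplete_frame(rng, n_rows=30, n_cols=3)
        out = chained_impute(df, "chained_rf", {"ntree": 5}, seed=1)[0]
        for col in df.columns:
            observed = set(df[col].dropna())
            for v in out.loc[df[col].isna(), col]:
                assert v in observed

    def test_linear_regression_recovers_exact_linear_structure(self, rng):
        # f2 = 3*f1 exactly, partially missing: closed-form regression oracle.
        f1 = rng.normal(size=60)
        f2 = 3.0 * f1
        f2_missing = f2.copy()
        f2_missing[:15] = NA
        df = frame({"f1": f1, "f2": f2_missing})
        out = chained_impute(df, "chained_linear", {"ridge": 0.0}, seed=0)[0]
        assert np.allclose(out["f2"].iloc[:15], 3.0 * f1[:15], atol=1e-6)

    def test_bayes_linear_chains_differ(self, rng):
        df = random_incomplete_frame(rng, n_rows=40, n_cols=4)
        tables = chained_impute(df, "chained_bayes_linear", {}, seed=3, m=3)
        distinct = {t.to_numpy().tobytes() for t in tables}
        assert len(distinct) >= 2

    def test_pmm_multiple_imputations_not_all_identical(self, rng):
        df = random_incomplete_frame(rng, n_rows=40, n_cols=4)
        spec = ImputerSpec("pmm", {"donors": 5, "ridge": 1e-5, "matchtype": 1}, n_imputations=10)
        fitted = fit(spec, df)
        result = apply(fitted, df)
        assert len(result.tables) == 10
        distinct = {t.to_numpy().tobytes() for t in result.tables}
        assert len(distinct) >= 2

    def test_observed_cells_never_altered(self, rng):
        df = random_incomplete_frame(rng, n_rows=30, n_cols=4)
        for method in ("pmm", "chained_linear", "chained_bayes_linear"):
            out = chained_impute(df, method, {}, seed=2)[0]
            obs = ~df.isna()
            assert np.array_equal(out.to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()])

    def test_single_feature_rejected(self):
        df = frame({"a": [1.0, NA, 2.0]})
        with pytest.raises(ImputationError, match="2 features"):
            chained_impute(df, "pmm", {}, seed=0)


class TestBpca:
    def test_rank_one_reconstruction_beats_mean_imputation(self, rng):
        n, p = 80, 6
        z = rng.normal(size=n)
        w = rng.normal(size=p) + 2.0
        X = np.outer(z, w) + rng.normal(scale=0.05, size=(n, p))
        mask = rng.random((n, p)) < 0.2
        mask[:, 0] &= ~np.all(mask, axis=1)  # keep rows partially observed
        df = frame({f"f{j}": np.where(mask[:, j], NA, X[:, j]) for j in range(p)})
        out = bpca_impute(df, npcs=1, maxsteps=200, seed=0)
        err_bpca = np.sqrt(np.nanmean((out.to_numpy() - X)[mask] ** 2))
        means = df.mean().to_numpy()
        err_mean = np.sqrt(np.nanmean((np.broadcast_to(means, (n, p)) - X)[mask] ** 2))
        assert err_bpca < 0.25 * err_mean

    def test_complete_table_unchanged(self):
        df = frame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 0.0], "c": [0.0, 1.0, 4.0]})
        pd.testing.assert_frame_equal(bpca_impute(df, npcs=1), df)

    def test_npcs_at_feature_count_rejected(self):
        df = frame({"a": [1.0, NA], "b": [1.0, 2.0]})
        with pytest.raises(ImputationError, match="npcs"):
            bpca_impute(df, npcs=2)


class TestIterativeRf:
    def test_complete_table_unchanged(self):
        df = frame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = iterative_rf_impute(df, ntree=5, seed=0)[0]
        pd.testing.assert_frame_equal(out, df)

    def test_first_iteration_matches_stepwise_oracle(self, rng):
        # Single incomplete column: first pass must equal an RF fitted on
        # observed rows with mean-initialised covariates.
        from sklearn.ensemble import RandomForestRegressor
        from missbench._seeds import child_seed

        df = random_incomplete_frame(rng, n_rows=20, n_cols=4)
        col = "f1"
        for c in df.columns:  # make f1 the only incomplete column
            if c != col:
                df[c] = df[c].fillna(df[c].mean())
        out = iterative_rf_impute(df, mtry="sqrt", ntree=10, seed=7, max_iter=1)[0]
        obs = df[col].notna()
        others = [c for c in df.columns if c != col]
        rf = RandomForestRegressor(
            n_estimators=10,
            max_features=2,  # sqrt(3) rounds to 2
            random_state=child_seed(7, 0, 0, df.columns.get_loc(col)),
            n_jobs=1,
        )
        rf.fit(df.loc[obs, others], df.loc[obs, col])
        expected = rf.predict(df.loc[~obs, others])
        assert np.allclose(out.loc[~obs, col].to_numpy(), expected)

    def test_multiple_runs_differ(self, rng):
        df = random_incomplete_frame(rng, n_rows=30, n_cols=4)
        tables = iterative_rf_impute(df, ntree=10, seed=1, m=5)
        distinct = {t.to_numpy().tobytes() for t in tables}
        assert len(distinct) >= 2


class TestReuseContract:
    @pytest.mark.parametrize("method", SIMPLE_METHODS)
    def test_simple_methods_reuse_training_fills_on_shifted_test(self, method, rng):
        train = random_incomplete_frame(rng)
        test = train + 100.0  # location shift; fills must stay training-derived
        fitted = fit(ImputerSpec(method), train)
        out = apply(fitted, test).tables[0]
        for col in train.columns:
            missing = test[col].isna()
            if missing.any():
                assert (out.loc[missing, col] == fitted.fill_values[col]).all()

    def test_refit_policy_changes_fills(self, rng):
        train = random_incomplete_frame(rng)
        test = train + 100.0
        fitted = fit(ImputerSpec("mean", reuse_policy="refit"), train)
        out = apply(fitted, test).tables[0]
        col = next(c for c in train.columns if test[c].isna().any())
        missing = test[col].isna()
        assert np.allclose(out.loc[missing, col].to_numpy(), test[col].mean())
        assert not np.allclose(out.loc[missing, col].to_numpy(), fitted.fill_values[col])

    def test_force_reuse_unsupported_for_refit_methods(self, rng):
        train = random_incomplete_frame(rng, n_cols=4)
        fitted = fit(ImputerSpec("pmm", reuse_policy="force"), train)
        with pytest.raises(NotImplementedError):
            apply(fitted, train)


class TestGrids:
    def test_small_grid_returned_whole(self):
        grid = method_grid("chained_rf")
        assert sample_grid(grid, cap=8, seed=0) == grid

    def test_large_grid_subsamples_distinct(self):
        grid = method_grid("pmm")
        assert len(grid) == 36
        sampled = sample_grid(grid, cap=8, seed=1)
        assert len(sampled) == 8
        assert len({tuple(sorted(h.items())) for h in sampled}) == 8

    def test_same_seed_same_sample(self):
        grid = method_grid("pmm")
        assert sample_grid(grid, 8, 5) == sample_grid(grid, 8, 5)

    def test_bpca_grid_respects_feature_count(self):
        grid = method_grid("bpca", n_features=5)
        assert max(h["npcs"] for h in grid) == 4

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="single-imputation"):
            ImputerSpec("mean", n_imputations=5)
        with pytest.raises(ValueError, match="unknown"):
            ImputerSpec("magic")


class TestRuntime:
    def test_per_dataset_time_divides_by_m(self, rng):
        df = random_incomplete_frame(rng, n_rows=25, n_cols=4)
        spec = ImputerSpec("pmm", {"donors": 3}, n_imputations=5)
        result = apply(fit(spec, df), df)
        assert result.elapsed_seconds_per_dataset == pytest.approx(result.elapsed_seconds / 5)
        assert record_runtime(result) >= 0.0


class TestOutputContract:
    @pytest.mark.parametrize(
        "method,hp",
        [
            ("mean", {}),
            ("indicator_augmentation", {}),
            ("knn", {"k": 1}),
            ("pmm", {"donors": 3}),
            ("chained_linear", {}),
            ("chained_bayes_linear", {}),
            ("chained_rf", {"ntree": 5}),
            ("bpca", {"npcs": 2}),
            ("iterative_rf", {"ntree": 5}),
        ],
    )
    def test_every_method_completes_and_preserves_observed(self, method, hp, rng):
        df = random_incomplete_frame(rng, n_rows=30, n_cols=5)
        fitted = fit(ImputerSpec(method, hp), df, seed=2)
        out = apply(fitted, df, seed=3).tables[0]
        assert not out[df.columns].isna().to_numpy().any()
        obs = ~df.isna()
        assert np.array_equal(
            out[df.columns].to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()]
        )
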