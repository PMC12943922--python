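import numpy as np
import pandas as pd
import pytest

from ssaeeg import (
    EEGRecording,
    align_to_grid,
    cohort_median,
    epoch_features,
    fit_mlr,
    phase_summary,
    predict_bis,
    select_significant,
)
from ssaeeg.errors import (
    EmptyInputError,
    EmptyModelError,
    MulticollinearityError,
    SchemaError,
)
from ssaeeg.io_eeg import FEATURE_COLUMNS

FS = 128.0


def linear_table(rng, n=40, noise_sd=0.0, coefs=None, intercept=10.0):
    """Feature table whose BIS is a known linear function of the features."""
    X = rng.standard_normal((n, 12)) * 5 + 10
    table = pd.DataFrame(X, columns=FEATURE_COLUMNS,
                         index=pd.Index(np.arange(n) * 8.0, name="t"))
    coefs = coefs if coefs is not None else rng.uniform(-2, 2, 12)
    table["BIS"] = intercept + X @ coefs + noise_sd * rng.standard_normal(n)
    return table, coefs, intercept


class TestEpochFeatures:
    def test_twelve_feature_columns(self, maintenance_recording):
        feats = epoch_features(maintenance_recording)
        assert list(feats.columns) == FEATURE_COLUMNS

    def test_spindle_group_cf_in_alpha_band(self, maintenance_recording):
        feats = epoch_features(maintenance_recording)
        cf_medians = feats[[f"CF{i}" for i in range(1, 7)]].median()
        assert ((cf_medians >= 8) & (cf_medians <= 13)).any()

    def test_zero_recording_gives_missing_rows(self, zeros_recording):
        feats = epoch_features(zeros_recording)
        assert len(feats) > 0
        assert feats.isna().all().all()

    def test_rows_indexed_at_epoch_centers(self, maintenance_recording):
        feats = epoch_features(maintenance_recording)
        assert feats.index[0] == pytest.approx(1.5)
        assert feats.index[1] == pytest.approx(3.5)


class TestAlignToGrid:
    def test_600s_grid_has_75_rows(self):
        idx = pd.Index(1.5 + 2.0 * np.arange(299), name="t")
        feats = pd.DataFrame({"CF1": np.arange(299.0)}, index=idx)
        aligned = align_to_grid(feats, grid_seconds=8.0)
        assert len(aligned) == 75
        assert aligned.index[0] == 0.0 and aligned.index[-1] == 592.0

    def test_cells_aggregate_at_most_four_epochs(self):
        # brute-force enumeration: with 2-s hop, any 8-s cell holds <= 4 centers
        centers = 1.5 + 2.0 * np.arange(299)
        cells = np.floor(centers / 8.0).astype(int)
        assert np.bincount(cells).max() <= 4
        feats = pd.DataFrame({"CF1": np.ones(299)}, index=pd.Index(centers, name="t"))
        aligned = align_to_grid(feats, grid_seconds=8.0)
        np.testing.assert_allclose(aligned["CF1"], 1.0)

    def test_single_epoch_cell_is_identity(self):
        feats = pd.DataFrame({"CF1": [4.2]}, index=pd.Index([1.5], name="t"))
        aligned = align_to_grid(feats, grid_seconds=8.0)
        assert aligned.loc[0.0, "CF1"] == 4.2

    def test_median_within_cell(self):
        feats = pd.DataFrame(
            {"CF1": [1.0, 5.0, 100.0]}, index=pd.Index([1.0, 3.0, 5.0], name="t")
        )
        aligned = align_to_grid(feats, grid_seconds=8.0)
        assert aligned.loc[0.0, "CF1"] == 5.0

    def test_bis_nearest_within_half_cell(self):
        feats = pd.DataFrame({"CF1": np.ones(3)}, index=pd.Index([1.5, 9.5, 17.5], name="t"))
        bis = pd.Series([55.0, 44.0], index=[0.5, 15.0])
        aligned = align_to_grid(feats, grid_seconds=8.0, bis=bis)
        assert aligned.loc[0.0, "BIS"] == 55.0
        assert np.isnan(aligned.loc[8.0, "BIS"])  # nearest is 3.5 s away... within 4
        # cell at 16 s: BIS at 15.0 is 1 s away -> matched
        assert aligned.loc[16.0, "BIS"] == 44.0


class TestCohortMedian:
    def test_single_table_identity(self, rng):
        table, _, _ = linear_table(rng)
        med = cohort_median([table])
        pd.testing.assert_frame_equal(med, table, check_names=False)

    def test_median_is_robust_to_outlier(self):
        idx = pd.Index([0.0], name="t")
        tables = [pd.DataFrame({"CF1": [v]}, index=idx) for v in (3.0, 5.0, 100.0)]
        assert cohort_median(tables).loc[0.0, "CF1"] == 5.0

    def test_grid_preserved_and_provenance(self, rng):
        tables = [linear_table(rng)[0] for _ in range(10)]
        med = cohort_median(tables)
        assert len(med) == len(tables[0])
        assert med.attrs["provenance"] == "cohort-median"

    def test_no_tables_raises(self):
        with pytest.raises(EmptyInputError):
            cohort_median([])

    def test_mismatched_grids_rejected(self, rng):
        t1, _, _ = linear_table(rng, n=10)
        t2, _, _ = linear_table(rng, n=12)
        with pytest.raises(SchemaError):
            cohort_median([t1, t2])


class TestFitMLR:
    def test_exact_linear_recovery(self, rng):
        table, coefs, intercept = linear_table(rng, n=40)
        model = fit_mlr(table)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)
        assert model.mae <= 1e-8
        np.testing.assert_allclose(
            [model.coefficients[p] for p in FEATURE_COLUMNS], coefs, atol=1e-8
        )
        assert model.intercept == pytest.approx(intercept, abs=1e-6)

    def test_constant_column_multicollinearity(self, rng):
        table, _, _ = linear_table(rng)
        table["CF3"] = 7.0
        with pytest.raises(MulticollinearityError) as exc:
            fit_mlr(table)
        assert "CF3" in exc.value.columns

    def test_duplicated_column_multicollinearity(self, rng):
        table, _, _ = linear_table(rng)
        table["TP6"] = table["CF1"] * 2.0
        with pytest.raises(MulticollinearityError):
            fit_mlr(table)

    def test_residual_orthogonality_and_r2_identity(self, rng):
        table, _, _ = linear_table(rng, n=60, noise_sd=5.0)
        model = fit_mlr(table)
        pred = predict_bis(model, table)
        resid = table["BIS"] - pred
        assert abs(resid.sum()) <= 1e-8 * np.abs(table["BIS"]).sum()
        for p in model.included_params:
            assert abs(np.dot(resid, table[p])) / len(table) <= 1e-6
        sse = np.sum(resid**2)
        sst = np.sum((table["BIS"] - table["BIS"].mean()) ** 2)
        assert model.r2 == pytest.approx(1 - sse / sst, abs=1e-10)
        assert model.mae <= model.rmse

    def test_too_few_rows(self, rng):
        table, _, _ = linear_table(rng, n=10)
        with pytest.raises(EmptyInputError):
            fit_mlr(table)

    def test_missing_rows_dropped(self, rng):
        table, _, _ = linear_table(rng, n=40)
        table.iloc[3, 0] = np.nan
        model = fit_mlr(table)
        assert model.n_obs == 39


class TestSelection:
    def test_alpha_one_returns_full_model(self, rng):
        table, _, _ = linear_table(rng, n=40, noise_sd=2.0)
        model = fit_mlr(table)
        assert select_significant(model, table, alpha=1.0) is model

    def test_no_significant_raises(self, rng):
        table, _, _ = linear_table(rng, n=40, noise_sd=2.0)
        model = fit_mlr(table)
        with pytest.raises(EmptyModelError):
            select_significant(model, table, alpha=1e-30)

    def test_reduced_model_keeps_true_drivers(self, rng):
        # strong effects on 4 params, zero on the rest
        coefs = np.zeros(12)
        coefs[[0, 4, 6, 11]] = [5.0, -4.0, 3.0, 6.0]
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            table, _, _ = linear_table(rng, n=75, noise_sd=3.0, coefs=coefs)
            reduced = select_significant(fit_mlr(table), table)
            true_drivers = {FEATURE_COLUMNS[i] for i in (0, 4, 6, 11)}
            if true_drivers <= set(reduced.included_params):
                hits += 1
        assert hits / n_rep >= 0.9


class TestPredict:
    def test_intercept_only_constant(self, rng):
        table, _, _ = linear_table(rng, n=20)
        from ssaeeg.anesthesia_features import RegressionModel

        model = RegressionModel(
            intercept=42.0, coefficients={}, p_values={}, r2=0.0, mae=0.0,
            rmse=0.0, n_obs=20, included_params=[],
        )
        pred = predict_bis(model, table)
        np.testing.assert_allclose(pred, 42.0)

    def test_training_mae_self_consistency(self, rng):
        table, _, _ = linear_table(rng, n=50, noise_sd=4.0)
        model = fit_mlr(table)
        pred = predict_bis(model, table)
        mae = np.mean(np.abs(table["BIS"] - pred))
        assert mae == pytest.approx(model.mae, abs=1e-9)

    def test_missing_column_schema_error(self, rng):
        table, _, _ = linear_table(rng, n=40)
        model = fit_mlr(table)
        with pytest.raises(SchemaError):
            predict_bis(model, table.drop(columns=["CF2"]))

    def test_missing_input_gives_missing_prediction(self, rng):
        table, _, _ = linear_table(rng, n=40)
        model = fit_mlr(table)
        table.iloc[5, 2] = np.nan
        pred = predict_bis(model, table)
        assert np.isnan(pred.iloc[5]) and np.isfinite(pred.iloc[6])


class TestPhaseSummary:
    @staticmethod
    def grid_table(values_by_phase, rng, sd=0.0, param="CF6"):
        t = np.arange(75) * 8.0
        vals = np.empty(75)
        for i, ti in enumerate(t):
            ph = min(2, int(ti // 200))
            vals[i] = values_by_phase[ph] + sd * rng.standard_normal()
        return pd.DataFrame({param: vals}, index=pd.Index(t, name="t"))

    def test_identical_distributions(self, rng):
        table = self.grid_table([5.0, 5.0, 5.0], rng, sd=1.0)
        summ = phase_summary(table, span_seconds=600.0)
        pct = summ.stats.loc[("CF6", "emergence"), "pct_change"]
        assert abs(pct) < 30
        assert summ.tests.loc["CF6", "kruskal_p"] > 0.05

    def test_pct_change_formula(self, rng):
        table = self.grid_table([10.0, 5.0, 10.0], rng)
        summ = phase_summary(table, span_seconds=600.0)
        assert summ.stats.loc[("CF6", "transition"), "pct_change"] == pytest.approx(-50.0)
        assert summ.stats.loc[("CF6", "maintenance"), "pct_change"] == 0.0

    def test_programmed_shift_detected(self, rng):
        table = self.grid_table([13.0, 13.5, 17.5], rng, sd=1.0)
        summ = phase_summary(table, span_seconds=600.0)
        assert summ.tests.loc["CF6", "p_emergence_vs_maintenance"] < 0.05

    def test_phases_partition_span(self, rng):
        table = self.grid_table([1.0, 2.0, 3.0], rng)
        summ = phase_summary(table, span_seconds=600.0)
        bounds = list(summ.phase_bounds.values())
        assert bounds[0][1] == bounds[1][0] and bounds[1][1] == bounds[2][0]
        assert bounds[2][1] - bounds[0][0] == 600.0

    def test_insufficient_rows_flagged(self, rng):
        t = np.array([0.0, 8.0, 250.0, 258.0, 410.0])
        table = pd.DataFrame({"CF1": np.ones(5)}, index=pd.Index(t, name="t"))
        summ = phase_summary(table, span_seconds=600.0)
        assert summ.tests.loc["CF1", "insufficient_data"]
        assert np.isnan(summ.tests.loc["CF1", "kruskal_p"])
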