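"""Window summaries, NEE conversion, outlier filtering, matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from sepsistraj import (FeatureMatrix, FeatureRegistry, MeanImputer,
                        apply_imputer, build_cohort, build_matrix,
                        compute_nee, default_registry, filter_outliers,
                        fit_mean_imputer, label_cohort, summarize_window)
from sepsistraj.errors import ContractViolation, DataError


class TestSummarizeWindow:
    def test_hand_computed_example(self):
        out = summarize_window([1.0, 2.0, 3.0])
        assert out["max"] == 3 and out["min"] == 1 and out["median"] == 2
        assert out["cv"] == pytest.approx(0.5)  # sample SD 1 over mean 2

    def test_single_value_masks_cv(self):
        out = summarize_window([5.0])
        assert out["max"] == out["min"] == out["median"] == 5
        assert np.isnan(out["cv"])

    def test_empty_window_masks_everything(self):
        assert all(np.isnan(v) for v in summarize_window([]).values())

    def test_zero_mean_masks_cv(self):
        out = summarize_window([-1.0, 1.0])
        assert np.isnan(out["cv"]) and out["max"] == 1.0


class TestOutlierFilter:
    def _obs(self, var, values):
        return pd.DataFrame({"patient_id": "P", "time_hours": 1.0,
                             "variable": var, "value": values})

    def test_out_of_range_removed(self):
        reg = default_registry()
        out = filter_outliers(self._obs("heart_rate", [70.0, 500.0]), reg)
        assert out["value"].tolist() == [70.0]

    def test_boundary_value_retained(self):
        reg = default_registry()  # heart_rate bounds [10, 300] closed
        out = filter_outliers(self._obs("heart_rate", [10.0, 300.0]), reg)
        assert len(out) == 2

    def test_unregistered_variable_passes_with_warning(self):
        reg = default_registry()
        with pytest.warns(UserWarning, match="mystery"):
            out = filter_outliers(self._obs("mystery", [1e9]), reg)
        assert len(out) == 1

    def test_empty_table(self):
        out = filter_outliers(self._obs("heart_rate", []), default_registry())
        assert len(out) == 0


def _infusion_rows(rows):
    return pd.DataFrame(rows, columns=["drug_name", "rate_value",
                                       "rate_units", "weight_based",
                                       "start_hours", "end_hours"])


class TestComputeNEE:
    def test_norepinephrine_identity(self):
        inf = _infusion_rows([("norepinephrine", 0.1, "ug/kg/min", True,
                               0.0, 10.0)])
        assert compute_nee(inf, 80.0, [5.0])[0] == pytest.approx(0.1)

    def test_linear_combination_with_factors(self):
        inf = _infusion_rows([
            ("norepinephrine", 0.1, "ug/kg/min", True, 0.0, 10.0),
            ("dopamine", 10.0, "ug/kg/min", True, 0.0, 10.0),
        ])
        assert compute_nee(inf, 80.0, [5.0])[0] == pytest.approx(0.2)

    def test_absolute_rate_divided_by_weight(self):
        inf = _infusion_rows([("norepinephrine", 8.0, "ug/min", False,
                               0.0, 10.0)])
        assert compute_nee(inf, 80.0, [5.0])[0] == pytest.approx(0.1)

    def test_vasopressin_units_per_minute(self):
        inf = _infusion_rows([("vasopressin", 0.04, "U/min", False,
                               0.0, 10.0)])
        assert compute_nee(inf, 80.0, [5.0])[0] == pytest.approx(0.1)

    def test_no_active_infusion_is_zero(self):
        inf = _infusion_rows([("norepinephrine", 0.1, "ug/kg/min", True,
                               0.0, 4.0)])
        assert compute_nee(inf, 80.0, [5.0])[0] == 0.0

    def test_unknown_drug_is_data_error(self):
        inf = _infusion_rows([("milrinone", 0.5, "ug/kg/min", True,
                               0.0, 10.0)])
        with pytest.raises(DataError, match="milrinone"):
            compute_nee(inf, 80.0, [5.0])

    def test_additivity_over_infusions(self, rng):
        drugs = ["norepinephrine", "epinephrine", "dopamine",
                 "phenylephrine", "vasopressin"]
        t = np.linspace(0, 24, 25)
        rows = []
        for d in drugs:
            rows.append((d, float(rng.uniform(0.01, 5)),
                         "U/min" if d == "vasopressin" else "ug/kg/min",
                         d != "vasopressin",
                         float(rng.uniform(0, 10)), float(rng.uniform(11, 24))))
        combined = compute_nee(_infusion_rows(rows), 75.0, t)
        sum_of_parts = sum(compute_nee(_infusion_rows([r]), 75.0, t)
                           for r in rows)
        np.testing.assert_allclose(combined, sum_of_parts, rtol=1e-12)


def _tiny_registry(n_static=2, n_tv=3):
    tv = [("heart_rate", "heart_rate", "bpm"), ("sbp", "sbp", "mmHg"),
          ("lactate", "lactate", "mmol/L"), ("nee", "nee", "ug/kg/min")]
    st = [("age_years", "age_years"), ("sex_male", "sex"),
          ("weight_kg", "weight_kg")]
    return FeatureRegistry(
        static_features=tuple(st[:n_static]),
        timevarying_features=tuple(tv[:n_tv]),
        outlier_ranges=default_registry().outlier_ranges,
        nee_conversion=default_registry().nee_conversion,
    )


class TestBuildMatrix:
    def test_column_count_formula(self, clean_bundles):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        for n_static, n_tv in [(2, 3), (3, 4), (1, 1)]:
            reg = _tiny_registry(n_static, n_tv)
            mat = build_matrix(labeled.head(30), bundles, reg)
            assert mat.X.shape[1] == n_static + 4 * n_tv
            assert list(mat.X.columns) == reg.column_names

    def test_default_registry_shape(self, clean_bundles):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        mat = build_matrix(labeled.head(40), bundles)
        reg = default_registry()
        n_static = len(reg.static_features)
        n_tv = len(reg.timevarying_features)
        assert mat.X.shape[1] == n_static + 4 * n_tv + 1  # + urine total
        assert "nee_max" in mat.X.columns

    def test_row_order_invariant_to_input_shuffle(self, clean_bundles, rng):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        sub = labeled.head(25)
        a = build_matrix(sub, bundles, _tiny_registry())
        b = build_matrix(sub.sample(frac=1, random_state=1), bundles,
                         _tiny_registry())
        pd.testing.assert_frame_equal(a.X.sort_index(), b.X.sort_index())

    def test_mask_matches_nan_cells(self, clean_bundles):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        mat = build_matrix(labeled.head(20), bundles, _tiny_registry())
        assert mat.mask.equals(mat.X.isna())
        assert np.isfinite(mat.X.to_numpy()).any()
        assert not np.isinf(mat.X.to_numpy()).any()

    def test_provenance_covers_every_column(self, clean_bundles):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        mat = build_matrix(labeled.head(10), bundles, _tiny_registry())
        assert mat.provenance["column"].tolist() == list(mat.X.columns)

    def test_missing_patient_is_data_error(self, clean_bundles):
        bundles, _ = clean_bundles
        labeled, _ = label_cohort(build_cohort(bundles), bundles)
        sub = labeled.head(5).copy()
        sub.loc[sub.index[0], "patient_id"] = "GHOST"
        with pytest.raises(DataError, match="GHOST"):
            build_matrix(sub, bundles, _tiny_registry())


class TestMeanImputer:
    def _matrix(self):
        X = pd.DataFrame({"a": [1.0, 3.0, np.nan], "b": [np.nan] * 3,
                          "c": [1.0, 1.0, 1.0]},
                         index=["p1", "p2", "p3"])
        prov = pd.DataFrame({"column": list("abc"), "source_variable": "-",
                             "summary": "static"})
        return FeatureMatrix(X, prov)

    def test_masked_cell_gets_training_mean(self):
        mat = self._matrix()
        imp = fit_mean_imputer(mat)
        out = apply_imputer(imp, mat)
        assert out.X.loc["p3", "a"] == 2.0

    def test_fully_missing_column_zero_filled_and_flagged(self):
        imp = fit_mean_imputer(self._matrix())
        assert imp.zero_filled_ == ["b"]
        assert (apply_imputer(imp, self._matrix()).X["b"] == 0).all()

    def test_complete_matrix_unchanged(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        imp = MeanImputer().fit(X)
        pd.testing.assert_frame_equal(imp.transform(X), X)

    def test_training_column_means_preserved(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X[X > 1.2] = np.nan
        imp = MeanImputer().fit(X)
        out = imp.transform(X)
        np.testing.assert_allclose(out.mean(), X.mean(), rtol=1e-12)

    def test_unfitted_imputer_raises(self):
        with pytest.raises(ContractViolation):
            MeanImputer().transform(pd.DataFrame({"a": [1.0]}))

    def test_imputation_statistics_come_from_training_rows_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        X.iloc[::5] = np.nan
        train, test = X.iloc[:20], X.iloc[20:]
        imp = MeanImputer().fit(train)
        out = imp.transform(test)
        filled = out.loc[test["a"].isna(), "a"]
        assert (filled == train["a"].mean()).all()
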