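import numpy as np
import pandas as pd
import pytest

from radiorisk.modeling import (
    CLINICAL_VARIABLES,
    FittedModel,
    ModelSpec,
    SelectionParams,
    StandardizationParams,
    adaptive_lasso_select,
    clinical_matrix,
    fit_model,
    standardize,
    worst_lesion_rows,
)
from radiorisk.radiomics import HRS6_NAME


def _noise_frame(rng, n, p, prefix="x"):
    return pd.DataFrame(rng.standard_normal((n, p)),
                        columns=[f"{prefix}{i}" for i in range(p)])


class TestStandardize:
    def test_output_moments_and_round_trip(self, rng):
        X = _noise_frame(rng, 50, 4) * 7 + 3
        Xs, params = standardize(X)
        assert np.allclose(Xs.mean(), 0, atol=1e-12)
        assert np.allclose(Xs.std(ddof=0), 1, atol=1e-12)
        back = Xs * pd.Series(params.scale) + pd.Series(params.center)
        np.testing.assert_allclose(back.values, X.values, atol=1e-12)

    def test_zero_variance_column_dropped(self, rng):
        X = _noise_frame(rng, 30, 3)
        X["flat"] = 5.0
        Xs, params = standardize(X)
        assert "flat" not in Xs.columns
        assert params.dropped == ["flat"]

    def test_stored_params_reapplied_verbatim(self, rng):
        X = _noise_frame(rng, 40, 3)
        _, params = standardize(X)
        X2 = _noise_frame(rng, 10, 3) + 100  # very different distribution
        Xs2, _ = standardize(X2, params)
        expected = (X2 - pd.Series(params.center)) / pd.Series(params.scale)
        np.testing.assert_allclose(Xs2.values, expected.values)

    def test_missing_values_median_imputed(self, rng):
        X = _noise_frame(rng, 30, 2)
        X.iloc[0, 0] = np.nan
        Xs, params = standardize(X)
        assert np.isfinite(Xs.values).all()

    def test_all_missing_column_fails(self, rng):
        X = _noise_frame(rng, 10, 2)
        X["gone"] = np.nan
        with pytest.raises(ValueError, match="gone"):
            standardize(X)


class TestClinicalMatrix:
    def test_dichotomizations(self):
        df = pd.DataFrame({"age": [60, 70], "psad": [0.1, 0.3],
                           "dre": [0, 2], "pirads": [2, 3]})
        out = clinical_matrix(df)
        assert list(out.columns) == list(CLINICAL_VARIABLES)
        assert out["dre_pos"].tolist() == [0.0, 1.0]
        assert out["pirads_high"].tolist() == [0.0, 1.0]


class TestModelSpec:
    def test_model1_is_clinical_only(self):
        spec = ModelSpec(1)
        assert spec.clinical_variables == list(CLINICAL_VARIABLES)
        assert spec.penalized_pool == [] and spec.forced_variables == []

    def test_model2_pool_and_forced_volume(self):
        spec = ModelSpec(2)
        assert len(spec.penalized_pool) == 162
        assert all(n.startswith("L_") for n in spec.penalized_pool)
        assert spec.forced_variables == [HRS6_NAME]

    def test_model3_uses_all_rois(self):
        assert len(ModelSpec(3).penalized_pool) == 486

    def test_models_4_5_add_clinical(self):
        assert ModelSpec(4).clinical_variables == list(CLINICAL_VARIABLES)
        assert len(ModelSpec(5).penalized_pool) == 486

    def test_intensity_only_pool_from_name_grammar(self):
        # one first-order family x 3 sequences x 9 descriptors per ROI
        assert len(ModelSpec(2, intensity_only=True).penalized_pool) == 27
        assert len(ModelSpec(3, intensity_only=True).penalized_pool) == 81

    def test_invalid_model_id(self):
        with pytest.raises(ValueError):
            ModelSpec(6)


class TestAdaptiveLasso:
    def test_planted_signal_is_selected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 150
            X = _noise_frame(rng, n, 20)
            logit = 2.5 * X["x3"] + rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            Xs, _ = standardize(X)
            selected = adaptive_lasso_select(Xs, y, SelectionParams(n_folds=5),
                                             seed=seed)
            hits += "x3" in selected
        assert hits == 5

    def test_pure_noise_selects_little(self):
        sparse = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = _noise_frame(rng, 150, 30)
            y = (rng.random(150) < 0.5).astype(int)
            Xs, _ = standardize(X)
            selected = adaptive_lasso_select(Xs, y, SelectionParams(n_folds=5),
                                             seed=seed)
            sparse += len(selected) <= 2
        assert sparse >= 4

    def test_single_class_fails(self, rng):
        X = _noise_frame(rng, 20, 3)
        with pytest.raises(ValueError, match="both classes"):
            adaptive_lasso_select(X, np.ones(20, int))

    def test_deterministic_given_seed(self, rng):
        X = _noise_frame(rng, 100, 15)
        y = (rng.random(100) < 0.5).astype(int)
        Xs, _ = standardize(X)
        a = adaptive_lasso_select(Xs, y, SelectionParams(n_folds=5), seed=3)
        b = adaptive_lasso_select(Xs, y, SelectionParams(n_folds=5), seed=3)
        assert a == b


class TestFitAndPredict:
    def test_model1_uses_exactly_four_predictors(self, analysis_table):
        model = fit_model(ModelSpec(1), analysis_table)
        assert sorted(model.variables) == sorted(CLINICAL_VARIABLES)

    def test_model2_always_contains_volume(self, analysis_table):
        model = fit_model(ModelSpec(2, selection=SelectionParams(n_folds=4)),
                          analysis_table)
        assert HRS6_NAME in model.variables

    def test_predictions_in_unit_interval_and_batch_consistent(self, analysis_table):
        model = fit_model(ModelSpec(1), analysis_table)
        probs = model.predict_lesion(analysis_table)
        assert np.all((probs > 0) & (probs < 1))
        one = model.predict_lesion(analysis_table.iloc[[3]])
        assert one[0] == pytest.approx(probs[3])

    def test_fit_is_deterministic(self, analysis_table):
        spec = ModelSpec(2, selection=SelectionParams(n_folds=4), seed=9)
        m1 = fit_model(spec, analysis_table)
        m2 = fit_model(spec, analysis_table)
        assert m1.selected == m2.selected
        assert m1.coefficients == m2.coefficients

    def test_single_class_label_fails(self, analysis_table):
        df = analysis_table.copy()
        df["low_risk"] = True
        with pytest.raises(ValueError, match="both classes"):
            fit_model(ModelSpec(1), df)

    def test_missing_variable_named_at_prediction(self, analysis_table):
        model = fit_model(ModelSpec(2, selection=SelectionParams(n_folds=4)),
                          analysis_table)
        broken = analysis_table.drop(columns=[HRS6_NAME])
        with pytest.raises(KeyError, match=HRS6_NAME):
            model.predict_lesion(broken)

    def test_json_round_trip_preserves_predictions(self, analysis_table, tmp_path):
        model = fit_model(ModelSpec(4, selection=SelectionParams(n_folds=4)),
                          analysis_table)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedModel.from_json(path)
        np.testing.assert_allclose(back.predict_lesion(analysis_table),
                                   model.predict_lesion(analysis_table), atol=1e-12)


class TestManualModelPredictions:
    def _manual_model(self, beta, intercept=0.5):
        variables = list(beta)
        std = StandardizationParams(center={v: 0.0 for v in variables},
                                    scale={v: 1.0 for v in variables},
                                    medians={v: 0.0 for v in variables},
                                    dropped=[])
        return FittedModel(spec=ModelSpec(2), variables=variables, selected=[],
                           standardization=std, intercept=intercept,
                           coefficients=beta)

    def test_all_zero_inputs_give_sigmoid_intercept(self):
        model = self._manual_model({HRS6_NAME: 1.2}, intercept=0.5)
        df = pd.DataFrame({HRS6_NAME: [0.0]})
        assert model.predict_lesion(df)[0] == pytest.approx(1 / (1 + np.exp(-0.5)))

    def test_monotone_in_positive_coefficient(self):
        model = self._manual_model({HRS6_NAME: 2.0})
        df = pd.DataFrame({HRS6_NAME: [-1.0, 0.0, 2.0]})
        probs = model.predict_lesion(df)
        assert probs[0] < probs[1] < probs[2]

    def test_patient_min_prob_policy(self):
        model = self._manual_model({HRS6_NAME: 1.0}, intercept=0.0)
        df = pd.DataFrame({HRS6_NAME: [2.2, -1.4], "patient_id": ["A", "A"],
                           "true_three_tier": [0, 1]})
        out = model.predict_patient(df, policy="min_prob")
        expected = 1 / (1 + np.exp(1.4))
        assert out.probability[0] == pytest.approx(expected)

    def test_patient_worst_lesion_truth_policy(self):
        model = self._manual_model({HRS6_NAME: 1.0}, intercept=0.0)
        df = pd.DataFrame({HRS6_NAME: [2.2, -1.4], "patient_id": ["A", "A"],
                           "true_three_tier": [0, 2]})
        out = model.predict_patient(df, policy="worst_lesion_truth")
        expected = 1 / (1 + np.exp(1.4))  # row with tier 2
        assert out.probability[0] == pytest.approx(expected)

    def test_single_lesion_policies_agree(self):
        model = self._manual_model({HRS6_NAME: 1.0})
        df = pd.DataFrame({HRS6_NAME: [0.3], "patient_id": ["A"],
                           "true_three_tier": [1]})
        a = model.predict_patient(df, policy="min_prob").probability[0]
        b = model.predict_patient(df, policy="worst_lesion_truth").probability[0]
        assert a == pytest.approx(b)

    def test_unknown_policy_fails(self):
        model = self._manual_model({HRS6_NAME: 1.0})
        df = pd.DataFrame({HRS6_NAME: [0.3], "patient_id": ["A"],
                           "true_three_tier": [1]})
        with pytest.raises(ValueError, match="policy"):
            model.predict_patient(df, policy="mean")


class TestWorstLesionRows:
    def test_picks_highest_tier_per_patient(self):
        df = pd.DataFrame({"patient_id": ["A", "A", "B"],
                           "true_three_tier": [0, 2, 1],
                           "val": [1, 2, 3]})
        out = worst_lesion_rows(df)
        assert out.set_index("patient_id").loc["A", "val"] == 2
        assert len(out) == 2
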