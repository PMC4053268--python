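"""Model presets, design matrices and logistic fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from hosprisk.models import (
    FittedModel,
    ModelSpec,
    RankDeficientError,
    SeparationError,
    build_design_matrix,
    fit_logistic,
    fit_preset,
    odds_ratios,
    predict_risk,
    prepare_features,
    preset,
    split_by_year,
)

from conftest import newton_logistic

#: published variable counts for the model family
VARIABLE_COUNTS = {
    "model1": 2, "model2a": 1, "model2b": 3, "model2c": 22, "model3": 1,
    "model4a": 3, "model4b": 5, "model4c": 24,
    "model5a": 4, "model5b": 6, "model5c": 25,
}


class TestSpecs:
    @pytest.mark.parametrize("name,count", sorted(VARIABLE_COUNTS.items()))
    def test_preset_variable_counts(self, name, count):
        assert preset(name).n_covariates == count

    def test_subgroup_presets(self):
        s = preset("model6:R61")
        assert s.subgroup == ("drg", "R61") and s.n_covariates == 25
        s = preset("model7:ED")
        assert s.subgroup == ("route", "ED")
        with pytest.raises(KeyError):
            preset("model7:walk-in")
        with pytest.raises(KeyError):
            preset("model99")

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec()

    def test_design_matrix_columns(self, small_cohort):
        X, y, names = build_design_matrix(small_cohort, preset("model5c"))
        assert names[0] == "intercept"
        assert len(names) == 26  # intercept + 25 covariates
        assert X.shape == (len(small_cohort), 26)
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_subgroup_filter_empties_informatively(self, small_cohort):
        spec = ModelSpec(True, "c", True, subgroup=("drg", "NOPE"))
        with pytest.raises(ValueError, match="NOPE"):
            build_design_matrix(small_cohort, spec)


class TestFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(20_000) < 0.013).astype(float)
        X = np.ones((len(y), 1))
        m = fit_logistic(X, y, ["intercept"])
        assert m.params[0] == pytest.approx(float(logit(y.mean())), abs=1e-8)

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(2000), rng.normal(size=(2000, 3))])
        eta = X @ np.array([-2.0, 0.8, -0.5, 0.3])
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(X, y)
        oracle = newton_logistic(X, y)
        assert np.allclose(m.params, oracle, atol=1e-6)
        assert m.grad_norm < 1e-6
        assert m.llf <= 0

    def test_duplicated_column_raises_rank_error(self):
        X = np.ones((100, 2))
        y = np.r_[np.zeros(50), np.ones(50)]
        with pytest.raises(RankDeficientError):
            fit_logistic(X, y, ["intercept", "dup"])

    def test_one_class_outcome_rejected(self):
        X = np.ones((50, 1))
        with pytest.raises(ValueError):
            fit_logistic(X, np.zeros(50))

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = x.copy()
        X = np.column_stack([np.ones(100), x])
        with pytest.raises(SeparationError):
            fit_logistic(X, y, ["intercept", "sep"])

    def test_fit_invariant_to_record_order(self, small_cohort):
        m1 = fit_preset(small_cohort, "model5a")
        shuffled = small_cohort.sample(frac=1.0, random_state=1)
        m2 = fit_preset(shuffled, "model5a")
        assert np.allclose(m1.params, m2.params, atol=1e-8)

    def test_nested_model_likelihood_ordering(self, small_cohort):
        lls = {name: fit_preset(small_cohort, name).llf
               for name in ("model1", "model4a", "model5a", "model5c")}
        assert lls["model1"] <= lls["model4a"] <= lls["model5a"] <= lls["model5c"]

    def test_json_round_trip(self, small_cohort, tmp_path):
        m = fit_preset(small_cohort, "model5c")
        path = tmp_path / "m.json"
        m.to_json(path)
        m2 = FittedModel.from_json(path)
        assert m2.names == m.names
        assert np.allclose(m2.params, m.params)
        assert m2.spec == m.spec


class TestPredict:
    def test_all_zero_coefficients_give_half(self, small_cohort):
        m = fit_preset(small_cohort, "model1")
        m.params[:] = 0.0
        p = predict_risk(m, small_cohort.head(50))
        assert np.allclose(p, 0.5)

    def test_extreme_linear_predictor_stays_open_interval(self, small_cohort):
        m = fit_preset(small_cohort, "model1")
        m.params[:] = [500.0, 500.0, 500.0]
        p = predict_risk(m, small_cohort.head(50))
        assert np.all(p > 0) and np.all(p < 1)

    def test_generator_truth_round_trip(self, small_cohort):
        """Predicting with the generator's own coefficients reproduces
        the generator's probabilities exactly."""
        from hosprisk.cohort import default_true_coefficients
        from hosprisk.exposure import ADMISSION_TIME_NAME, PERIOD_NAMES

        beta = default_true_coefficients()
        spec = preset("model5c")
        X, _, names = build_design_matrix(small_cohort, spec)
        order = {
            "intercept": "intercept", "age": "age", "gender_M": "gender_M",
            "charlson": "charlson", ADMISSION_TIME_NAME: ADMISSION_TIME_NAME,
            **{n: n for n in PERIOD_NAMES},
        }
        m = fit_preset(small_cohort, "model5c")
        m.params = np.array([beta[order[n]] for n in names])
        p = predict_risk(m, small_cohort)
        assert np.allclose(p, small_cohort["true_p"].to_numpy(), atol=1e-12)


class TestSplit:
    def test_prospective_split(self, small_cohort):
        train, test = split_by_year(small_cohort, 2007)
        assert (pd.to_datetime(train["admission"]).dt.year < 2007).all()
        assert (pd.to_datetime(test["admission"]).dt.year == 2007).all()
        assert len(train) + len(test) == len(small_cohort)

    def test_single_year_data_fails(self, small_cohort):
        only_2007 = small_cohort[
            pd.to_datetime(small_cohort["admission"]).dt.year == 2007
        ]
        with pytest.raises(ValueError):
            split_by_year(only_2007, 2007)

    def test_records_after_test_year_excluded(self, small_cohort):
        train, test = split_by_year(small_cohort, 2006)
        assert len(train) + len(test) < len(small_cohort)


class TestOddsRatios:
    def test_reference_is_unity_and_shape(self, small_cohort):
        m = fit_preset(small_cohort, "model5c")
        table = odds_ratios(m)
        assert len(table) == 21
        ref = table[(table["day"] == "Mon") & (table["block"] == "daytime")]
        assert ref["odds_ratio"].iloc[0] == pytest.approx(1.0)

    def test_equal_coefficients_give_unit_ratios(self, small_cohort):
        m = fit_preset(small_cohort, "model5c")
        for n in m.names:
            if n.startswith("count_"):
                m.params[m.names.index(n)] = 0.25
        table = odds_ratios(m)
        assert np.allclose(table["odds_ratio"], 1.0)

    def test_requires_variant_c(self, small_cohort):
        m = fit_preset(small_cohort, "model1")
        with pytest.raises(ValueError):
            odds_ratios(m)
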