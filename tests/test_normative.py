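"""Normative GLM fitting, Z-scoring, burden counting, calibration."""

import numpy as np
import pandas as pd
import pytest

from longconn.normative import (
    NormativeModel,
    NormativeModelSet,
    abnormal_burden,
    fit_normative_model,
    fit_normative_models,
    global_residual_table,
    zscore_patient,
)


def simulate_controls(rng, n=200, b0=3.0, b_age=0.0, b_sex=0.0, noise=1.0):
    ages = rng.uniform(5, 18, size=n)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    sex_num = (sexes == "female").astype(float)
    y = b0 + b_age * ages + b_sex * sex_num + rng.normal(0, noise, size=n)
    return y, ages, sexes


class TestFit:
    def test_noiseless_fit_rejected_for_zero_sd(self, rng):
        ages = rng.uniform(5, 18, size=20)
        sexes = np.array(["male", "female"] * 10)
        y = 1.0 + 2.0 * ages
        with pytest.raises(ValueError, match="constant in controls"):
            fit_normative_model(y, ages, sexes)

    def test_null_age_coefficient_within_ci(self, rng):
        y, ages, sexes = simulate_controls(rng, n=200)
        m = fit_normative_model(y, ages, sexes, feature="f")
        # 99% CI of the age slope under the null: |beta| < 2.576 * SE; SE ~ sd/(sqrt(n)*sd_age)
        se = 1.0 / (np.sqrt(200) * ages.std())
        assert abs(m.age_coefficient) < 3 * se
        assert 0.85 < m.control_residual_sd < 1.15

    def test_parameter_recovery(self, rng):
        y, ages, sexes = simulate_controls(rng, n=500, b0=2.0, b_age=0.4, b_sex=-1.5)
        m = fit_normative_model(y, ages, sexes)
        se_age = 1.0 / (np.sqrt(500) * ages.std())
        assert abs(m.age_coefficient - 0.4) < 3 * se_age
        assert abs(m.sex_coefficient - (-1.5)) < 3 * 2 / np.sqrt(500) * 2
        assert abs(m.intercept - 2.0) < 0.5

    def test_single_sex_rejected(self, rng):
        ages = rng.uniform(5, 18, size=30)
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="sex"):
            fit_normative_model(y, ages, np.repeat("male", 30))

    def test_constant_age_rejected(self, rng):
        y = rng.normal(size=30)
        sexes = np.array(["male", "female"] * 15)
        with pytest.raises(ValueError, match="age"):
            fit_normative_model(y, np.full(30, 10.0), sexes)

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_normative_model(
                rng.normal(size=4), rng.uniform(5, 18, 4), ["male", "female"] * 2
            )


class TestZScore:
    @pytest.fixture
    def fixture_model(self):
        return NormativeModel(
            feature="f", intercept=1.0, age_coefficient=2.0, sex_coefficient=0.0,
            control_residual_mean=0.0, control_residual_sd=2.0, age_range=(2.0, 20.0),
        )

    def test_fixture_arithmetic(self, fixture_model):
        # prediction at age 3 = 1 + 2*3 = 7; z = (9 - 7)/2 = 1
        assert zscore_patient(fixture_model, 9.0, 3.0, "male") == pytest.approx(1.0)

    def test_value_at_prediction_scores_minus_mean_over_sd(self, fixture_model):
        assert zscore_patient(fixture_model, 7.0, 3.0, "male") == pytest.approx(0.0)

    def test_training_controls_rescore_to_stored_z(self, rng):
        y, ages, sexes = simulate_controls(rng, n=100)
        m = fit_normative_model(y, ages, sexes)
        z = m.zscore(y, ages, sexes)
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_age_outside_range_warns(self, fixture_model):
        with pytest.warns(UserWarning, match="outside control range"):
            zscore_patient(fixture_model, 9.0, 1.0, "male")

    def test_affine_shift_moves_only_intercept(self, rng):
        y, ages, sexes = simulate_controls(rng, n=150, b_age=0.3)
        m1 = fit_normative_model(y, ages, sexes)
        m2 = fit_normative_model(y + 5.0, ages, sexes)
        assert m2.intercept == pytest.approx(m1.intercept + 5.0, abs=1e-8)
        assert m2.age_coefficient == pytest.approx(m1.age_coefficient, abs=1e-10)
        assert m2.zscore(y[0] + 5.0, ages[0], sexes[0]) == pytest.approx(
            m1.zscore(y[0], ages[0], sexes[0]), abs=1e-8
        )


class TestBurden:
    def test_no_abnormal_below_threshold(self):
        b = abnormal_burden(np.array([0.0, 1.9, -1.9]), 2.0)
        assert b.n_abnormal_total == 0

    def test_counts_each_direction(self):
        b = abnormal_burden(np.array([2.5, -3.0, 1.0]), 2.0)
        assert (b.n_abnormal_total, b.n_above, b.n_below) == (2, 1, 1)

    def test_exact_threshold_not_counted(self):
        b = abnormal_burden(np.array([2.0, -2.0]), 2.0)
        assert b.n_abnormal_total == 0

    def test_normal_tail_rate(self, rng):
        z = rng.standard_normal(20_000)
        b = abnormal_burden(z, 2.0)
        rate = b.n_abnormal_total / 20_000
        # 2*Phi(-2) = 0.0455; binomial 99% band for n = 20000
        assert abs(rate - 0.0455) < 2.576 * np.sqrt(0.0455 * 0.9545 / 20_000) + 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            abnormal_burden(np.array([0.0, np.nan]), 2.0)


class TestResidualTable:
    def test_controls_have_zero_mean_residuals(self, rng):
        y, ages, sexes = simulate_controls(rng, n=80, b_age=0.2)
        table = pd.DataFrame(
            {
                "subject_id": [f"c{i}" for i in range(80)],
                "timepoint": "control",
                "age": ages,
                "sex": sexes,
                "f": y,
            }
        )
        models = fit_normative_models(table[["f"]], ages, sexes)
        out = global_residual_table(table, models)
        assert out["residual"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_injected_shift_recovered(self, rng):
        y, ages, sexes = simulate_controls(rng, n=300, b_age=0.2)
        models = fit_normative_models(pd.DataFrame({"f": y}), ages, sexes)
        delta = 2.5
        y2, ages2, sexes2 = simulate_controls(rng, n=300, b_age=0.2)
        table = pd.DataFrame(
            {
                "subject_id": [f"p{i}" for i in range(300)],
                "timepoint": "early",
                "age": ages2,
                "sex": sexes2,
                "f": y2 + delta,
            }
        )
        out = global_residual_table(table, models)
        assert out["residual"].mean() == pytest.approx(delta, abs=0.25)

    def test_model_set_json_round_trip(self, rng, tmp_path):
        y, ages, sexes = simulate_controls(rng, n=60, b_age=0.3, b_sex=0.5)
        models = fit_normative_models(pd.DataFrame({"f": y}), ages, sexes)
        p = models.to_json(tmp_path / "models.json")
        back = NormativeModelSet.from_json(p)
        assert back["f"].age_coefficient == models["f"].age_coefficient
        assert back["f"].control_residual_sd == models["f"].control_residual_sd
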