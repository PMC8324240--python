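"""Risk-model contract: Cox recovery, binary classifiers, fixed scores."""

import numpy as np
import pandas as pd
import pytest

from strokescreen.config import GeneratorConfig
from strokescreen.cohort import generate_cohort
from strokescreen.exceptions import FitError, SchemaError
from strokescreen.metrics import auroc, calibration_table
from strokescreen.models import (
    BinaryRiskModel,
    CoxRiskModel,
    FixedLinearScore,
    fit_binary,
    fit_cox,
    recalibrate_fixed_score,
    refit_fixed_score,
    tune_hyperparameters,
)
from strokescreen.prep import BinaryDataset, SurvivalDataset, make_survival_dataset, split_cohort


def survival_dataset(features: pd.DataFrame, time, event, horizon=9.0):
    return SurvivalDataset(
        features=features,
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
        horizon=horizon,
        ids=np.arange(len(features)),
        role="train",
    )


def binary_dataset(features: pd.DataFrame, label, interval=(0.0, 9.0)):
    return BinaryDataset(
        features=features,
        label=np.asarray(label, dtype=int),
        interval=interval,
        ids=np.arange(len(features)),
        role="train",
    )


@pytest.fixture(scope="module")
def hr2_dataset():
    """Exponential survival with a single binary covariate at true HR = 2."""
    rng = np.random.default_rng(17)
    n = 50_000
    x = rng.integers(0, 2, n)
    h = 0.02 * 2.0**x
    t_event = rng.exponential(1.0 / h)
    time = np.minimum(t_event, 9.0)
    event = (t_event <= 9.0).astype(int)
    return survival_dataset(pd.DataFrame({"x": x.astype(float)}), time, event)


class TestCoxModel:
    def test_recovers_log_hazard_ratio_of_two(self, hr2_dataset):
        model = fit_cox(hr2_dataset)
        assert model.coef_["x"] == pytest.approx(np.log(2), abs=0.05)

    def test_null_coefficients_give_baseline_risk_for_everyone(self, hr2_dataset):
        model = fit_cox(hr2_dataset)
        model.coef_[:] = 0.0
        risks = model.predict_risk(hr2_dataset.features, 9.0)
        assert np.allclose(risks, risks[0])
        assert risks[0] == pytest.approx(1.0 - model.baseline_survival_at(9.0))

    def test_risk_monotone_in_horizon(self, hr2_dataset):
        model = fit_cox(hr2_dataset)
        x = hr2_dataset.features.iloc[:5]
        risks = np.column_stack([model.predict_risk(x, t) for t in (1.0, 3.0, 6.0, 9.0)])
        assert (np.diff(risks, axis=1) >= 0).all()
        assert ((risks >= 0) & (risks <= 1)).all()

    def test_predictions_rank_like_linear_predictor(self, hr2_dataset):
        from scipy.stats import spearmanr

        model = fit_cox(hr2_dataset)
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"x": rng.normal(size=200)})
        rho = spearmanr(model.linear_predictor(x), model.predict_risk(x, 9.0)).statistic
        assert rho == pytest.approx(1.0)

    def test_interval_risk_consistent_with_conditional_survival(self, hr2_dataset):
        model = fit_cox(hr2_dataset)
        x = hr2_dataset.features.iloc[:3]
        r09 = model.predict_risk(x, 9.0)
        r03 = model.predict_risk(x, 3.0)
        r39 = model.predict_interval_risk(x, 3.0, 9.0)
        # 1 - (1-r09) = 1 - (1-r03)(1-r39)
        assert np.allclose(1 - r09, (1 - r03) * (1 - r39))

    def test_too_few_events_rejected(self):
        ds = survival_dataset(pd.DataFrame({"x": [0.0, 1.0, 0.5]}), [1, 2, 3], [1, 0, 0])
        with pytest.raises(FitError):
            fit_cox(ds)

    def test_json_roundtrip_preserves_predictions(self, hr2_dataset, tmp_path):
        model = fit_cox(hr2_dataset)
        path = tmp_path / "cox.json"
        model.to_json(path)
        clone = CoxRiskModel.from_json(path)
        x = hr2_dataset.features.iloc[:50]
        assert np.allclose(model.predict_risk(x, 9.0), clone.predict_risk(x, 9.0))


class TestBinaryModels:
    def test_logistic_regression_separates_separable_toy(self):
        features = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]})
        ds = binary_dataset(features, [0, 0, 1, 1])
        model = fit_binary("lr", ds)
        assert auroc(model.predict_risk(features), ds.label) == 1.0

    def test_predictions_are_probabilities(self):
        rng = np.random.default_rng(2)
        features = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        label = (rng.random(500) < 0.3).astype(int)
        for spec in ("lr", "gbt"):
            p = fit_binary(spec, ds := binary_dataset(features, label)).predict_risk(features)
            assert ((p >= 0) & (p <= 1)).all() and np.isfinite(p).all()

    def test_single_class_training_rejected(self):
        features = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(FitError):
            fit_binary("lr", binary_dataset(features, [0, 0, 0]))

    def test_isotonic_svm_probability_monotone_in_margin(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 2))
        y = (x[:, 0] + 0.5 * rng.normal(size=400) > 0).astype(int)
        features = pd.DataFrame(x, columns=["a", "b"])
        model = fit_binary("svm", binary_dataset(features, y))
        p = model.predict_risk(features)
        # rank agreement with the single informative direction
        from scipy.stats import spearmanr

        assert spearmanr(p, x[:, 0]).statistic > 0.97

    def test_gbt_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        features = pd.DataFrame(rng.normal(size=(800, 4)), columns=list("abcd"))
        label = (rng.random(800) < 0.2).astype(int)
        ds = binary_dataset(features, label)
        p1 = fit_binary("gbt", ds, seed=5).predict_risk(features)
        p2 = fit_binary("gbt", ds, seed=5).predict_risk(features)
        assert np.array_equal(p1, p2)


@pytest.fixture(scope="module")
def default_training_data():
    cfg = GeneratorConfig(n_individuals=50_000, early_censor_rate=0.0, seed=31)
    cohort, _ = generate_cohort(cfg)
    roles = split_cohort(cohort, fractions=(1.0, 0.0, 0.0), seed=1)
    return cfg, cohort, make_survival_dataset(cohort, roles, "train")


def generator_score(cfg) -> FixedLinearScore:
    """A fixed linear score using the generator's own coefficients."""
    coef = {
        "age": cfg.beta["age_z"] / cfg.age_sd,
        "sbp": cfg.beta["sbp_z"] / cfg.sbp_sd,
        "current_smoker": cfg.beta["current_smoker"],
        "bp_treatment": cfg.beta["bp_treatment"],
        "diabetes": cfg.beta["diabetes"],
        "chd": cfg.beta["chd"],
    }
    centering = {"age": cfg.age_mean, "sbp": cfg.sbp_mean}
    return FixedLinearScore(coef, centering, [9.0], [0.92])


class TestFixedLinearScore:
    def test_recalibration_in_the_large(self, default_training_data):
        cfg, cohort, train = default_training_data
        recal = recalibrate_fixed_score(generator_score(cfg), train)
        mean_risk = recal.predict_risk(train.features, 9.0).mean()
        assert mean_risk == pytest.approx(cohort["event"].mean(), abs=0.005)

    def test_halved_baseline_risk_detected_as_underestimation(self, default_training_data):
        cfg, _, train = default_training_data
        recal = recalibrate_fixed_score(generator_score(cfg), train)
        half_risk = 1.0 - np.sqrt(recal.baseline_survival)  # halves -log S0, ~halves risk
        miscal = FixedLinearScore(
            recal.coefficients, recal.centering, recal.baseline_times,
            1.0 - half_risk / 2.0,
        )
        res = calibration_table(miscal, train)
        assert (res.table["obs"] > res.table["p_mean"]).all()
        assert res.chi2 > calibration_table(recal, train).chi2

    def test_refitted_mode_equals_cox_on_reduced_variables(self, default_training_data):
        cfg, _, train = default_training_data
        score = generator_score(cfg)
        refit = refit_fixed_score(score, train)
        direct = fit_cox(
            SurvivalDataset(
                features=train.features[score.variables],
                time=train.time, event=train.event,
                horizon=train.horizon, ids=train.ids, role=train.role,
            )
        )
        pd.testing.assert_series_equal(refit.coef_, direct.coef_)

    def test_as_published_mode_never_reestimates(self, default_training_data):
        cfg, _, train = default_training_data
        score = generator_score(cfg)
        before = dict(score.coefficients)
        score.fit(train)
        assert score.coefficients == before and score.mode == "as_published"

    def test_missing_variable_is_schema_error(self, default_training_data):
        cfg, _, train = default_training_data
        score = generator_score(cfg)
        score.coefficients["not_a_column"] = 1.0
        with pytest.raises(SchemaError, match="not_a_column"):
            score.predict_risk(train.features, 9.0)


@pytest.fixture(scope="module")
def tuning_data():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(1200, 3))
    y = (rng.random(1200) < 1 / (1 + np.exp(-1.5 * x[:, 0]))).astype(int)
    return binary_dataset(pd.DataFrame(x, columns=list("abc")), y)


class TestHyperparameterTuning:

    def test_singleton_grid_chosen(self, tuning_data):
        sel = tune_hyperparameters("lr", tuning_data, k=3, grid=[{"C": 0.7}])
        assert sel.chosen == {"C": 0.7}

    def test_dominant_setting_chosen(self, tuning_data):
        # an L1 penalty strong enough to zero every coefficient yields
        # constant predictions (chance AUROC), strictly dominated per fold
        crippled = {"C": 1e-4, "l1_ratio": 1.0, "solver": "saga"}
        sel = tune_hyperparameters(
            "lr", tuning_data, k=3, grid=[crippled, {"C": 1.0}], seed=2
        )
        assert sel.chosen == {"C": 1.0}
        assert sel.scores[1] > sel.scores[0]

    def test_selection_reproducible_with_seed(self, tuning_data):
        grid = [{"max_leaf_nodes": 4}, {"max_leaf_nodes": 15}]
        a = tune_hyperparameters("gbt", tuning_data, k=3, grid=grid, seed=7)
        b = tune_hyperparameters("gbt", tuning_data, k=3, grid=grid, seed=7)
        assert a.chosen_index == b.chosen_index and a.scores == b.scores
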