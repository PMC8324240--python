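"""Discrimination/calibration metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

from helpers import brute_force_auroc
from strokescreen.exceptions import UndefinedMetricError
from strokescreen.metrics import (
    auroc,
    bootstrap_ci,
    calibration_table,
    hosmer_lemeshow,
    km_survival_at,
    nam_dagostino,
    risk_groups,
)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_chance(self):
        assert auroc([0.3] * 10, [1, 0] * 5) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_pair_count(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(10, 200)
            scores = rng.choice(np.round(rng.random(8), 2), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_score_negation_symmetry(self, labels):
        labels = np.asarray(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.linspace(0, 1, len(labels))  # tie-free
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)


class TestHosmerLemeshow:
    def test_exactly_calibrated_groups_give_zero(self):
        # each decile's label mean equals its predicted mean exactly
        ps = np.arange(1, 11) / 20.0  # 0.05 .. 0.50, 20*p integral
        pred = np.repeat(ps, 20)
        labels = np.concatenate([[1] * int(20 * p) + [0] * (20 - int(20 * p)) for p in ps])
        res = hosmer_lemeshow(pred, labels, n_groups=10)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 8

    def test_two_group_hand_computation(self):
        # 50 at p=0.1 with 10 events, 50 at p=0.3 with 10 events:
        # 25/4.5 + 25/10.5 = 7.936507...
        pred = np.array([0.1] * 50 + [0.3] * 50)
        labels = np.array([1] * 10 + [0] * 40 + [1] * 10 + [0] * 40)
        res = hosmer_lemeshow(pred, labels, n_groups=2)
        assert res.chi2 == pytest.approx(25 / 4.5 + 25 / 10.5, abs=1e-12)
        assert res.chi2 == pytest.approx(7.9365079365, abs=1e-9)

    def test_invariant_to_within_group_permutation(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0.05, 0.6, 400)
        labels = rng.integers(0, 2, 400)
        base = hosmer_lemeshow(pred, labels).chi2
        groups = risk_groups(pred)
        perm = np.arange(400)
        for g in range(10):
            idx = np.flatnonzero(groups == g)
            perm[idx] = rng.permutation(idx)
        assert hosmer_lemeshow(pred[perm], labels[perm]).chi2 == pytest.approx(base)

    def test_group_sizes_partition_input(self):
        pred = np.random.default_rng(0).random(1003)
        groups = risk_groups(pred, 10)
        sizes = np.bincount(groups)
        assert sizes.sum() == 1003 and sizes.max() - sizes.min() <= 1

    def test_degenerate_group_flagged_not_fatal(self):
        pred = np.array([0.0] * 10 + [0.5] * 10)
        labels = np.array([0] * 10 + [1] * 5 + [0] * 5)
        res = hosmer_lemeshow(pred, labels, n_groups=2)
        assert res.flags and np.isfinite(res.chi2)


class TestKaplanMeier:
    def test_matches_lifelines_on_random_censored_data(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = rng.integers(5, 120)
            time = np.round(rng.exponential(5.0, n), 1) + 0.1  # induce ties
            event = rng.integers(0, 2, n)
            t = float(rng.uniform(0.5, 12.0))
            kmf = KaplanMeierFitter().fit(time, event)
            s, _ = km_survival_at(time, event, t)
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
            )

    def test_hand_product(self):
        # events at 1 and 2 among 4 at risk: (1 - 1/4)(1 - 1/3) = 1/2
        s, _ = km_survival_at([1.0, 2.0, 3.0, 9.5], [1, 1, 0, 0], 9.0)
        assert s == pytest.approx(0.5)

    def test_greenwood_variance_hand_value(self):
        # var = S^2 * [1/(4*3) + 1/(3*2)] = 0.25 * 0.25
        s, var = km_survival_at([1.0, 2.0, 3.0, 9.5], [1, 1, 0, 0], 9.0)
        assert var == pytest.approx(0.25 * (1 / 12 + 1 / 6))


class TestNamDagostino:
    def test_single_group_observed_risk_is_km(self):
        res = nam_dagostino(
            [0.4, 0.4, 0.4, 0.4], [1.0, 2.0, 3.0, 9.5], [1, 1, 0, 0], 9.0, n_groups=1
        )
        assert res.table["obs"].iloc[0] == pytest.approx(0.5)

    def test_equals_hosmer_lemeshow_without_censoring(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(60, 300)
            pred = rng.uniform(0.02, 0.6, n)
            labels = (rng.random(n) < pred).astype(int)
            if labels.min() == labels.max():
                continue
            time = np.where(labels == 1, rng.uniform(0.1, 8.9, n), 9.0)
            nd = nam_dagostino(pred, time, labels, 9.0)
            hl = hosmer_lemeshow(pred, labels)
            assert nd.chi2 == pytest.approx(hl.chi2, abs=1e-10)
            assert nd.df == 9 and hl.df == 8  # df conventions differ

    def test_group_without_horizon_followup_merged_and_flagged(self):
        pred = np.array([0.1] * 10 + [0.9] * 10)
        time = np.array([9.0] * 10 + [1.0] * 10)
        event = np.array([0] * 10 + [0] * 10)  # high-risk group all censored early
        res = nam_dagostino(pred, time, event, 9.0, n_groups=2)
        assert res.flags
        assert len(res.table) == 1


class TestCalibrationTable:
    class _TruthModel:
        """Predicts a stored per-row risk column."""

        def predict_risk(self, features, horizon=None):
            return features["truth"].to_numpy()

    def test_ideal_predictions_sit_on_diagonal(self, big_cohort):
        from strokescreen.prep import SurvivalDataset

        _, cohort, truth = big_cohort
        import pandas as pd

        ds = SurvivalDataset(
            features=pd.DataFrame({"truth": truth["true_risk"].to_numpy()}),
            time=cohort["time"].to_numpy(),
            event=cohort["event"].to_numpy(),
            horizon=9.0,
            ids=cohort["id"].to_numpy(),
            role="validation",
        )
        res = calibration_table(self._TruthModel(), ds)
        gaps = (res.table["obs"] - res.table["p_mean"]).abs()
        se = np.sqrt(res.table["p_mean"] * (1 - res.table["p_mean"]) / res.table["n"])
        assert (gaps <= np.maximum(0.01, 3 * se)).all()

    def test_halved_predictions_fall_below_observed_in_every_decile(self, big_cohort):
        from strokescreen.prep import SurvivalDataset
        import pandas as pd

        _, cohort, truth = big_cohort
        ds = SurvivalDataset(
            features=pd.DataFrame({"truth": truth["true_risk"].to_numpy() / 2.0}),
            time=cohort["time"].to_numpy(),
            event=cohort["event"].to_numpy(),
            horizon=9.0,
            ids=cohort["id"].to_numpy(),
            role="validation",
        )
        res = calibration_table(self._TruthModel(), ds)
        assert (res.table["obs"] > res.table["p_mean"]).all()


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        ci = bootstrap_ci(lambda x: 3.14, np.arange(50), n_resamples=20, seed=0)
        assert ci.lower == ci.upper == ci.point == 3.14

    def test_single_resample(self):
        data = np.arange(10.0)
        ci = bootstrap_ci(np.mean, data, n_resamples=1, seed=4)
        assert ci.lower == ci.upper

    def test_deterministic_given_seed(self):
        data = np.random.default_rng(1).random(200)
        a = bootstrap_ci(np.mean, data, n_resamples=100, seed=9)
        b = bootstrap_ci(np.mean, data, n_resamples=100, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_undefined_resamples_redrawn_and_counted(self):
        labels = np.array([1, 0, 0, 0, 0])
        scores = np.array([0.9, 0.1, 0.2, 0.3, 0.4])
        ci = bootstrap_ci(lambda s, l: auroc(s, l), (scores, labels), n_resamples=200, seed=2)
        assert ci.n_redrawn > 0
        assert np.isfinite(ci.lower) and np.isfinite(ci.upper)

    def test_auroc_interval_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        widths = {}
        for n in (500, 2000, 8000):
            scores = rng.random(n)
            labels = (rng.random(n) < scores).astype(int)
            ci = bootstrap_ci(lambda s, l: auroc(s, l), (scores, labels),
                              n_resamples=300, seed=1)
            widths[n] = ci.upper - ci.lower
        assert widths[500] > widths[2000] > widths[8000]
        assert 2.0 < widths[500] / widths[8000] < 8.0  # ~ sqrt(16) = 4
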