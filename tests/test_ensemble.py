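import numpy as np
import pandas as pd
import pytest

from riverch4 import ensemble as ens
from riverch4.synth import ALL_PREDICTORS, NUTRIENTS, simulate_observations
from tests.conftest import SMALL_LEARNERS, single_signal_params


class _Const:
    """Stub learner predicting a constant log value."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _stub_ensemble(values=(1.0, 2.0, 3.0)) -> ens.TrainedMonthlyEnsemble:
    frame = pd.DataFrame({"TP": [0.1, 0.2], "NH4N": [0.1, 0.2]})
    e = ens.TrainedMonthlyEnsemble(
        month=1, response="ln_flux", predictors=("TP", "NH4N"),
        log_predictors=("TP", "NH4N"),
        X_frame=frame, y_log=np.zeros(2),
        train_index=np.array([0]), test_index=np.array([1]),
    )
    for name, v in zip(ens.LEARNER_NAMES, values):
        e.learners[name] = _Const(v)
    return e


class TestSelectPredictors:
    def test_self_predictor_kept(self):
        obs = simulate_observations(300, single_signal_params(seed=1, noise=0.0))
        # TP drives the response exactly -> |r| = 1 > threshold
        selected, report = ens.select_predictors(obs, "ln_flux", keep_list=())
        assert "TP" in selected
        assert report.loc[report.predictor == "TP", "r"].abs().iloc[0] > 0.99

    def test_noise_predictor_dropped(self):
        obs = simulate_observations(5000, single_signal_params(seed=2, noise=0.3))
        selected, report = ens.select_predictors(obs, "ln_flux", keep_list=())
        # elevation has no effect in this world
        assert "elevation" not in selected

    def test_keep_list_member_tagged_mechanistic(self):
        obs = simulate_observations(5000, single_signal_params(seed=3, noise=0.3))
        selected, report = ens.select_predictors(
            obs, "ln_flux", keep_list=("precipitation",)
        )
        row = report.loc[report.predictor == "precipitation"].iloc[0]
        assert "precipitation" in selected
        assert row["reason"] == "mechanistic"

    def test_empty_candidates_rejected(self, observations):
        with pytest.raises(ValueError):
            ens.select_predictors(observations, "ln_flux", candidates=())


class TestTuneHyperparameters:
    @staticmethod
    def _xy(n=60, seed=0):
        r = np.random.default_rng(seed)
        X = r.normal(size=(n, 2))
        y = X[:, 0] + 0.1 * r.normal(size=n)
        return X, y

    def test_singleton_grid(self):
        X, y = self._xy()
        best = ens.tune_hyperparameters(
            X, y, "forest", {"n_estimators": [30]}, folds=5
        )
        assert best == {"n_estimators": 30}

    def test_determinism(self):
        X, y = self._xy()
        grid = {"n_estimators": [20, 40], "min_samples_leaf": [1, 4]}
        a = ens.tune_hyperparameters(X, y, "forest", grid, folds=5, seed=3)
        b = ens.tune_hyperparameters(X, y, "forest", grid, folds=5, seed=3)
        assert a == b

    def test_better_setting_wins(self):
        # linear signal: an un-regularized SVR with adequate C beats C ~ 0
        X, y = self._xy(n=200, seed=1)
        best = ens.tune_hyperparameters(
            X, y, "svr", {"C": [1e-6, 10.0]}, folds=5
        )
        assert best["C"] == 10.0

    def test_n_below_folds(self):
        X, y = self._xy(n=5)
        with pytest.raises(ValueError):
            ens.tune_hyperparameters(X, y, "forest", {"n_estimators": [10]}, folds=10)

    def test_empty_grid(self):
        X, y = self._xy()
        with pytest.raises(ValueError):
            ens.tune_hyperparameters(X, y, "forest", {}, folds=5)


class TestMonthWindow:
    def test_january_wraps(self):
        assert ens.month_window(1) == (12, 1, 2)

    def test_june(self):
        assert ens.month_window(6) == (5, 6, 7)

    def test_december_wraps(self):
        assert ens.month_window(12) == (11, 12, 1)

    def test_invalid_month(self):
        with pytest.raises(ValueError):
            ens.month_window(13)


class TestFitMonthlyEnsemble:
    def test_window_rows_used(self, observations):
        model = ens.fit_monthly_ensemble(
            observations, 1, "ln_flux", learner_params=SMALL_LEARNERS, seed=0
        )
        assert set(model.X_frame["month"]).issubset({12, 1, 2})

    def test_below_minimum_names_month(self, observations):
        tiny = observations.head(4)
        with pytest.raises(ValueError, match="month 3"):
            ens.fit_monthly_ensemble(tiny, 3, "ln_flux", min_n=10)

    def test_split_is_seeded(self, observations):
        a = ens.fit_monthly_ensemble(
            observations, 2, "ln_flux", learner_params=SMALL_LEARNERS, seed=5
        )
        b = ens.fit_monthly_ensemble(
            observations, 2, "ln_flux", learner_params=SMALL_LEARNERS, seed=5
        )
        np.testing.assert_array_equal(a.train_index, b.train_index)
        np.testing.assert_array_equal(a.test_index, b.test_index)

    def test_noiseless_linear_recovery(self):
        obs = simulate_observations(1500, single_signal_params(seed=4, noise=0.0))
        selected, _ = ens.select_predictors(obs, "ln_flux", keep_list=())
        model = ens.fit_monthly_ensemble(
            obs, 6, "ln_flux", predictors=selected, seed=0
        )
        r2 = model.holdout_r2()
        for name in (*ens.LEARNER_NAMES, "ensemble"):
            assert r2[name] >= 0.99, name


class TestEnsemblePredict:
    def test_mean_then_exponential(self):
        e = _stub_ensemble((1.0, 2.0, 3.0))
        frame = pd.DataFrame({"TP": [0.1], "NH4N": [0.1]})
        out = ens.ensemble_predict(e, frame, output="natural")
        assert out[0] == pytest.approx(np.exp(2.0))

    def test_identical_members_equal_single(self):
        e = _stub_ensemble((1.7, 1.7, 1.7))
        frame = pd.DataFrame({"TP": [0.1], "NH4N": [0.1]})
        out = ens.ensemble_predict(e, frame, output="log")
        assert out[0] == pytest.approx(1.7)

    def test_missing_predictor_listed(self):
        e = _stub_ensemble()
        with pytest.raises(KeyError, match="NH4N"):
            ens.ensemble_predict(e, pd.DataFrame({"TP": [0.1]}))

    def test_monotone_along_tp_ramp(self):
        obs = simulate_observations(1200, single_signal_params(seed=6, noise=0.1))
        model = ens.fit_monthly_ensemble(
            obs, 6, "ln_flux", predictors=("TP",), learner_params=SMALL_LEARNERS, seed=0
        )
        # ramp inside the training range; trees are only weakly monotone so
        # allow negligible local wiggles
        lo, hi = obs["TP"].quantile([0.05, 0.95])
        ramp = pd.DataFrame({"TP": np.geomspace(lo, hi, 15)})
        for name in ("forest", "boosting"):
            X = model.design(ramp).to_numpy()
            pred = model.learners[name].predict(X)
            assert (np.diff(pred) >= -0.02).all(), name
            assert pred[-1] > pred[0], name


class TestLoocv:
    def test_exact_fit_count(self):
        calls = []

        class Counting:
            def fit(self, X, y):
                calls.append(1)
                self.mean = y.mean()
                return self

            def predict(self, X):
                return np.full(len(X), self.mean)

        X = np.arange(5.0)[:, None]
        y = np.arange(5.0)
        res = ens.loocv_evaluate(X, y, Counting)
        assert len(calls) == 5
        assert res["n_fits"] == 5

    def test_perfect_linear_data(self):
        from sklearn.linear_model import LinearRegression

        X = np.linspace(0, 1, 20)[:, None]
        y = 2 * X[:, 0] + 1
        res = ens.loocv_evaluate(X, y, LinearRegression)
        assert res["r2"] == pytest.approx(1.0, abs=1e-12)
        assert res["rmse"] == pytest.approx(0.0, abs=1e-10)

    def test_null_data_low_r2(self):
        from sklearn.linear_model import LinearRegression

        r = np.random.default_rng(0)
        X = r.normal(size=(300, 3))
        y = r.normal(size=300)
        res = ens.loocv_evaluate(X, y, LinearRegression)
        assert res["r2"] <= 0.1

    def test_too_small(self):
        with pytest.raises(ValueError):
            ens.loocv_evaluate(np.zeros((2, 1)), np.zeros(2), object)

    def test_cap_limits_fits(self):
        from sklearn.linear_model import LinearRegression

        X = np.linspace(0, 1, 50)[:, None]
        y = X[:, 0]
        res = ens.loocv_evaluate(X, y, LinearRegression, cap=10, seed=1)
        assert res["n_fits"] == 10


@pytest.fixture(scope="module")
def trained():
    obs = simulate_observations(800, single_signal_params(seed=8, noise=0.2))
    return ens.fit_monthly_ensemble(
        obs, 6, "ln_flux",
        predictors=("TP", "NH4N", "elevation", "slope"),
        learner_params=SMALL_LEARNERS, seed=0,
    )


class TestFuseImportance:
    def test_dominant_signal_ranks_first_with_score_one(self, trained):
        table = ens.fuse_importance(trained, seed=0)
        assert table["predictor"].iloc[0] == "TP"
        assert table["fused"].iloc[0] == pytest.approx(1.0)

    def test_fused_in_unit_interval(self, trained):
        table = ens.fuse_importance(trained, seed=0)
        assert ((table["fused"] >= 0) & (table["fused"] <= 1)).all()

    def test_minmax_affine_invariance(self, rng):
        v = rng.normal(size=10)
        np.testing.assert_allclose(ens._minmax(3.5 * v + 2.0), ens._minmax(v), atol=1e-12)

    def test_untrained_rejected(self):
        e = ens.TrainedMonthlyEnsemble(
            month=1, response="ln_flux", predictors=("TP",), log_predictors=()
        )
        with pytest.raises(ValueError):
            ens.fuse_importance(e)

    def test_all_noise_ranking_unstable(self):
        # with no signal anywhere, the top predictor varies across seeds
        tops = set()
        for seed in range(4):
            params = single_signal_params(seed=30 + seed, beta=0.0, noise=0.5)
            obs = simulate_observations(250, params)
            model = ens.fit_monthly_ensemble(
                obs, 6, "ln_flux",
                predictors=("TP", "NH4N", "elevation", "slope", "soc"),
                learner_params=SMALL_LEARNERS, seed=seed,
            )
            tops.add(ens.fuse_importance(model, seed=seed)["predictor"].iloc[0])
        assert len(tops) >= 2


class TestAblation:
    def test_nutrients_carry_all_signal(self):
        obs = simulate_observations(700, single_signal_params(seed=9, noise=0.2))
        res = ens.ablation_compare(
            obs, "ln_flux",
            predictors=("TP", "NH4N", "TN", "NO3N", "elevation", "slope", "soc",
                        "precipitation", "gpp"),
            learner_params=SMALL_LEARNERS, seed=0,
        )
        assert res["r2_full"] > 0.8
        assert res["r2_no_nutrient"] < 0.2
        assert res["r2_swapped"] > 0.8

    def test_uninformative_nutrients_small_delta(self):
        # response driven by elevation only; nutrients are noise
        params = single_signal_params(seed=10, beta=0.0, noise=0.2)
        params = params.__class__(**{**params.to_dict(), "terrestrial_betas": {"elevation": 0.004}})
        obs = simulate_observations(700, params)
        res = ens.ablation_compare(
            obs, "ln_flux",
            predictors=("TP", "NH4N", "TN", "NO3N", "elevation", "slope"),
            learner_params=SMALL_LEARNERS, seed=0,
        )
        assert abs(res["delta_r2"]) < 0.1

    def test_identical_sets_zero_delta(self, observations):
        res = ens.ablation_compare(
            observations.head(200), "ln_flux",
            predictors=("elevation", "slope", "soc"),
            nutrient_predictors=(),
            learner_params=SMALL_LEARNERS, seed=0,
        )
        assert res["delta_r2"] == 0.0

    def test_missing_nutrient_column(self, observations):
        with pytest.raises(KeyError):
            ens.ablation_compare(
                observations.drop(columns=["TP"]), "ln_flux",
                learner_params=SMALL_LEARNERS,
            )


class TestPartialDependence:
    def test_constant_model_flat(self):
        e = _stub_ensemble((1.0, 1.0, 1.0))
        curve = ens.partial_dependence(e, "TP", [0.1, 1.0, 10.0])
        assert curve["mean_prediction"].nunique() == 1

    def test_single_point_grid(self):
        e = _stub_ensemble()
        curve = ens.partial_dependence(e, "TP", [0.5])
        assert len(curve) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ens.partial_dependence(_stub_ensemble(), "TP", [])

    def test_unknown_predictor_rejected(self):
        with pytest.raises(KeyError):
            ens.partial_dependence(_stub_ensemble(), "DOC", [1.0])

    def test_linear_shape_recovery(self):
        obs = simulate_observations(1200, single_signal_params(seed=12, noise=0.1))
        model = ens.fit_monthly_ensemble(
            obs, 6, "ln_flux", predictors=("TP",), learner_params=SMALL_LEARNERS, seed=0
        )
        lo, hi = obs["TP"].quantile([0.1, 0.9])
        grid = np.geomspace(lo, hi, 9)
        curve = ens.partial_dependence(model, "TP", grid, output="log")
        # log-scale PD should be close to linear in ln TP with slope ~0.5
        slope, intercept = np.polyfit(np.log(grid), curve["mean_prediction"], 1)
        assert slope == pytest.approx(0.5, abs=0.12)
        resid = curve["mean_prediction"] - (slope * np.log(grid) + intercept)
        assert np.abs(resid).max() < 0.12


class TestEnsembleProperty:
    def test_ensemble_beats_worst_member(self):
        wins = 0
        for seed in range(5):
            obs = simulate_observations(600, single_signal_params(seed=40 + seed, noise=0.3))
            model = ens.fit_monthly_ensemble(
                obs, 6, "ln_flux", predictors=("TP", "NH4N", "elevation"),
                learner_params=SMALL_LEARNERS, seed=seed,
            )
            r2 = model.holdout_r2()
            worst = min(r2[name] for name in ens.LEARNER_NAMES)
            wins += r2["ensemble"] >= worst
        assert wins >= 4
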