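"""Monthly three-learner ensembles for ln CH4 concentration and ln flux.

Each calendar month gets an ensemble of a random forest, a gradient-boosted
tree model and an RBF support-vector regressor, trained on the focal month
plus its two adjacent months (wrapping across the year boundary) with a
seeded 70/30 split.  Predictions are averaged in log space and
exponentiated.  Variable importance is fused across the three algorithms
after min-max normalization.

Tree importances stand in for gain/SHAP attributions and permutation
importance covers the forest and the SVR, keeping the three importance
routes algorithm-specific.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from riverch4.synth import ALL_PREDICTORS, NUTRIENTS

LEARNER_NAMES: tuple[str, ...] = ("forest", "boosting", "svr")

#: Predictors stored/modelled post-log-transform (strongly right-skewed).
DEFAULT_LOG_PREDICTORS: tuple[str, ...] = NUTRIENTS + ("population_density",)

#: Terrestrial variables kept regardless of correlation strength because of
#: their mechanistic role.
DEFAULT_KEEP_LIST: tuple[str, ...] = (
    "precipitation",
    "gpp",
    "npp",
    "soil_respiration",
)

RESPONSE_COLUMNS: dict[str, str] = {"ln_flux": "diff_flux", "ln_conc": "ch4_conc"}

_DEFAULT_LEARNER_PARAMS: dict[str, dict] = {
    "forest": {"n_estimators": 200, "min_samples_leaf": 2},
    "boosting": {"n_estimators": 300, "learning_rate": 0.1, "max_depth": 3},
    "svr": {"C": 100.0, "epsilon": 0.01, "gamma": "scale"},
}


def make_learner(name: str, params: Mapping | None = None, seed: int = 0):
    """Fresh unfitted learner of the given kind.

    The SVR standardizes both features and target internally so its default
    ``C``/``epsilon`` behave across response scales.
    """
    p = dict(_DEFAULT_LEARNER_PARAMS[name])
    if params:
        p.update(params)
    if name == "forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    if name == "boosting":
        return GradientBoostingRegressor(random_state=seed, **p)
    if name == "svr":
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), SVR(**p)),
            transformer=StandardScaler(),
        )
    raise ValueError(f"unknown learner {name!r}")


# ---------------------------------------------------------------------------
# Design matrix helpers
# ---------------------------------------------------------------------------


def build_design(
    frame: pd.DataFrame,
    predictors: Sequence[str],
    log_predictors: Sequence[str] = DEFAULT_LOG_PREDICTORS,
) -> pd.DataFrame:
    """Predictor matrix in declared order, skewed columns log-transformed."""
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise KeyError(f"missing predictors: {missing}")
    X = frame[list(predictors)].astype(float).copy()
    for col in predictors:
        if col in log_predictors:
            vals = X[col].to_numpy()
            if np.any(vals <= 0):
                vals = np.clip(vals, 1e-12, None)
            X[col] = np.log(vals)
    return X


def response_vector(frame: pd.DataFrame, response: str) -> np.ndarray:
    """ln of the natural-scale response column for ``response``."""
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response {response!r}")
    vals = frame[RESPONSE_COLUMNS[response]].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("response values must be finite and > 0 for log modelling")
    return np.log(vals)


# ---------------------------------------------------------------------------
# Predictor selection
# ---------------------------------------------------------------------------


def select_predictors(
    observations: pd.DataFrame,
    response: str,
    candidates: Sequence[str] = ALL_PREDICTORS,
    *,
    threshold: float = 0.1,
    keep_list: Sequence[str] = DEFAULT_KEEP_LIST,
    log_predictors: Sequence[str] = DEFAULT_LOG_PREDICTORS,
) -> tuple[list[str], pd.DataFrame]:
    """Correlation filter |r| > threshold plus a mechanistic keep-list.

    Returns the selected predictor list (candidate order preserved) and a
    report with per-candidate r, n and the selection reason.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate predictor set is empty")
    y = response_vector(observations, response)
    rows = []
    selected = []
    for cand in candidates:
        if cand not in observations.columns:
            raise KeyError(f"candidate predictor {cand!r} not in table")
        x = build_design(observations, [cand], log_predictors)[cand].to_numpy()
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() >= 3 and np.std(x[mask]) > 0:
            r = float(stats.pearsonr(x[mask], y[mask]).statistic)
        else:
            r = np.nan
        keep = False
        reason = "dropped"
        if np.isfinite(r) and abs(r) > threshold:
            keep, reason = True, "correlation"
        elif cand in keep_list:
            keep, reason = True, "mechanistic"
        if keep:
            selected.append(cand)
        rows.append({"predictor": cand, "r": r, "n": int(mask.sum()),
                     "selected": keep, "reason": reason})
    return selected, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    # itertools.product over insertion-ordered keys: first-in-grid wins ties
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune_hyperparameters(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    learner_name: str,
    grid: Mapping[str, Sequence],
    *,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Grid point minimizing the mean cross-validated squared residual.

    Ties are broken by first-in-grid order; fold assignment is seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if len(y) < folds:
        raise ValueError(f"n={len(y)} is below the number of folds ({folds})")
    points = _grid_points(grid)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_params, best_score = None, np.inf
    for point in points:
        residuals = []
        for train_idx, test_idx in splits:
            model = make_learner(learner_name, point, seed=seed)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            residuals.append((y[test_idx] - pred) ** 2)
        score = float(np.concatenate(residuals).mean())
        if score < best_score:
            best_params, best_score = point, score
    assert best_params is not None
    return best_params


# ---------------------------------------------------------------------------
# Monthly ensembles
# ---------------------------------------------------------------------------


def month_window(month: int) -> tuple[int, int, int]:
    """The focal month with its two adjacent months, wrapping over the year."""
    if month not in range(1, 13):
        raise ValueError(f"month must be in 1..12, got {month}")
    return ((month - 2) % 12 + 1, month, month % 12 + 1)


@dataclass
class TrainedMonthlyEnsemble:
    """Three fitted learners for one calendar month and one response."""

    month: int
    response: str
    predictors: tuple[str, ...]
    log_predictors: tuple[str, ...]
    learners: dict = field(default_factory=dict)
    chosen_params: dict = field(default_factory=dict)
    seed: int = 0
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None
    X_frame: pd.DataFrame | None = None  # raw (pre-log) window predictors
    y_log: np.ndarray | None = None

    @property
    def is_trained(self) -> bool:
        return all(name in self.learners for name in LEARNER_NAMES)

    def design(self, frame: pd.DataFrame) -> pd.DataFrame:
        return build_design(frame, self.predictors, self.log_predictors)

    def holdout_r2(self) -> dict[str, float]:
        """Held-out R2 per learner plus the log-space ensemble mean."""
        X_test = self.design(self.X_frame.iloc[self.test_index]).to_numpy()
        y_test = self.y_log[self.test_index]
        out = {}
        preds = []
        for name in LEARNER_NAMES:
            p = self.learners[name].predict(X_test)
            preds.append(p)
            out[name] = float(r2_score(y_test, p))
        out["ensemble"] = float(r2_score(y_test, np.mean(preds, axis=0)))
        return out


def fit_monthly_ensemble(
    observations: pd.DataFrame,
    month: int,
    response: str,
    *,
    predictors: Sequence[str] = ALL_PREDICTORS,
    log_predictors: Sequence[str] = DEFAULT_LOG_PREDICTORS,
    seed: int = 0,
    min_n: int = 5,
    test_fraction: float = 0.3,
    learner_params: Mapping[str, Mapping] | None = None,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    tune_folds: int = 10,
) -> TrainedMonthlyEnsemble:
    """Fit the three learners for one month on its three-month window.

    ``grids`` optionally maps learner name to a hyperparameter grid tuned by
    seeded k-fold CV on the training split; otherwise ``learner_params``
    (or package defaults) are used directly.
    """
    window = month_window(month)
    frame = observations.loc[observations["month"].isin(window)].reset_index(drop=True)
    if len(frame) < max(min_n, 3):
        raise ValueError(
            f"month {month}: only {len(frame)} observations in window {window}, "
            f"minimum is {max(min_n, 3)}"
        )
    X_frame = frame
    X = build_design(frame, predictors, log_predictors).to_numpy()
    y = response_vector(frame, response)

    rng = np.random.default_rng([seed, month, 0 if response == "ln_flux" else 1])
    perm = rng.permutation(len(frame))
    n_test = max(1, int(round(test_fraction * len(frame))))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])

    ens = TrainedMonthlyEnsemble(
        month=month,
        response=response,
        predictors=tuple(predictors),
        log_predictors=tuple(log_predictors),
        seed=seed,
        train_index=train_idx,
        test_index=test_idx,
        X_frame=X_frame,
        y_log=y,
    )
    for name in LEARNER_NAMES:
        params = dict((learner_params or {}).get(name, {}))
        if grids and name in grids and grids[name]:
            folds = min(tune_folds, len(train_idx))
            tuned = tune_hyperparameters(
                X[train_idx], y[train_idx], name, grids[name], folds=folds, seed=seed
            )
            params.update(tuned)
        model = make_learner(name, params, seed=seed)
        model.fit(X[train_idx], y[train_idx])
        ens.learners[name] = model
        ens.chosen_params[name] = params
    return ens


class MeanLogEnsemble:
    """sklearn-style wrapper: fit the three learners, predict their mean.

    Operates entirely in the caller's response space (log space in the
    pipeline); used for LOOCV and ablation where a single estimator-like
    object is convenient.
    """

    def __init__(self, learner_params: Mapping[str, Mapping] | None = None, seed: int = 0):
        self.learner_params = learner_params or {}
        self.seed = seed
        self.models_: dict = {}

    def fit(self, X, y):
        for name in LEARNER_NAMES:
            model = make_learner(name, self.learner_params.get(name, {}), seed=self.seed)
            model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
            self.models_[name] = model
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.mean([m.predict(X) for m in self.models_.values()], axis=0)


def ensemble_predict(
    ensemble: TrainedMonthlyEnsemble,
    frame: pd.DataFrame,
    *,
    output: str = "natural",
    smearing: bool = False,
    per_member: bool = False,
):
    """Ensemble prediction for new predictor rows.

    The three log-scale predictions are averaged and, for
    ``output="natural"``, exponentiated.  ``smearing=True`` additionally
    multiplies by Duan's smearing factor estimated from training residuals.
    ``per_member=True`` returns a DataFrame with per-learner columns next to
    the ensemble column.
    """
    missing = [p for p in ensemble.predictors if p not in frame.columns]
    if missing:
        raise KeyError(f"prediction input lacks predictors: {missing}")
    X = ensemble.design(frame).to_numpy()
    member_logs = {name: ensemble.learners[name].predict(X) for name in LEARNER_NAMES}
    mean_log = np.mean(list(member_logs.values()), axis=0)

    factor = 1.0
    if smearing and output == "natural":
        X_train = ensemble.design(ensemble.X_frame.iloc[ensemble.train_index]).to_numpy()
        resid = ensemble.y_log[ensemble.train_index] - np.mean(
            [ensemble.learners[n].predict(X_train) for n in LEARNER_NAMES], axis=0
        )
        factor = float(np.mean(np.exp(resid)))

    def back(v):
        return np.exp(v) * factor if output == "natural" else v

    if per_member:
        out = pd.DataFrame({name: back(v) for name, v in member_logs.items()},
                           index=frame.index)
        out["ensemble"] = back(mean_log)
        return out
    return back(mean_log)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def loocv_evaluate(
    X,
    y,
    model_factory: Callable[[], object],
    *,
    cap: int | None = None,
    seed: int = 0,
) -> dict:
    """Leave-one-out cross-validation: R2 and RMSE over held-out predictions.

    Performs exactly ``n`` fits, each trained on ``n - 1`` points.  For
    large ``n`` a ``cap`` evaluates a seeded random subset of held-out
    points (each fit still uses ``n - 1`` training rows) — the number of
    fits is then ``cap``, recorded in the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 observations")
    indices = np.arange(n)
    if cap is not None and cap < n:
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(n, size=cap, replace=False))
    preds = np.empty(len(indices))
    for j, i in enumerate(indices):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = model_factory()
        model.fit(X[mask], y[mask])
        preds[j] = model.predict(X[i][None, :])[0]
    truth = y[indices]
    return {
        "r2": float(r2_score(truth, preds)),
        "rmse": float(np.sqrt(mean_squared_error(truth, preds))),
        "n_fits": int(len(indices)),
    }


# ---------------------------------------------------------------------------
# Importance fusion, ablation, partial dependence
# ---------------------------------------------------------------------------


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def fuse_importance(
    ensemble: TrainedMonthlyEnsemble,
    *,
    n_repeats: int = 5,
    seed: int = 0,
    top_n: int = 15,
) -> pd.DataFrame:
    """Fused 0-1 variable importance across the three algorithms.

    Forest and SVR importances come from seeded permutation importance on
    the held-out split; boosting uses its internal gain-based importances.
    Each algorithm's vector is min-max normalized to [0, 1] then averaged
    with equal weight; the table is sorted descending with a top-``top_n``
    flag.
    """
    if not ensemble.is_trained:
        raise ValueError("ensemble is not trained")
    X_test = ensemble.design(ensemble.X_frame.iloc[ensemble.test_index]).to_numpy()
    y_test = ensemble.y_log[ensemble.test_index]

    raw = {}
    for name in ("forest", "svr"):
        pi = permutation_importance(
            ensemble.learners[name], X_test, y_test,
            n_repeats=n_repeats, random_state=seed,
            scoring="neg_mean_squared_error",
        )
        raw[name] = pi.importances_mean
    raw["boosting"] = ensemble.learners["boosting"].feature_importances_

    table = pd.DataFrame({"predictor": list(ensemble.predictors)})
    for name in LEARNER_NAMES:
        table[f"{name}_raw"] = raw[name]
        table[f"{name}_norm"] = _minmax(raw[name])
    table["fused"] = table[[f"{n}_norm" for n in LEARNER_NAMES]].mean(axis=1)
    table = table.sort_values("fused", ascending=False, kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["top"] = table["rank"] <= top_n
    return table


def ablation_compare(
    observations: pd.DataFrame,
    response: str,
    *,
    predictors: Sequence[str] = ALL_PREDICTORS,
    nutrient_predictors: Sequence[str] = NUTRIENTS,
    log_predictors: Sequence[str] = DEFAULT_LOG_PREDICTORS,
    learner_params: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    test_fraction: float = 0.3,
    n_swap: int = 4,
) -> dict:
    """Held-out ensemble R2 with, without and with swapped-in nutrients.

    ``no_nutrient`` drops the nutrient predictors; ``swapped`` replaces the
    ``n_swap`` most influential non-nutrient predictors of the no-nutrient
    set with the nutrients, keeping the predictor count constant.  All three
    fits share one seeded train/test split.
    """
    predictors = list(predictors)
    for nut in nutrient_predictors:
        if nut not in observations.columns:
            raise KeyError(f"nutrient column {nut!r} absent from observations")
    no_nutrient = [p for p in predictors if p not in nutrient_predictors]

    y = response_vector(observations, response)
    rng = np.random.default_rng([seed, 99])
    perm = rng.permutation(len(observations))
    n_test = max(1, int(round(test_fraction * len(observations))))
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])

    def fit_r2(pred_set: Sequence[str]) -> float:
        X = build_design(observations, pred_set, log_predictors).to_numpy()
        model = MeanLogEnsemble(learner_params, seed=seed)
        model.fit(X[train_idx], y[train_idx])
        return float(r2_score(y[test_idx], model.predict(X[test_idx])))

    if not nutrient_predictors:
        # nothing to swap; all three sets coincide
        r2 = fit_r2(predictors)
        return {
            "r2_full": r2, "r2_no_nutrient": r2, "r2_swapped": r2,
            "delta_r2": 0.0, "swapped_out": [],
        }

    # rank non-nutrient predictors by |r| with the response on training rows
    influence = []
    X_nn = build_design(observations, no_nutrient, log_predictors)
    for p in no_nutrient:
        x = X_nn[p].to_numpy()[train_idx]
        yy = y[train_idx]
        m = np.isfinite(x) & np.isfinite(yy)
        r = abs(stats.pearsonr(x[m], yy[m]).statistic) if m.sum() > 2 and np.std(x[m]) > 0 else 0.0
        influence.append((p, r))
    influence.sort(key=lambda t: -t[1])
    top_terrestrial = [p for p, _ in influence[:n_swap]]
    swapped = [p for p in no_nutrient if p not in top_terrestrial] + list(nutrient_predictors)

    r2_full = fit_r2(predictors)
    r2_no = fit_r2(no_nutrient) if no_nutrient != predictors else r2_full
    r2_swap = fit_r2(swapped) if swapped != predictors else r2_full
    return {
        "r2_full": r2_full,
        "r2_no_nutrient": r2_no,
        "r2_swapped": r2_swap,
        "delta_r2": r2_full - r2_no,
        "swapped_out": top_terrestrial,
    }


def partial_dependence(
    ensemble: TrainedMonthlyEnsemble,
    predictor: str,
    grid,
    *,
    output: str = "log",
) -> pd.DataFrame:
    """Marginal-effect curve: mean prediction with ``predictor`` clamped.

    The predictor is clamped on the raw (pre-log) scale to each grid value
    over the ensemble's training window rows.
    """
    if predictor not in ensemble.predictors:
        raise KeyError(f"{predictor!r} is not a model predictor")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("partial dependence grid is empty")
    rows = []
    base = ensemble.X_frame.copy()
    for value in grid:
        base[predictor] = value
        pred = ensemble_predict(ensemble, base, output=output)
        rows.append({"value": float(value), "mean_prediction": float(np.mean(pred))})
    return pd.DataFrame(rows)
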