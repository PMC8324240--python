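"""Risk models behind a single "absolute risk over a horizon" contract.

Every model exposes ``predict_risk(features, horizon) -> probabilities``:

* :class:`CoxRiskModel` — proportional-hazards fit (lifelines backend)
  with a Breslow-type baseline survival, so risk(t) =
  1 - S0(t) ** exp(beta'(x - xbar)) is available at any horizon;
* :class:`BinaryRiskModel` — scikit-learn classifiers (logistic
  regression, gradient-boosted trees; optional isotonic-calibrated SVM
  and MLP plug-ins) trained per follow-up window, where ``horizon`` is
  fixed by the training interval and the argument is ignored;
* :class:`FixedLinearScore` — an externally published sex-specific
  linear score (coefficients and baseline survival supplied as
  configuration), usable as-published, recalibrated (baseline and
  centering re-estimated only), or refitted (coefficients re-estimated
  on the same variable set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sksurv.linear_model.coxph import BreslowEstimator

from .exceptions import ConfigurationError, FitError, SchemaError
from .metrics import auroc
from .prep import BinaryDataset, SurvivalDataset


def _step_lookup(times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Right-continuous step-function value at t (1.0 before the first knot)."""
    i = np.searchsorted(times, t, side="right") - 1
    return 1.0 if i < 0 else float(values[i])


class CoxRiskModel:
    """Cox proportional-hazards model with baseline survival.

    ``predict_risk(x, t) = 1 - S0(t) ** exp(beta'(x - xbar))`` where S0 is
    the Breslow-type baseline survival at the training covariate means.
    """

    def __init__(self, penalty: float = 0.0, l1_ratio: float = 1.0):
        self.penalty = penalty
        self.l1_ratio = l1_ratio
        self.coef_: pd.Series | None = None
        self.center_: pd.Series | None = None
        self.baseline_times_: np.ndarray | None = None
        self.baseline_survival_: np.ndarray | None = None

    @property
    def metadata(self) -> dict:
        return {
            "family": "cox",
            "penalty": self.penalty,
            "l1_ratio": self.l1_ratio,
            "horizons": "any",
        }

    def fit(self, train: SurvivalDataset) -> "CoxRiskModel":
        if int(np.sum(train.event)) < 2:
            raise FitError("Cox fit needs at least 2 events")
        if np.ptp(train.time) == 0:
            raise FitError("Cox fit needs non-constant event/censoring times")
        df = train.features.copy()
        df["T"] = train.time
        df["E"] = train.event
        cph = CoxPHFitter(
            penalizer=self.penalty, l1_ratio=self.l1_ratio if self.penalty > 0 else 0.0
        )
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError as exc:  # pragma: no cover - diagnostic path
            raise FitError(f"Cox partial-likelihood fit did not converge: {exc}") from exc
        self.coef_ = cph.params_.copy()
        self.center_ = cph._norm_mean.copy()
        base = cph.baseline_survival_  # at the covariate means (Breslow-type)
        self.baseline_times_ = base.index.to_numpy(dtype=float)
        self.baseline_survival_ = base.iloc[:, 0].to_numpy(dtype=float)
        return self

    def _check_fitted(self) -> None:
        if self.coef_ is None:
            raise FitError("model is not fitted")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor beta'(x - xbar)."""
        self._check_fitted()
        missing = [c for c in self.coef_.index if c not in features.columns]
        if missing:
            raise SchemaError(f"features missing model covariates: {missing}")
        x = features[self.coef_.index].to_numpy(dtype=float)
        return (x - self.center_.to_numpy()) @ self.coef_.to_numpy()

    def baseline_survival_at(self, t: float) -> float:
        self._check_fitted()
        return _step_lookup(self.baseline_times_, self.baseline_survival_, t)

    def predict_risk(self, features: pd.DataFrame, horizon: float) -> np.ndarray:
        s0 = self.baseline_survival_at(horizon)
        return 1.0 - s0 ** np.exp(self.linear_predictor(features))

    def predict_interval_risk(
        self, features: pd.DataFrame, t0: float, t1: float
    ) -> np.ndarray:
        """Risk of an event in [t0, t1) conditional on being event-free at t0."""
        s0, s1 = self.baseline_survival_at(t0), self.baseline_survival_at(t1)
        ratio = s1 / s0 if s0 > 0 else 0.0
        return 1.0 - ratio ** np.exp(self.linear_predictor(features))

    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "family": "cox",
            "penalty": self.penalty,
            "l1_ratio": self.l1_ratio,
            "coef": self.coef_.to_dict(),
            "center": self.center_.to_dict(),
            "baseline_times": self.baseline_times_.tolist(),
            "baseline_survival": self.baseline_survival_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxRiskModel":
        d = json.loads(Path(path).read_text())
        m = cls(penalty=d["penalty"], l1_ratio=d["l1_ratio"])
        m.coef_ = pd.Series(d["coef"])
        m.center_ = pd.Series(d["center"]).reindex(m.coef_.index)
        m.baseline_times_ = np.asarray(d["baseline_times"], dtype=float)
        m.baseline_survival_ = np.asarray(d["baseline_survival"], dtype=float)
        return m


def fit_cox(train: SurvivalDataset, penalty: float = 0.0) -> CoxRiskModel:
    """Fit a (optionally L1-penalized) Cox model to a survival dataset."""
    return CoxRiskModel(penalty=penalty).fit(train)


BINARY_SPECS = ("lr", "gbt", "svm", "mlp")


def _make_estimator(spec: str, seed: int, params: dict):
    if spec == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **params)
        )
    if spec == "gbt":
        # conservative capacity: cohort risk surfaces are smooth and
        # low-dimensional, and desk-scale training sets (~1e4-1e5 rows,
        # ~1e3 events) overfit quickly at the library defaults
        defaults = dict(
            max_iter=200,
            learning_rate=0.05,
            max_leaf_nodes=7,
            min_samples_leaf=200,
            l2_regularization=1.0,
            early_stopping=False,
        )
        defaults.update(params)
        return HistGradientBoostingClassifier(random_state=seed, **defaults)
    if spec == "svm":
        base = make_pipeline(StandardScaler(), LinearSVC(**params))
        # margin model: isotonic regression maps decision values to
        # probabilities, monotone in the raw score
        return CalibratedClassifierCV(base, method="isotonic", cv=3)
    if spec == "mlp":
        defaults = dict(hidden_layer_sizes=(32, 16), max_iter=300)
        defaults.update(params)
        return MLPClassifier(random_state=seed, **defaults)
    raise ConfigurationError(f"unknown binary model spec {spec!r}; expected {BINARY_SPECS}")


class BinaryRiskModel:
    """Binary classifier treated as an interval-risk model.

    The prediction task's follow-up window is fixed at training time;
    ``predict_risk`` ignores any horizon beyond it.
    """

    def __init__(self, spec: str, seed: int = 0, **params):
        self.spec = spec
        self.seed = seed
        self.params = params
        self.estimator = _make_estimator(spec, seed, params)
        self.interval: tuple[float, float] | None = None
        self.feature_names_: list[str] | None = None

    @property
    def metadata(self) -> dict:
        return {
            "family": self.spec,
            "interval": self.interval,
            "hyperparameters": dict(self.params),
        }

    def fit(self, train: BinaryDataset) -> "BinaryRiskModel":
        y = np.asarray(train.label)
        if len(np.unique(y)) < 2:
            raise FitError(f"{self.spec} training data contains a single class")
        self.estimator.fit(train.features.to_numpy(dtype=float), y)
        self.interval = train.interval
        self.feature_names_ = list(train.features.columns)
        return self

    def predict_risk(self, features: pd.DataFrame, horizon: float | None = None) -> np.ndarray:
        if self.feature_names_ is None:
            raise FitError("model is not fitted")
        x = features[self.feature_names_].to_numpy(dtype=float)
        return self.estimator.predict_proba(x)[:, 1]


def fit_binary(spec: str, train: BinaryDataset, seed: int = 0, **params) -> BinaryRiskModel:
    """Fit a binary risk model ('lr' or 'gbt'; 'svm'/'mlp' optional plug-ins)."""
    return BinaryRiskModel(spec, seed=seed, **params).fit(train)


class FixedLinearScore:
    """A published sex-specific linear risk score used as a benchmark.

    Parameters are supplied as configuration: named coefficients, a
    centering vector, and a baseline survival curve (knot times and
    values).  ``mode`` records provenance: "as_published",
    "recalibrated", or "refitted".
    """

    def __init__(
        self,
        coefficients: dict[str, float],
        centering: dict[str, float],
        baseline_times: Sequence[float],
        baseline_survival: Sequence[float],
        mode: str = "as_published",
    ):
        self.coefficients = dict(coefficients)
        self.centering = dict(centering)
        self.baseline_times = np.asarray(baseline_times, dtype=float)
        self.baseline_survival = np.asarray(baseline_survival, dtype=float)
        self.mode = mode

    @property
    def metadata(self) -> dict:
        return {"family": "fixed_linear_score", "mode": self.mode}

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    def _check_variables(self, columns) -> None:
        for v in self.variables:
            if v not in columns:
                raise SchemaError(f"score variable {v!r} missing from features")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        self._check_variables(features.columns)
        lp = np.zeros(len(features))
        for v, b in self.coefficients.items():
            lp += b * (features[v].to_numpy(dtype=float) - self.centering.get(v, 0.0))
        return lp

    def predict_risk(self, features: pd.DataFrame, horizon: float) -> np.ndarray:
        s0 = _step_lookup(self.baseline_times, self.baseline_survival, horizon)
        return 1.0 - s0 ** np.exp(self.linear_predictor(features))

    def fit(self, train: SurvivalDataset) -> "FixedLinearScore":
        """No-op: an as-published score never re-estimates anything."""
        return self


def recalibrate_fixed_score(
    score: FixedLinearScore, train: SurvivalDataset
) -> FixedLinearScore:
    """Re-estimate only the baseline survival and centering on ``train``.

    Coefficients are frozen; the baseline survival is re-estimated by the
    Breslow estimator given the score's linear predictor, which fixes
    calibration-in-the-large while preserving the published ranking.
    """
    score._check_variables(train.features.columns)
    centering = {v: float(train.features[v].mean()) for v in score.variables}
    shifted = FixedLinearScore(
        score.coefficients, centering, [0.0], [1.0], mode="recalibrated"
    )
    lp = shifted.linear_predictor(train.features)
    breslow = BreslowEstimator().fit(
        lp, train.event.astype(bool), np.asarray(train.time, dtype=float)
    )
    surv = breslow.baseline_survival_
    shifted.baseline_times = np.asarray(surv.x, dtype=float)
    shifted.baseline_survival = np.asarray(surv.y, dtype=float)
    return shifted


def refit_fixed_score(
    score: FixedLinearScore, train: SurvivalDataset, penalty: float = 0.0
) -> CoxRiskModel:
    """Re-estimate the score's coefficients on its own variable set.

    Definitionally equivalent to :func:`fit_cox` on the reduced feature
    matrix; returns the refitted Cox model.
    """
    score._check_variables(train.features.columns)
    reduced = SurvivalDataset(
        features=train.features[score.variables],
        time=train.time,
        event=train.event,
        horizon=train.horizon,
        ids=train.ids,
        role=train.role,
    )
    return fit_cox(reduced, penalty=penalty)


@dataclass
class HyperparameterSelection:
    """Outcome of a k-fold cross-validated grid search."""

    k: int
    grid: list[dict]
    metric: str
    scores: list[float]
    chosen_index: int

    @property
    def chosen(self) -> dict:
        return self.grid[self.chosen_index]


def tune_hyperparameters(
    spec: str,
    train: BinaryDataset,
    k: int = 5,
    grid: Sequence[dict] = ({},),
    metric=auroc,
    seed: int = 0,
) -> HyperparameterSelection:
    """Select hyperparameters by stratified k-fold CV within the training set.

    The per-fold metric (default AUROC) is averaged per candidate; ties
    are broken toward the earlier grid entry, so ordering the grid from
    simplest to most complex encodes the tie-break preference.
    Deterministic given ``seed``.
    """
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    grid = list(grid)
    if not grid:
        raise ConfigurationError("hyperparameter grid must be nonempty")
    x = train.features.to_numpy(dtype=float)
    y = np.asarray(train.label)
    folds = list(StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(x, y))
    scores = []
    for params in grid:
        fold_scores = []
        for tr, va in folds:
            est = _make_estimator(spec, seed, params)
            est.fit(x[tr], y[tr])
            fold_scores.append(metric(est.predict_proba(x[va])[:, 1], y[va]))
        scores.append(float(np.mean(fold_scores)))
    chosen = int(np.argmax(scores))  # argmax keeps the first (simplest) on ties
    return HyperparameterSelection(
        k=k,
        grid=grid,
        metric=getattr(metric, "__name__", str(metric)),
        scores=scores,
        chosen_index=chosen,
    )
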