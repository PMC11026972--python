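"""Eight-model screening harness and the five evaluation metrics.

Candidate predictors — linear regression, decision tree, support vector
regression, Adaboost, random forest, XGBoost, XGBoost random forest, and the
pathway graph neural network — each map the 31 normalized inputs to the 5
cause-specific burdens; the total burden is always obtained by summing the
five causes, never predicted directly. Performance is assessed on actual
error (RMSE, MAE), relative error (MAPE, RMSPE) and correlation (R²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor, XGBRFRegressor

from .catalog import CAUSES, PanelDataset, PathwayGraph
from .gnn import GNNRegressor, build_graph_batch

MODEL_NAMES = (
    "linear_regression",
    "decision_tree",
    "svr",
    "adaboost",
    "random_forest",
    "xgboost",
    "xgboost_rf",
    "gnn",
)

#: Models whose scikit-learn estimator handles a single output only; they are
#: fitted once per cause under the hood.
_SINGLE_OUTPUT = {"svr", "adaboost"}


@dataclass(frozen=True)
class PredictorSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


def default_specs(seed: int = 0) -> list[PredictorSpec]:
    """One spec per candidate model, at the documented defaults."""
    return [PredictorSpec(name, seed=seed) for name in MODEL_NAMES]


def _make_estimator(spec: PredictorSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "linear_regression":
        return LinearRegression(**hp)
    if spec.name == "decision_tree":
        hp.setdefault("max_depth", 8)
        return DecisionTreeRegressor(random_state=spec.seed, **hp)
    if spec.name == "svr":
        hp.setdefault("C", 1.0)
        hp.setdefault("epsilon", 0.01)
        return SVR(**hp)
    if spec.name == "adaboost":
        hp.setdefault("n_estimators", 100)
        return AdaBoostRegressor(random_state=spec.seed, **hp)
    if spec.name == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.name == "xgboost":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("learning_rate", 0.1)
        hp.setdefault("max_depth", 4)
        return XGBRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if spec.name == "xgboost_rf":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("max_depth", 6)
        return XGBRFRegressor(random_state=spec.seed, n_jobs=1, **hp)
    raise AssertionError(spec.name)


class FittedPredictor:
    """A fitted multi-output regressor from the 31 inputs to the 5 causes."""

    def __init__(self, spec: PredictorSpec, inputs: list[str],
                 pathway: PathwayGraph | None = None):
        self.spec = spec
        self.inputs = list(inputs)
        self.outputs = list(CAUSES)
        self.pathway = pathway
        self._estimators = None  # sklearn/xgboost estimator(s) or GNNRegressor
        self._catalog = None

    # -- fitting ------------------------------------------------------------
    def _fit(self, train: PanelDataset) -> "FittedPredictor":
        X = train.values(self.inputs)
        Y = train.values(self.outputs)
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("training panel contains missing values")
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        self._catalog = train.catalog
        if self.spec.name == "gnn":
            if self.pathway is None:
                raise ValueError("the gnn model requires a pathway graph")
            hp = dict(self.spec.hyperparameters)
            model = GNNRegressor(self.pathway, seed=self.spec.seed, **hp)
            batch = build_graph_batch(self.pathway, train.frame)
            model.fit(batch, Y)
            self._estimators = model
        elif self.spec.name in _SINGLE_OUTPUT:
            ests = []
            for j in range(Y.shape[1]):
                est = _make_estimator(self.spec)
                est.fit(X, Y[:, j])
                ests.append(est)
            self._estimators = ests
        else:
            est = _make_estimator(self.spec)
            est.fit(X, Y)
            self._estimators = est
        return self

    # -- prediction ---------------------------------------------------------
    def predict_values(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted normalized burdens as an (n_rows, 5) array."""
        if self.spec.name == "gnn":
            batch = build_graph_batch(self.pathway, frame)
            return self._estimators.predict(batch)
        X = frame[self.inputs].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("prediction panel contains missing inputs")
        if isinstance(self._estimators, list):
            return np.column_stack([est.predict(X) for est in self._estimators])
        return np.asarray(self._estimators.predict(X))

    def predict(self, panel: PanelDataset) -> pd.DataFrame:
        """Predicted normalized burden per cause, one row per panel row."""
        frame = panel.frame
        return pd.DataFrame(self.predict_values(frame), columns=self.outputs,
                            index=frame.index)


def fit(spec: PredictorSpec, train: PanelDataset,
        pathway: PathwayGraph | None = None) -> FittedPredictor:
    """Fit one candidate model on a normalized, complete training panel."""
    if not train.normalized:
        raise ValueError("train panel must be normalized before fitting")
    inputs = train.catalog.inputs
    return FittedPredictor(spec, inputs, pathway)._fit(train)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelEvaluation:
    rmse: float
    mae: float
    mape: float
    rmspe: float
    r2: float
    n_zero_actual: int = 0  # rows excluded from the relative errors

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mae": self.mae, "mape": self.mape,
                "rmspe": self.rmspe, "r2": self.r2}


def _metrics_1d(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float, float, float, int]:
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    nz = y != 0
    n_zero = int((~nz).sum())
    if nz.any():
        rel = err[nz] / y[nz]
        mape = float(np.mean(np.abs(rel)))
        rmspe = float(np.sqrt(np.mean(rel**2)))
    else:
        mape = rmspe = float("nan")
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return rmse, mae, mape, rmspe, r2, n_zero


def compute_metrics(y: np.ndarray, yhat: np.ndarray, pooling: str = "macro") -> ModelEvaluation:
    """RMSE, MAE, MAPE, RMSPE and R² for (possibly multi-output) predictions.

    ``pooling="macro"`` computes each metric per cause and averages across
    the five causes; ``"pooled"`` flattens all cause-rows together. Rows with
    a zero actual are excluded from the relative errors and counted.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat shapes differ")
    if y.ndim == 1 or pooling == "pooled":
        vals = _metrics_1d(y.ravel(), yhat.ravel())
        return ModelEvaluation(*vals)
    if pooling != "macro":
        raise ValueError("pooling must be 'macro' or 'pooled'")
    per_col = [_metrics_1d(y[:, j], yhat[:, j]) for j in range(y.shape[1])]
    arr = np.array([c[:5] for c in per_col])
    n_zero = sum(c[5] for c in per_col)
    return ModelEvaluation(*(float(v) for v in arr.mean(axis=0)), n_zero_actual=n_zero)


def evaluate(model: FittedPredictor, test: PanelDataset,
             pooling: str = "macro") -> ModelEvaluation:
    """Evaluate a fitted model on a normalized, complete test panel."""
    y = test.values(model.outputs)
    yhat = model.predict(test).to_numpy()
    return compute_metrics(y, yhat, pooling=pooling)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    ranking: list[tuple[PredictorSpec, ModelEvaluation]]
    failures: list[tuple[PredictorSpec, str]]
    fitted: dict[str, FittedPredictor]

    @property
    def best(self) -> tuple[PredictorSpec, ModelEvaluation]:
        return self.ranking[0]

    def table(self) -> pd.DataFrame:
        rows = [{"model": s.name, **ev.as_dict()} for s, ev in self.ranking]
        return pd.DataFrame(rows)


def screen(
    specs: list[PredictorSpec],
    train: PanelDataset,
    test: PanelDataset,
    pathway: PathwayGraph | None = None,
    pooling: str = "macro",
) -> ScreenResult:
    """Fit and evaluate every candidate; rank by RMSE ascending (ties broken
    by MAE, then name). A failing model is recorded and excluded, not fatal."""
    if not specs:
        raise ValueError("need at least one predictor spec")
    results, failures, fitted = [], [], {}
    for spec in specs:
        try:
            model = fit(spec, train, pathway=pathway)
            ev = evaluate(model, test, pooling=pooling)
            results.append((spec, ev))
            fitted[spec.name] = model
        except Exception as exc:  # noqa: BLE001 - screening is best-effort
            failures.append((spec, f"{type(exc).__name__}: {exc}"))
    results.sort(key=lambda se: (se[1].rmse, se[1].mae, se[0].name))
    return ScreenResult(results, failures, fitted)
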