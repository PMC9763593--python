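"""Cross-modal matching prediction models.

Two prediction directions are supported: *audio* (the 8 color perceptual
attributes predict the interval consonance index I) and *visual* (I predicts
one color attribute).  Four model families mirror the usual small-data
regression toolbox:

* ``MLR`` — ordinary least-squares multiple linear regression;
* ``SVR`` — epsilon-insensitive support-vector regression with an RBF
  kernel exp(−γ‖x−y‖²), γ initialized to 0.01;
* ``RF``  — a bagged forest of regression trees (bootstrap per tree);
* ``BP``  — a back-propagation network with one hidden layer of 4 logistic
  units and a linear output, trained by full-batch gradient descent.

Models are scored by 10-fold cross-validation: shuffled, near-equal folds,
each used once as the test set; out-of-fold predictions are pooled and
summarized by Pearson r (and its [0,1] rescaling (r+1)/2), MAE and RMSE,
then a final model is refit on all data.

The module also evaluates a set of fixed, previously published linear
prediction equations (ids 15–23) relating piano-interval consonance to
color attributes, usable as reference predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .correlation import pearson_r
from .ratings import ATTRIBUTES

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ModelReport",
    "mlr_fit",
    "metrics",
    "make_estimator",
    "kfold_cv",
    "hyperparam_search",
    "printed_model_predict",
    "PRINTED_EQUATIONS",
]

FAMILIES = ("MLR", "SVR", "RF", "BP")

#: Default hyperparameters per family (all overridable via ModelSpec).
_DEFAULTS: dict[str, dict] = {
    "MLR": {},
    "SVR": {"gamma": 0.01, "C": 1.0, "epsilon": 0.1},
    "RF": {"n_estimators": 100},
    "BP": {"learning_rate_init": 0.05, "max_iter": 2000},
}


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: family, direction, class and seed."""

    family: str
    direction: str  # "audio" (8 attrs -> I) or "visual" (I -> one attr)
    interval_class: str = "piano-harmonic"
    target_attribute: str | None = None  # visual direction only
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.direction not in ("audio", "visual"):
            raise ValueError(f"direction must be 'audio' or 'visual', got {self.direction!r}")
        if self.direction == "visual":
            if self.target_attribute not in ATTRIBUTES:
                raise ValueError("visual direction requires a target_attribute")
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.family]) - {"max_iter"}
        if unknown:
            raise ValueError(f"unknown {self.family} hyperparameters: {sorted(unknown)}")

    def resolved_hyperparameters(self) -> dict:
        hp = dict(_DEFAULTS[self.family])
        hp.update(self.hyperparameters)
        return hp


@dataclass
class ModelReport:
    """Cross-validated scores and the final refit model."""

    spec: ModelSpec
    r: float | None
    r_norm: float | None
    MAE: float
    RMSE: float
    cv_scheme: str
    coefficients: dict | None = None  # MLR only: intercept + per-feature betas
    model: object | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "direction": self.spec.direction,
            "interval_class": self.spec.interval_class,
            "target_attribute": self.spec.target_attribute,
            "hyperparameters": self.spec.resolved_hyperparameters(),
            "seed": self.spec.seed,
            "r": self.r,
            "r_norm": self.r_norm,
            "MAE": self.MAE,
            "RMSE": self.RMSE,
            "cv_scheme": self.cv_scheme,
            "coefficients": self.coefficients,
        }


def mlr_fit(X, y, feature_names: list[str] | None = None) -> np.ndarray:
    """OLS coefficients (intercept first) minimizing the residual sum of
    squares; raises on a rank-deficient design naming collinear columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = feature_names or [f"x{i}" for i in range(p)]
        # identify columns whose removal restores full rank
        collinear = [
            names[i]
            for i in range(p)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def metrics(y_true, y_pred) -> tuple[float | None, float | None, float, float]:
    """(r, r_norm, MAE, RMSE) for a prediction vector.

    r is the Pearson correlation between truth and prediction and
    r_norm = (r + 1)/2 its rescaling to [0, 1]; both are None when the
    predictions are constant (correlation undefined).  MAE and RMSE are
    always computed.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    mae = float(mean_absolute_error(y_true, y_pred))
    rmse = float(math.sqrt(mean_squared_error(y_true, y_pred)))
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        return None, None, mae, rmse
    r, _ = pearson_r(y_true, y_pred)
    return r, (r + 1.0) / 2.0, mae, rmse


class _FullBatchMLP(MLPRegressor):
    """MLPRegressor whose sgd updates always use the whole training set."""

    def fit(self, X, y):
        self.batch_size = len(X)
        return super().fit(X, y)


def make_estimator(spec: ModelSpec):
    """Build the (unfitted) scikit-learn estimator for a model spec."""
    hp = spec.resolved_hyperparameters()
    if spec.family == "MLR":
        return LinearRegression()
    if spec.family == "SVR":
        return SVR(kernel="rbf", gamma=hp["gamma"], C=hp["C"], epsilon=hp["epsilon"])
    if spec.family == "RF":
        return RandomForestRegressor(
            n_estimators=int(hp["n_estimators"]),
            bootstrap=True,
            random_state=spec.seed,
        )
    # BP: inputs standardized for stable gradient descent on a 4-node net
    return make_pipeline(
        StandardScaler(),
        _FullBatchMLP(
            hidden_layer_sizes=(4,),
            activation="logistic",
            solver="sgd",
            learning_rate_init=hp["learning_rate_init"],
            max_iter=int(hp["max_iter"]),
            random_state=spec.seed,
            tol=1e-7,
            n_iter_no_change=50,
        ),
    )


def kfold_cv(spec: ModelSpec, X, y, k: int = 10) -> ModelReport:
    """k-fold cross-validation followed by a final fit on all data.

    The rows are shuffled with the spec's seed and split into k contiguous
    near-equal folds; each fold serves once as the test set.  Out-of-fold
    predictions are pooled and scored with :func:`metrics`, then the model
    is refit on the full data set and attached to the report.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(
            f"n={n} < k={k}; reduce k (leave-one-out would be k={n})"
        )
    splitter = KFold(n_splits=k, shuffle=True, random_state=spec.seed)
    y_pred = np.empty(n)
    for train, test in splitter.split(X):
        est = make_estimator(spec)
        est.fit(X[train], y[train])
        y_pred[test] = est.predict(X[test])
    r, r_norm, mae, rmse = metrics(y, y_pred)
    final = make_estimator(spec)
    final.fit(X, y)
    coeffs = None
    if spec.family == "MLR":
        coeffs = {
            "intercept": float(final.intercept_),
            "betas": [float(b) for b in final.coef_],
        }
    return ModelReport(
        spec=spec,
        r=r,
        r_norm=r_norm,
        MAE=mae,
        RMSE=rmse,
        cv_scheme=f"{k}-fold shuffled (seed={spec.seed})",
        coefficients=coeffs,
        model=final,
    )


#: Hyperparameter search spaces: name -> (low, high, log-scale?, integer?)
_SEARCH_SPACES: dict[str, dict[str, tuple[float, float, bool, bool]]] = {
    "SVR": {
        "gamma": (1e-3, 1.0, True, False),
        "C": (0.1, 100.0, True, False),
        "epsilon": (0.01, 1.0, True, False),
    },
    "RF": {"n_estimators": (10, 300, False, True)},
    "BP": {"learning_rate_init": (1e-3, 0.5, True, False)},
    "MLR": {},
}


def _cv_score(spec: ModelSpec, X, y, k: int) -> float:
    report = kfold_cv(spec, X, y, k=k)
    return -np.inf if report.r is None else report.r


def hyperparam_search(
    spec: ModelSpec, X, y, budget: int = 20, k: int = 10
) -> dict:
    """Two-stage hyperparameter search maximizing cross-validated r.

    Stage 1 samples ``budget`` random points from the family's ranges
    (log-uniform where the range spans decades); stage 2 refines with a
    small per-parameter grid bracketing the stage-1 optimum.  Deterministic
    for a fixed spec seed.
    """
    if budget < 1:
        raise ValueError("budget must be ≥ 1")
    space = _SEARCH_SPACES[spec.family]
    if not space:
        return {}
    rng = np.random.default_rng(spec.seed)

    def sample() -> dict:
        point = {}
        for name, (lo, hi, log, integer) in space.items():
            if log:
                v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                v = float(rng.uniform(lo, hi))
            point[name] = int(round(v)) if integer else v
        return point

    def evaluate(point: dict) -> float:
        trial = ModelSpec(
            family=spec.family,
            direction=spec.direction,
            interval_class=spec.interval_class,
            target_attribute=spec.target_attribute,
            hyperparameters=point,
            seed=spec.seed,
        )
        return _cv_score(trial, X, y, k)

    # stage 1: random sampling
    best_point, best_score = None, -np.inf
    for _ in range(budget):
        point = sample()
        score = evaluate(point)
        if score > best_score:
            best_point, best_score = point, score

    # stage 2: per-parameter grid around the stage-1 optimum
    for name, (lo, hi, log, integer) in space.items():
        center = best_point[name]
        if log:
            grid = center * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        else:
            half = (hi - lo) / 8.0
            grid = center + half * np.array([-2, -1, 0, 1, 2])
        for v in np.clip(grid, lo, hi):
            v = int(round(v)) if integer else float(v)
            if v == best_point[name]:
                continue
            candidate = dict(best_point)
            candidate[name] = v
            score = evaluate(candidate)
            if score > best_score:
                best_point, best_score = candidate, score
    return best_point


#: Published linear prediction equations.  Audio-direction equations map
#: the 8 attribute means to a consonance index; visual-direction equations
#: map a consonance index to one attribute.  Attribute units: 1–5 scale;
#: consonance in dB.
PRINTED_EQUATIONS: dict[int, dict] = {
    15: {
        "direction": "audio",
        "interval_class": "piano-harmonic",
        "coefficients": {
            "CW": -25.944, "SH": 13.918, "TT": -25.791, "FN": -43.541,
            "WS": -12.917, "P": -15.421, "A": 53.862, "D": -27.861,
        },
        "intercept": 298.87,
    },
    16: {
        "direction": "audio",
        "interval_class": "piano-melodic",
        "coefficients": {
            "CW": -68.951, "SH": -78.879, "TT": 4.823, "FN": 118.165,
            "D": -29.515,
        },
        "intercept": 168.613,
    },
    17: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "CW", "slope": -0.008, "intercept": 3.175},
    18: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "TT", "slope": -0.023, "intercept": 3.506},
    19: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "FN", "slope": -0.008, "intercept": 3.364},
    20: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "WS", "slope": -0.013, "intercept": 3.380},
    21: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "A", "slope": -0.007, "intercept": 2.958},
    22: {"direction": "visual", "interval_class": "piano-harmonic",
         "target": "D", "slope": -0.009, "intercept": 2.264},
    23: {"direction": "visual", "interval_class": "piano-melodic",
         "target": "SH", "slope": -0.012, "intercept": 3.272},
}


def printed_model_predict(equation_id: int, inputs) -> float:
    """Evaluate one of the published linear equations.

    For audio-direction equations ``inputs`` is a mapping attribute → mean
    value (1–5 scale); for visual-direction equations it is the scalar
    consonance index in dB.
    """
    try:
        eq = PRINTED_EQUATIONS[equation_id]
    except KeyError:
        raise ValueError(f"unknown equation id {equation_id}") from None
    if eq["direction"] == "audio":
        total = eq["intercept"]
        for name, coef in eq["coefficients"].items():
            if name not in inputs:
                raise ValueError(f"equation {equation_id} needs input {name!r}")
            total += coef * float(inputs[name])
        return float(total)
    return float(eq["slope"] * float(inputs) + eq["intercept"])
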