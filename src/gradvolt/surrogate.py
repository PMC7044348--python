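"""Regression surrogates mapping the 10-feature vector to induced voltage.

The central surrogate is a fully connected two-hidden-layer neural network
(10 → 25 → 120 → 1, leaky-ReLU hidden activations, linear output) trained
with Adam on mean-squared error over z-scored features; batch size 32, 300
epochs.  It is implemented directly in numpy so that training is exactly
reproducible from a seed.  Four comparison algorithms — linear- and
RBF-kernel support vector regression, random forests and gradient boosting —
run behind the same :class:`RegressorSpec` interface via scikit-learn.

The modelling surface follows the statsmodels convention: a
:class:`VoltageSurrogate` model object built from data whose ``fit()`` returns
a :class:`VoltageSurrogateResults` carrying the trained estimator, its
training history and a ``summary()`` table.  The functional helpers
(:func:`train_regressor`, :func:`predict`, :func:`tune_hyperparameters`) are
thin wrappers over those objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .dataset import FEATURE_COLUMNS

ALGORITHMS = ("SVMLIN", "SVMRBF", "RF", "GB", "NN")

NN_DEFAULTS: Mapping[str, object] = {
    "hidden_units": (25, 120),
    "batch_size": 32,
    "epochs": 300,
    "learning_rate": 1e-3,
    "leaky_slope": 0.01,
    "output_activation": "linear",  # 'leaky_relu' available for nonneg targets
}

#: small comparison-algorithm grids (desk scale)
DEFAULT_GRIDS = {
    "SVMLIN": {"C": [0.1, 1.0, 10.0]},
    "SVMRBF": {"C": [0.1, 1.0, 10.0], "gamma": [0.03, 0.1, 0.3]},
    "RF": {"n_estimators": [100, 300], "max_depth": [4, 8, None]},
    "GB": {"n_estimators": [100, 300], "max_depth": [4, 8],
           "learning_rate": [0.05, 0.1]},
    "NN": {},  # the NN default spec is the tuned optimum
}

SERIALIZATION_VERSION = 1


class SurrogateError(ValueError):
    """Invalid training data or specification."""


@dataclass(frozen=True)
class RegressorSpec:
    """Algorithm choice plus hyperparameters and a training seed."""

    algorithm: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise SurrogateError(f"unknown algorithm {self.algorithm!r}; "
                                 f"expected one of {ALGORITHMS}")
        hp = self.hyperparameters
        if isinstance(hp, Mapping):
            hp = tuple(sorted(hp.items()))
        object.__setattr__(self, "hyperparameters", tuple(hp))

    @property
    def params(self) -> dict:
        base = dict(NN_DEFAULTS) if self.algorithm == "NN" else {}
        base.update(dict(self.hyperparameters))
        return base


def default_nn_spec(seed: int = 0, **overrides) -> RegressorSpec:
    return RegressorSpec("NN", tuple(sorted(overrides.items())), seed)


@dataclass
class TrainingHistory:
    """Per-epoch mean-squared-error losses (V²); empty for non-NN models."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# the numpy neural network

class DenseNet:
    """Small fully connected regressor trained with Adam on MSE.

    Weights use He-normal initialisation from a seeded generator; mini-batch
    order is reshuffled each epoch from the same generator, so training is a
    pure function of (data, spec, seed).
    """

    def __init__(self, n_features: int, hidden_units: Sequence[int],
                 leaky_slope: float = 0.01, output_activation: str = "linear",
                 seed: int = 0):
        sizes = [n_features, *hidden_units, 1]
        rng = np.random.default_rng(seed)
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                             size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.slope = leaky_slope
        self.output_activation = output_activation
        self.rng = rng

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.W) + sum(b.size for b in self.b)

    def _leaky(self, z):
        return np.where(z > 0, z, self.slope * z)

    def _forward(self, X):
        acts = [X]
        z_cache = []
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            z_cache.append(z)
            last = i == len(self.W) - 1
            if last and self.output_activation == "linear":
                a = z
            else:
                a = self._leaky(z)
            acts.append(a)
        return acts, z_cache

    def predict(self, X) -> np.ndarray:
        acts, _ = self._forward(np.asarray(X, dtype=float))
        return acts[-1][:, 0]

    def _grad(self, X, y):
        acts, zs = self._forward(X)
        m = len(X)
        pred = acts[-1][:, 0]
        delta = (2.0 / m) * (pred - y)[:, None]
        if self.output_activation != "linear":
            delta = delta * np.where(zs[-1] > 0, 1.0, self.slope)
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * np.where(zs[i - 1] > 0, 1.0,
                                                         self.slope)
        return gW, gb, float(np.mean((pred - y) ** 2))

    def fit(self, X, y, X_val=None, y_val=None, epochs: int = 300,
            batch_size: int = 32, learning_rate: float = 1e-3) -> TrainingHistory:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        hist = TrainingHistory()
        for _ in range(epochs):
            order = self.rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                idx = order[start:start + batch_size]
                gW, gb, _ = self._grad(X[idx], y[idx])
                t += 1
                corr = np.sqrt(1 - b2**t) / (1 - b1**t)
                for i in range(len(self.W)):
                    mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                    vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                    self.W[i] -= learning_rate * corr * mW[i] / (np.sqrt(vW[i]) + eps)
                    mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                    vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                    self.b[i] -= learning_rate * corr * mb[i] / (np.sqrt(vb[i]) + eps)
            train_mse = float(np.mean((self.predict(X) - y) ** 2))
            if not np.isfinite(train_mse):
                raise SurrogateError("NN training diverged (non-finite loss)")
            hist.train_loss.append(train_mse)
            if X_val is not None and len(X_val):
                hist.val_loss.append(
                    float(np.mean((self.predict(X_val) - y_val) ** 2)))
        return hist


def _sklearn_estimator(spec: RegressorSpec):
    p = dict(spec.hyperparameters)
    if spec.algorithm == "SVMLIN":
        return SVR(kernel="linear", C=p.get("C", 1.0))
    if spec.algorithm == "SVMRBF":
        return SVR(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"))
    if spec.algorithm == "RF":
        return RandomForestRegressor(
            n_estimators=p.get("n_estimators", 300),
            max_depth=p.get("max_depth"), random_state=spec.seed, n_jobs=1)
    if spec.algorithm == "GB":
        return GradientBoostingRegressor(
            n_estimators=p.get("n_estimators", 300),
            max_depth=p.get("max_depth", 4),
            learning_rate=p.get("learning_rate", 0.1), random_state=spec.seed)
    raise SurrogateError(f"no sklearn backend for {spec.algorithm}")


# ---------------------------------------------------------------------------
# model / results objects

def design_matrix(rows) -> np.ndarray:
    """Extract the (n, 10) feature matrix from a DataFrame or array."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in rows.columns]
        if missing:
            raise SurrogateError(f"rows lack feature columns {missing}")
        X = rows[FEATURE_COLUMNS].to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_COLUMNS):
        raise SurrogateError(
            f"expected {len(FEATURE_COLUMNS)} features, got shape {X.shape}")
    return X


class VoltageSurrogate:
    """Surrogate regression model for gradient-induced voltage.

    Parameters
    ----------
    endog : array-like
        Target voltages in V.
    exog : array-like or DataFrame
        The 10-feature design matrix (schema of ``FEATURE_COLUMNS``).
    spec : RegressorSpec, optional
        Algorithm and hyperparameters; defaults to the two-layer NN.
    """

    def __init__(self, endog, exog, spec: RegressorSpec | None = None):
        self.spec = spec if spec is not None else default_nn_spec()
        self.exog = design_matrix(exog)
        self.endog = np.asarray(endog, dtype=float)
        if len(self.endog) != len(self.exog):
            raise SurrogateError("endog and exog lengths differ")
        if len(self.endog) < 50:
            raise SurrogateError("need at least 50 training rows")
        if not (np.isfinite(self.exog).all() and np.isfinite(self.endog).all()):
            raise SurrogateError("non-finite values in training data")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: RegressorSpec | None = None,
                       target: str = "v_total_V") -> "VoltageSurrogate":
        return cls(df[target].to_numpy(dtype=float), df, spec)

    def fit(self, validation=None, validation_target: str = "v_total_V"
            ) -> "VoltageSurrogateResults":
        """Train the surrogate; features are z-scored on training statistics
        only (validation rows never leak into the scaler or the fit)."""
        mean = self.exog.mean(axis=0)
        scale = self.exog.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = (self.exog - mean) / scale
        spec = self.spec
        if spec.algorithm == "NN":
            p = spec.params
            net = DenseNet(Xs.shape[1], p["hidden_units"], p["leaky_slope"],
                           p["output_activation"], seed=spec.seed)
            Xv = yv = None
            if validation is not None:
                Xv = (design_matrix(validation) - mean) / scale
                yv = (validation[validation_target].to_numpy(dtype=float)
                      if isinstance(validation, pd.DataFrame) else None)
            hist = net.fit(Xs, self.endog, Xv, yv, epochs=p["epochs"],
                           batch_size=p["batch_size"],
                           learning_rate=p["learning_rate"])
            backend = net
        else:
            est = _sklearn_estimator(spec)
            est.fit(Xs, self.endog)
            hist = TrainingHistory()
            backend = est
        return VoltageSurrogateResults(self, backend, mean, scale, hist)


class VoltageSurrogateResults:
    """Fitted surrogate: predictions, training history and summary."""

    def __init__(self, model: VoltageSurrogate, backend, feature_mean,
                 feature_scale, history: TrainingHistory,
                 uncertainty: tuple | None = None):
        self.model = model
        self.spec = model.spec
        self.backend = backend
        self.feature_mean = np.asarray(feature_mean)
        self.feature_scale = np.asarray(feature_scale)
        self.history = history
        #: conservative (mse_mV, mae_mV) attached after cross-validation
        self.uncertainty = uncertainty

    @property
    def n_parameters(self) -> int | None:
        if isinstance(self.backend, DenseNet):
            return self.backend.n_parameters
        return None

    def predict(self, rows) -> np.ndarray:
        X = design_matrix(rows)
        if len(X) == 0:
            return np.zeros(0)
        Xs = (X - self.feature_mean) / self.feature_scale
        return np.asarray(self.backend.predict(Xs), dtype=float)

    def summary(self) -> str:
        lines = [
            "Voltage surrogate results",
            "=" * 38,
            f"algorithm:        {self.spec.algorithm}",
            f"training rows:    {len(self.model.endog)}",
        ]
        if self.n_parameters is not None:
            lines.append(f"parameters:       {self.n_parameters}")
        for k, v in sorted(dict(self.spec.hyperparameters).items()):
            lines.append(f"  {k}: {v}")
        if len(self.history):
            lines.append(f"final train MSE:  {self.history.train_loss[-1]:.6g} V^2")
            if self.history.val_loss:
                lines.append(f"final val MSE:    {self.history.val_loss[-1]:.6g} V^2")
        if self.uncertainty is not None:
            mse, mae = self.uncertainty
            lines.append(f"uncertainty:      MSE {mse:.1f} mV, MAE {mae:.1f} mV")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": SERIALIZATION_VERSION,
            "spec": {"algorithm": self.spec.algorithm,
                     "hyperparameters": self.spec.hyperparameters,
                     "seed": self.spec.seed},
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
            "uncertainty": self.uncertainty,
            "history": {"train": self.history.train_loss,
                        "val": self.history.val_loss},
        }
        if isinstance(self.backend, DenseNet):
            payload["nn_weights"] = self.backend.W
            payload["nn_biases"] = self.backend.b
            payload["nn_meta"] = {"slope": self.backend.slope,
                                  "output_activation": self.backend.output_activation}
        else:
            payload["sklearn_estimator"] = self.backend
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "VoltageSurrogateResults":
        payload = joblib.load(path)
        if payload.get("format_version") != SERIALIZATION_VERSION:
            raise SurrogateError("unsupported surrogate file version")
        spec = RegressorSpec(payload["spec"]["algorithm"],
                             payload["spec"]["hyperparameters"],
                             payload["spec"]["seed"])
        hist = TrainingHistory(payload["history"]["train"],
                               payload["history"]["val"])
        obj = cls.__new__(cls)
        obj.model = None
        obj.spec = spec
        obj.feature_mean = np.asarray(payload["feature_mean"])
        obj.feature_scale = np.asarray(payload["feature_scale"])
        obj.history = hist
        obj.uncertainty = payload.get("uncertainty")
        if "nn_weights" in payload:
            meta = payload["nn_meta"]
            net = DenseNet.__new__(DenseNet)
            net.W = [np.asarray(w) for w in payload["nn_weights"]]
            net.b = [np.asarray(b) for b in payload["nn_biases"]]
            net.slope = meta["slope"]
            net.output_activation = meta["output_activation"]
            net.rng = np.random.default_rng(spec.seed)
            obj.backend = net
        else:
            obj.backend = payload["sklearn_estimator"]
        return obj


# ---------------------------------------------------------------------------
# functional wrappers

def train_regressor(spec: RegressorSpec, train_rows: pd.DataFrame,
                    validation_rows: pd.DataFrame | None = None,
                    target: str = "v_total_V"):
    """Fit a surrogate on a dataset table; returns (results, history)."""
    model = VoltageSurrogate.from_dataframe(train_rows, spec, target)
    res = model.fit(validation=validation_rows, validation_target=target)
    return res, res.history


def predict(results: VoltageSurrogateResults, rows) -> np.ndarray:
    return results.predict(rows)


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid)
    out = [{}]
    for k in keys:
        out = [{**d, k: v} for d in out for v in grid[k]]
    return out


def tune_hyperparameters(algorithm: str, grid: Mapping[str, Sequence] | list,
                         train_rows: pd.DataFrame, k: int = 3, seed: int = 0,
                         target: str = "v_total_V") -> RegressorSpec:
    """Exhaustive grid search with k-fold cross-validation.

    Returns the grid point with the lowest mean validation MSE; ties are
    broken by grid order (first wins).  Deterministic given the seed, which
    drives both the fold shuffling and each candidate's training.
    """
    points = grid if isinstance(grid, list) else _grid_points(grid)
    if not points:
        raise SurrogateError("hyperparameter grid is empty")
    if k < 2:
        raise SurrogateError("need at least 2 folds")
    if k > len(train_rows):
        raise SurrogateError("more folds than training rows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    best = None
    for point in points:
        spec = RegressorSpec(algorithm, tuple(sorted(point.items())), seed)
        mses = []
        for tr_idx, va_idx in kf.split(train_rows):
            tr = train_rows.iloc[tr_idx]
            va = train_rows.iloc[va_idx]
            res, _ = train_regressor(spec, tr, target=target)
            err = res.predict(va) - va[target].to_numpy(dtype=float)
            mses.append(float(np.mean(err**2)))
        score = float(np.mean(mses))
        if best is None or score < best[0] - 1e-15:
            best = (score, spec)
    return best[1]
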