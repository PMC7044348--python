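"""Metrics, leave-one-body-out cross-validation and uncertainty derivation.

Surrogate performance is summarised by three statistics: the coefficient of
determination R², the mean squared error, and the *median* absolute error.
Following the dataset's reporting convention, MSE is expressed in "mV" as
V² × 1000 and MAE as |error| in mV — a convention that keeps the two numbers
on comparable scales for volt-level targets.

Generalisation to unseen anatomy is probed with leave-one-body-model-out
cross-validation: the surrogate is trained on the condensed rows of all other
bodies, monitored per-epoch on the held-out body's condensed rows, and scored
on the held-out body's *extended* rows, which retain the replicate routing
variability the features cannot resolve.  Because no separate validation set
exists for a production model trained on everything, the conservative
(fold-wise maximum) MSE and MAE from cross-validation serve as its prediction
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surrogate import (ALGORITHMS, DEFAULT_GRIDS, RegressorSpec,
                        TrainingHistory, default_nn_spec, train_regressor,
                        tune_hyperparameters)

#: "mV" reporting scale for MSE (V²×1000) and MAE (V×1000)
MV = 1000.0


class EvaluationError(ValueError):
    """Inconsistent evaluation inputs."""


@dataclass(frozen=True)
class Metrics:
    """Evaluation triple; ``r2`` is NaN (flagged) for zero-variance targets."""

    r2: float
    mse_mV: float
    mae_mV: float
    mean_error_mV: float = np.nan
    r2_defined: bool = True

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mse_mV": self.mse_mV, "mae_mV": self.mae_mV,
                "mean_error_mV": self.mean_error_mV}


def compute_metrics(y_true, y_pred) -> Metrics:
    """R², MSE (V²×1000) and median absolute error (mV) of predictions."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise EvaluationError("y_true and y_pred must be equal-length, nonempty")
    err = p - y
    mse = float(np.mean(err**2)) * MV
    mae = float(np.median(np.abs(err))) * MV
    bias = float(np.mean(err)) * MV
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return Metrics(np.nan, mse, mae, bias, r2_defined=False)
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return Metrics(r2, mse, mae, bias)


@dataclass(frozen=True)
class CVResult:
    """One leave-one-body-out fold (with the held-out predictions)."""

    held_out_body: str
    metrics: Metrics
    history: TrainingHistory
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None


def _check_tables(condensed: pd.DataFrame, extended: pd.DataFrame):
    for name, df in (("condensed", condensed), ("extended", extended)):
        if "body" not in df.columns:
            raise EvaluationError(f"{name} table lacks a 'body' column")
    missing = set(extended["body"]) - set(condensed["body"])
    if missing:
        raise EvaluationError(
            f"bodies {sorted(missing)} present in extended but not condensed")


def leave_one_body_out(condensed: pd.DataFrame, extended: pd.DataFrame,
                       spec: RegressorSpec | None = None,
                       target: str = "v_total_V") -> list[CVResult]:
    """Train on all-but-one body's condensed rows, validate per epoch on the
    held-out condensed rows, and score on the held-out extended rows."""
    _check_tables(condensed, extended)
    bodies = list(dict.fromkeys(extended["body"]))
    if len(bodies) < 2:
        raise EvaluationError("need at least two bodies for cross-validation")
    if spec is None:
        spec = default_nn_spec()
    out = []
    for body in bodies:
        train = condensed[condensed["body"] != body]
        val = condensed[condensed["body"] == body]
        test = extended[extended["body"] == body]
        res, hist = train_regressor(spec, train, validation_rows=val,
                                    target=target)
        y_true = test[target].to_numpy(dtype=float)
        y_pred = res.predict(test)
        out.append(CVResult(body, compute_metrics(y_true, y_pred), hist,
                            y_true, y_pred))
    return out


def derive_uncertainty(cv_results) -> tuple[float, float]:
    """Most conservative (element-wise maximum) MSE and MAE across folds."""
    cv_results = list(cv_results)
    if not cv_results:
        raise EvaluationError("no cross-validation results")
    return (max(r.metrics.mse_mV for r in cv_results),
            max(r.metrics.mae_mV for r in cv_results))


def algorithm_comparison(condensed: pd.DataFrame, extended: pd.DataFrame,
                         heaviest_body: str,
                         algorithms=ALGORITHMS,
                         grids=None, k: int = 3, seed: int = 0,
                         target: str = "v_total_V") -> pd.DataFrame:
    """Tune and train each algorithm on all bodies except the heaviest, then
    score it on the heaviest body's rows.

    The heaviest body is the most out-of-distribution anatomy, so this
    comparison gauges generalisation; the signed mean-error column exposes
    systematic under- or over-estimation.
    """
    _check_tables(condensed, extended)
    if heaviest_body not in set(condensed["body"]):
        raise EvaluationError(f"unknown body {heaviest_body!r}")
    grids = dict(DEFAULT_GRIDS) if grids is None else grids
    train = condensed[condensed["body"] != heaviest_body]
    test = extended[extended["body"] == heaviest_body]
    rows = []
    for algo in algorithms:
        if algo not in ALGORITHMS:
            raise EvaluationError(f"unknown algorithm label {algo!r}")
        grid = grids.get(algo, {})
        if grid:
            spec = tune_hyperparameters(algo, grid, train, k=k, seed=seed,
                                        target=target)
        else:
            spec = (default_nn_spec(seed=seed) if algo == "NN"
                    else RegressorSpec(algo, (), seed))
        res, _ = train_regressor(spec, train, target=target)
        m = compute_metrics(test[target].to_numpy(dtype=float),
                            res.predict(test))
        rows.append({"algorithm": algo, **m.as_dict(),
                     "hyperparameters": dict(spec.hyperparameters)})
    return pd.DataFrame(rows)


def check_no_leakage(condensed: pd.DataFrame, extended: pd.DataFrame) -> bool:
    """True when, for every fold, the held-out body's (height, mass) tuple
    never occurs among that fold's training features."""
    for body in dict.fromkeys(extended["body"]):
        train = condensed[condensed["body"] != body]
        held = extended[extended["body"] == body]
        held_keys = set(zip(held["height"], held["mass_100kg"]))
        train_keys = set(zip(train["height"], train["mass_100kg"]))
        if held_keys & train_keys:
            return False
    return True


def plot_true_vs_predicted(y_true, y_pred, metrics: Metrics | None = None,
                           title: str = "", ax=None):
    """Diagnostic scatter of predicted vs true voltage with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y_true, y_pred, s=4, alpha=0.4)
    lim = [0.0, float(max(np.max(y_true), np.max(y_pred)) * 1.05)]
    ax.plot(lim, lim, "r-", lw=1)
    ax.set_xlabel("true voltage (V)")
    ax.set_ylabel("predicted voltage (V)")
    if metrics is not None and metrics.r2_defined:
        title = (f"{title}  R²={metrics.r2:.2f} MSE={metrics.mse_mV:.0f} mV "
                 f"MAE={metrics.mae_mV:.0f} mV")
    ax.set_title(title.strip(), fontsize=9)
    return ax
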