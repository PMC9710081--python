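"""Scikit-learn-style classifiers for adherence prediction.

Five model families are compared: logistic regression and a
cross-validated ridge classifier (linear, non-temporal), an MLP
(non-linear, non-temporal) and two recurrent many-to-one networks —
simple RNN and LSTM — that consume the quarterly sequence directly.

All estimators follow the sklearn contract (``fit`` / ``predict`` /
``get_params``; fitted attributes end in an underscore).  The recurrent
estimators accept 3-D input ``(n_samples, n_timesteps, n_features)``;
everything else takes ordinary 2-D matrices.  ``decision_function`` (or the
class-1 probability) supplies the continuous score for ROC analysis: the
ridge classifier exposes its regression value on the ±1 targets, since its
hard sign alone would not trace a curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .nn import (
    LSTMNet,
    MLPNet,
    SimpleRNNNet,
    TrainingConfig,
    fit_network,
    sigmoid,
)

#: L2 grid searched by the cross-validated ridge classifier.
DEFAULT_L2_GRID = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class LinearModelParams:
    """Intercept and per-feature coefficients of a fitted linear model."""

    intercept: float
    coef: np.ndarray
    family: str  # "logistic" | "ridge"
    l2: float = 0.0


def logistic_predict(params: LinearModelParams, x: np.ndarray) -> np.ndarray:
    """Event probability ``p = 1/(1 + exp(-(b0 + x.b)))``."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != len(params.coef):
        raise ValueError(
            f"width mismatch: {x.shape[1]} features vs {len(params.coef)} coefficients")
    p = sigmoid(params.intercept + x @ params.coef)
    return float(p[0]) if squeeze else p


def _ridge_solve(X, t, l2: float, fit_intercept: bool = True):
    """Minimise ||t - Xb||^2 + l2 ||b||^2 (intercept unpenalised)."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if fit_intercept:
        xm = X.mean(axis=0)
        tm = t.mean()
        Xc, tc = X - xm, t - tm
    else:
        xm, tm = np.zeros(X.shape[1]), 0.0
        Xc, tc = X, t
    A = Xc.T @ Xc + l2 * np.eye(X.shape[1])
    if l2 == 0.0:
        rank = np.linalg.matrix_rank(Xc)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                "l2=0 with rank-deficient design matrix")
    coef = np.linalg.solve(A, Xc.T @ tc)
    intercept = tm - xm @ coef if fit_intercept else 0.0
    return float(intercept), coef


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    l2_grid: Sequence[float] = DEFAULT_L2_GRID,
    cv: int = 5,
    seed: int = 0,
) -> LinearModelParams:
    """Ridge classification on ±1 targets with CV choice of the L2 strength.

    The binary response is recoded to -1/+1 and the task treated as a
    penalised regression; the chosen L2 minimises mean validation squared
    error over ``cv`` deterministic folds.
    """
    grid = list(l2_grid)
    if not grid or any(l2 < 0 for l2 in grid):
        raise ValueError("l2_grid must be non-empty with all values >= 0")
    X = np.asarray(X, dtype=float)
    t = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n = len(t)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv)
    mean_err = []
    for l2 in grid:
        errs = []
        for k in range(cv):
            val = folds[k]
            tr = np.concatenate([folds[j] for j in range(cv) if j != k])
            try:
                b0, b = _ridge_solve(X[tr], t[tr], l2)
            except np.linalg.LinAlgError:
                errs.append(np.inf)
                continue
            pred = b0 + X[val] @ b
            errs.append(float(((t[val] - pred) ** 2).mean()))
        mean_err.append(float(np.mean(errs)))
    best = int(np.argmin(mean_err))
    b0, b = _ridge_solve(X, t, grid[best])
    return LinearModelParams(intercept=b0, coef=b, family="ridge",
                             l2=grid[best])


class RidgeAdherenceClassifier(BaseEstimator, ClassifierMixin):
    """Cross-validated ridge classifier (±1 targets, closed form)."""

    def __init__(self, l2_grid: Sequence[float] = DEFAULT_L2_GRID,
                 cv: int = 5, seed: int = 0):
        self.l2_grid = l2_grid
        self.cv = cv
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        params = ridge_fit(X, y, self.l2_grid, cv=self.cv, seed=self.seed)
        self.params_ = params
        self.coef_ = params.coef
        self.intercept_ = params.intercept
        self.l2_ = params.l2
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class LogisticAdherenceClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression front-end (sklearn solver, Eq-style predict)."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000, seed: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        lr = LogisticRegression(C=self.C, max_iter=self.max_iter,
                                random_state=self.seed)
        lr.fit(X, y)
        self.params_ = LinearModelParams(
            intercept=float(lr.intercept_[0]), coef=lr.coef_[0],
            family="logistic")
        return self

    def predict_proba(self, X):
        p1 = logistic_predict(self.params_, np.atleast_2d(np.asarray(X, float)))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


class _NetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the numpy network estimators."""

    def _build_net(self, n_features):  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_X(self, X):
        return np.asarray(X, dtype=float)

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.net_ = self._build_net(X.shape[-1])
        self.n_features_in_ = X.shape[-1]
        cfg = TrainingConfig(batch_size=self.batch_size, epochs=self.epochs,
                             l2=getattr(self, "l2", 0.0), seed=self.seed)
        self.params_, self.history_ = fit_network(
            self.net_, X, y, cfg, X_val=X_val, y_val=y_val)
        return self

    def predict_proba(self, X):
        return self.net_.forward(self.params_, self._check_X(X))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


class MLPAdherenceClassifier(_NetClassifier):
    """3-dense-layer MLP with per-hidden-layer dropout and softmax output."""

    def __init__(self, hidden=(64, 64), dropout=(0.2152, 0.1758),
                 activation: str = "relu", batch_size: int = 256,
                 epochs: int = 50, seed: int = 0):
        self.hidden = hidden
        self.dropout = dropout
        self.activation = activation
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _build_net(self, n_features):
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer widths must be positive")
        return MLPNet(n_features, hidden=self.hidden,
                      activation=self.activation, dropout=self.dropout)


class SimpleRNNAdherenceClassifier(_NetClassifier):
    """Many-to-one simple RNN; expects (n, T, F) input."""

    def __init__(self, units: int = 8, l2: float = 1.202e-2,
                 activation: str = "sigmoid", batch_size: int = 4096,
                 epochs: int = 100, seed: int = 0):
        self.units = units
        self.l2 = l2
        self.activation = activation
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("recurrent models expect (n, T, F) input")
        return X

    def _build_net(self, n_features):
        if self.units <= 0:
            raise ValueError("units must be positive")
        return SimpleRNNNet(n_features, hidden=self.units,
                            activation=self.activation)


class LSTMAdherenceClassifier(_NetClassifier):
    """Many-to-one LSTM with forget gate; expects (n, T, F) input."""

    def __init__(self, units: int = 4, l2: float = 9.261e-3,
                 batch_size: int = 1024, epochs: int = 100, seed: int = 0):
        self.units = units
        self.l2 = l2
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("recurrent models expect (n, T, F) input")
        return X

    def _build_net(self, n_features):
        if self.units <= 0:
            raise ValueError("units must be positive")
        return LSTMNet(n_features, hidden=self.units)


# ---------------------------------------------------------------------------
# data splitting and hyperparameter selection
# ---------------------------------------------------------------------------

@dataclass
class SplitScheme:
    """Held-out test set plus 5 rotated 90/10 train/validation folds."""

    test_fraction: float = 10096 / 100096
    n_folds: int = 5

    def split(self, n: int, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_test = int(round(self.test_fraction * n))
        test_idx = np.sort(order[:n_test])
        rest = order[n_test:]
        blocks = np.array_split(rest, 2 * self.n_folds)
        folds = []
        for k in range(self.n_folds):
            val = np.sort(blocks[k])
            train = np.sort(np.concatenate(
                [blocks[j] for j in range(len(blocks)) if j != k]))
            folds.append((train, val))
        return {"test": test_idx, "folds": folds}


def _validation_loss(est, X_val, y_val) -> float:
    y_val = np.asarray(y_val, dtype=int)
    if hasattr(est, "predict_proba"):
        p = np.clip(est.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
        return float(-np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))
    pred = est.decision_function(X_val)
    t = np.where(y_val > 0, 1.0, -1.0)
    return float(((t - pred) ** 2).mean())


def select_hyperparameters(
    factory,
    grid: Sequence[dict],
    X: np.ndarray,
    y: np.ndarray,
    scheme: Optional[SplitScheme] = None,
    seed: int = 0,
) -> tuple[dict, list]:
    """Pick the grid entry with the lowest mean validation loss.

    ``factory(config)`` must return an unfitted estimator.  Entries whose
    fits raise (e.g. structurally invalid settings) score infinity and are
    thereby excluded.  Returns ``(best_config, table)`` where the table has
    one ``{config, fold_losses, mean_loss}`` row per entry.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    scheme = scheme or SplitScheme(test_fraction=0.0)
    splits = scheme.split(len(y), seed)
    table = []
    for config in grid:
        losses = []
        for train, val in splits["folds"]:
            try:
                est = factory(config)
                est.fit(X[train], y[train])
                losses.append(_validation_loss(est, X[val], y[val]))
            except Exception:
                losses.append(np.inf)
        table.append({"config": config, "fold_losses": losses,
                      "mean_loss": float(np.mean(losses))})
    best = min(range(len(grid)), key=lambda i: table[i]["mean_loss"])
    return grid[best], table
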