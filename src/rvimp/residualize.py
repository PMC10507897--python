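"""Residualization of the feature of interest.

The feature of interest Z is decomposed into the part explained by the
remaining predictors and a residual:  a model g from a chosen class G is
fitted by least squares to predict Z from X_{-p}, and

    Z = g(X_{-p}) + eps_Z .

The residual vector eps_Z carries the information in Z that the other
predictors cannot explain; its permutation importance in the adjusted
forest is what the resampling test examines.

Model classes: ordinary least squares (low-dimensional default), ridge
regression (penalised, preferable when p is large relative to n), or a
random forest (non-linear g).  For the forest class the in-sample
residuals are taken against *out-of-bag* predictions: an overfitted g
would otherwise shrink the residuals toward zero artificially and with
them the residual importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from . import _tree
from .datasets import REGRESSION, TabularDataset
from .forest import ForestSpec, train_forest

__all__ = ["ResidualModelSpec", "ResidualModel", "fit_g", "residuals"]

OLS = "ols_linear"
RIDGE = "ridge"
RANDOM_FOREST = "random_forest"
_CLASSES = (OLS, RIDGE, RANDOM_FOREST)


@dataclass(frozen=True)
class ResidualModelSpec:
    """Choice of model class G and its hyperparameters."""

    model_class: str = OLS
    penalty: float = 1.0  # ridge L2 weight
    forest_spec: ForestSpec = field(default_factory=ForestSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_class not in _CLASSES:
            raise ValueError(f"model_class must be one of {_CLASSES}")
        if self.penalty < 0:
            raise ValueError("ridge penalty must be >= 0")

    def with_seed(self, seed: int) -> "ResidualModelSpec":
        if self.model_class == RANDOM_FOREST:
            return ResidualModelSpec(
                self.model_class, self.penalty, self.forest_spec.with_seed(seed), int(seed)
            )
        return ResidualModelSpec(self.model_class, self.penalty, self.forest_spec, int(seed))


class ResidualModel:
    """Fitted g; predicts Z from the remaining predictors."""

    def __init__(self, spec, columns, kind, state, insample_loss, oob_loss=None):
        self.spec = spec
        self.columns = list(columns)
        self.kind = kind
        self._state = state
        self.insample_loss = insample_loss
        self.oob_loss = oob_loss

    def predict(self, X_minus) -> np.ndarray:
        X = _as_matrix(X_minus, self.columns)
        if self.kind in (OLS, RIDGE):
            coef, intercept = self._state["coef"], self._state["intercept"]
            return X @ coef + intercept
        forest = self._state["forest"]
        acc = np.zeros(X.shape[0])
        X = np.ascontiguousarray(X)
        for tr in forest.trees:
            acc += _tree.predict_tree(*tr, X)
        return acc / forest.n_trees

    def _training_residuals(self, X: np.ndarray, z: np.ndarray) -> np.ndarray | None:
        """OOB residuals when (X, z) is the training block (forest g)."""
        if self.kind != RANDOM_FOREST:
            return None
        Xtrain = self._state["X_train"]
        if X.shape != Xtrain.shape or not np.array_equal(X, Xtrain):
            return None
        return z - self._state["oob_pred"]


def _as_matrix(X_minus, columns=None) -> np.ndarray:
    if isinstance(X_minus, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in X_minus.columns]
            if missing:
                raise ValueError(f"missing columns in X_minus: {missing}")
            X_minus = X_minus[columns]
        return np.ascontiguousarray(X_minus.to_numpy(), dtype=np.float64)
    X = np.ascontiguousarray(np.asarray(X_minus), dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X_minus must be 2-dimensional")
    if columns is not None and X.shape[1] != len(columns):
        raise ValueError(
            f"X_minus has {X.shape[1]} columns, model was fitted on {len(columns)}"
        )
    return X


def _reject_non_continuous(z: np.ndarray) -> None:
    uniq = np.unique(z)
    if len(uniq) == 2 and set(uniq) <= {0.0, 1.0}:
        raise ValueError(
            "Z appears binary; residualization is defined for continuous Z only"
        )


def fit_g(X_minus, z: np.ndarray, spec: ResidualModelSpec) -> ResidualModel:
    """Least-squares fit of Z on the remaining predictors within class G.

    Exact for OLS/ridge; ensemble approximation for the forest class.  A
    constant Z is fitted by the intercept alone.
    """
    columns = list(X_minus.columns) if isinstance(X_minus, pd.DataFrame) else None
    X = _as_matrix(X_minus)
    z = np.asarray(z, dtype=np.float64).ravel()
    if X.shape[0] != len(z):
        raise ValueError("X_minus and z must have the same number of rows")
    if len(z) < 2:
        raise ValueError("need at least 2 rows to fit g")
    _reject_non_continuous(z)
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]

    if spec.model_class == OLS:
        A = np.column_stack([np.ones(len(z)), X])
        beta, *_ = np.linalg.lstsq(A, z, rcond=None)
        state = {"coef": beta[1:], "intercept": float(beta[0])}
        pred = A @ beta
        return ResidualModel(spec, columns, OLS, state, float(np.mean((z - pred) ** 2)))

    if spec.model_class == RIDGE:
        # standardize internally so the penalty is scale-free; coefficients
        # are stored back on the original scale
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        model = Ridge(alpha=spec.penalty, fit_intercept=True)
        model.fit(Xs, z)
        coef = model.coef_ / sd
        intercept = float(model.intercept_ - (mu * coef).sum())
        state = {"coef": coef, "intercept": intercept}
        pred = X @ coef + intercept
        return ResidualModel(spec, columns, RIDGE, state, float(np.mean((z - pred) ** 2)))

    # random forest g
    data = TabularDataset(pd.DataFrame(X, columns=columns), z, REGRESSION)
    forest = train_forest(data, spec.forest_spec)
    acc = np.zeros(len(z))
    cnt = np.zeros(len(z))
    for tr, o in zip(forest.trees, forest.oob):
        if len(o) == 0:
            continue
        acc[o] += _tree.predict_tree(*tr, np.ascontiguousarray(X[o]))
        cnt[o] += 1
    never_oob = cnt == 0
    oob_pred = np.empty(len(z))
    oob_pred[~never_oob] = acc[~never_oob] / cnt[~never_oob]
    if never_oob.any():
        warnings.warn(
            f"{int(never_oob.sum())} row(s) were never out-of-bag; "
            "their residuals use the full-forest prediction",
            stacklevel=2,
        )
        full = np.zeros(int(never_oob.sum()))
        Xn = np.ascontiguousarray(X[never_oob])
        for tr in forest.trees:
            full += _tree.predict_tree(*tr, Xn)
        oob_pred[never_oob] = full / forest.n_trees
    state = {"forest": forest, "oob_pred": oob_pred, "X_train": X.copy()}
    insample = float(np.mean((z - ResidualModel(spec, columns, RANDOM_FOREST, state, 0.0).predict(X)) ** 2))
    oob_loss = float(np.mean((z - oob_pred) ** 2))
    return ResidualModel(spec, columns, RANDOM_FOREST, state, insample, oob_loss)


def residuals(model: ResidualModel, X_minus, z: np.ndarray) -> np.ndarray:
    """eps_Z = z - g(X_minus).

    For a forest g evaluated on its own training block the prediction is
    the out-of-bag one (see module docstring).
    """
    X = _as_matrix(X_minus, model.columns)
    z = np.asarray(z, dtype=np.float64).ravel()
    if X.shape[0] != len(z):
        raise ValueError("X_minus and z must have the same number of rows")
    oob_res = model._training_residuals(X, z)
    eps = oob_res if oob_res is not None else z - model.predict(X)
    # residuals at float-rounding scale are an exactly explained Z; snap
    # them to zero so the adjusted forest cannot treat the rounding noise
    # as a row fingerprint
    scale = max(1.0, float(np.max(np.abs(z)))) if len(z) else 1.0
    if np.max(np.abs(eps)) <= 1e-10 * scale:
        return np.zeros_like(eps)
    return eps
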