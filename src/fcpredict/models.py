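"""Feature-only predictors and the shared scaling step.

The baseline model predicts the training-target mean; linear regression and
random-forest regression use only the seven single-neuron features.  All
models see standard-scaled inputs and targets, with the scaler fitted on the
training split only.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold

log = logging.getLogger(__name__)

__all__ = [
    "StandardScaler1D",
    "standard_scale",
    "baseline_predict",
    "linear_fit_predict",
    "forest_fit_predict",
    "DEFAULT_FOREST_GRID",
]


class StandardScaler1D:
    """Column-wise standard scaler that drops zero-variance train columns."""

    def fit(self, x: np.ndarray) -> "StandardScaler1D":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0)
        self.keep_ = self.sd_ > 0
        if not np.all(self.keep_):
            log.warning("dropping %d zero-variance columns", int((~self.keep_).sum()))
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        return z

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return z * self.sd_[self.keep_] + self.mean_[self.keep_]


def standard_scale(
    train_values: np.ndarray, test_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, StandardScaler1D]:
    """Scale train to mean 0 / SD 1 per column; transform test with the
    *train* statistics (the test split never leaks into the scaler)."""
    scaler = StandardScaler1D().fit(train_values)
    return scaler.transform(train_values), scaler.transform(test_values), scaler


def baseline_predict(train_targets: np.ndarray, n_test: int) -> np.ndarray:
    """Constant predictor: the mean of the training targets."""
    train_targets = np.asarray(train_targets, dtype=float)
    if train_targets.size == 0:
        raise ValueError("empty training targets")
    return np.full(n_test, train_targets.mean())


def linear_fit_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Ordinary least squares with intercept (scikit-learn defaults)."""
    train_x = np.atleast_2d(train_x)
    if train_x.shape[0] <= train_x.shape[1]:
        raise ValueError("need more training rows than features")
    model = LinearRegression().fit(train_x, train_y)
    return model.predict(np.atleast_2d(test_x))


DEFAULT_FOREST_GRID = {"n_estimators": [100], "max_depth": [None, 5]}


def forest_fit_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    grid: dict | None = None,
    seed: int = 0,
    inner_cv: int = 3,
) -> np.ndarray:
    """Random-forest regression with an inner grid search.

    The grid is selected by seeded K-fold validation on the training split
    only; the winning configuration is refitted on the full training split.
    """
    grid = DEFAULT_FOREST_GRID if grid is None else grid
    if not grid:
        raise ValueError("empty grid")
    base = RandomForestRegressor(random_state=seed)
    n_candidates = int(np.prod([len(v) for v in grid.values()]))
    if n_candidates == 1:
        params = {k: v[0] for k, v in grid.items()}
        model = RandomForestRegressor(random_state=seed, **params).fit(train_x, train_y)
    else:
        cv = KFold(n_splits=inner_cv, shuffle=True, random_state=seed)
        search = GridSearchCV(base, grid, cv=cv, scoring="neg_mean_squared_error")
        search.fit(train_x, train_y)
        model = search.best_estimator_
    return model.predict(np.atleast_2d(test_x))
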