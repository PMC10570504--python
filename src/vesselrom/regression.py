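"""Chained random-forest regression from 2-D shape coordinates to POD coefficients.

One random forest per retained POD mode, organised as a regressor chain: the
forest for mode j receives the two embedding coordinates plus the chain's
predictions for the upstream modes as features, so correlations between mode
coefficients are exploited.  By default the upstream features seen during
training are the already-fitted forests' own (in-sample) predictions, which
matches what the chain sees at predict time; the variant that trains on the
true upstream coefficients is available via ``cascade="true"``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["ChainedForestRegressor", "coefficient_rmse_percent"]


class ChainedForestRegressor(RegressorMixin, BaseEstimator):
    """Regressor chain of per-mode random forests.

    Parameters
    ----------
    n_estimators : int
        Trees per forest (default 70).
    max_depth : int
        Maximum tree depth (default 20).
    order : sequence of int or None
        Chain order as a permutation of target indices; None chains targets
        in their given order (modes sorted by descending singular value).
    cascade : {"predicted", "true"}
        Upstream features used during training: the chain's own in-sample
        predictions, or the true coefficients.
    random_state : int
        Seed; fit and predict are deterministic given it.
    """

    def __init__(
        self,
        n_estimators: int = 70,
        max_depth: int = 20,
        order=None,
        cascade: str = "predicted",
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.order = order
        self.cascade = cascade
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching sample counts")
        if self.cascade not in ("predicted", "true"):
            raise ValueError("cascade must be 'predicted' or 'true'")
        k = Y.shape[1]
        order = np.arange(k) if self.order is None else np.asarray(self.order)
        if sorted(order) != list(range(k)):
            raise ValueError("order must be a permutation of the target indices")

        self.order_ = order
        self.estimators_ = []
        upstream = np.empty((X.shape[0], 0))
        for step, j in enumerate(order):
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=self.random_state + step,
            )
            feats = np.hstack([X, upstream])
            rf.fit(feats, Y[:, j])
            self.estimators_.append(rf)
            nxt = rf.predict(feats) if self.cascade == "predicted" else Y[:, j]
            upstream = np.hstack([upstream, nxt[:, None]])
        self.n_features_in_ = X.shape[1]
        self.n_targets_ = k
        return self

    def predict(self, X) -> np.ndarray:
        """Thread queries through the chain; returns (n, k) coefficients."""
        check_is_fitted(self, "estimators_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features")
        out = np.empty((X.shape[0], self.n_targets_))
        upstream = np.empty((X.shape[0], 0))
        for rf, j in zip(self.estimators_, self.order_):
            pred = rf.predict(np.hstack([X, upstream]))
            out[:, j] = pred
            upstream = np.hstack([upstream, pred[:, None]])
        return out


def coefficient_rmse_percent(
    predicted: np.ndarray,
    true: np.ndarray,
    mode: int,
    training_range: float | None = None,
) -> float:
    """RMSE of one mode's predicted coefficients as a percent of its range.

    Normalised by ``training_range`` when given, else by the range of the true
    coefficients for that mode.  A zero range makes the metric undefined and
    returns NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true coefficient arrays must match")
    err = predicted[:, mode] - true[:, mode]
    rmse = float(np.sqrt(np.mean(err**2)))
    rng = (
        float(true[:, mode].max() - true[:, mode].min())
        if training_range is None
        else float(training_range)
    )
    if rng == 0.0:
        return float("nan")
    return 100.0 * rmse / rng
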