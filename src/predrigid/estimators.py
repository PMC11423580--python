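"""Scikit-learn style front ends.

:class:`RigidityRegressor` is a weighted ridge regressor over gradient
rows whose fitted state exposes the whole rigidity family (PR, LPR,
CPR, predictive variance, curvature probes); because rigidities depend
only on the loss curvature, it can also be fitted without targets.
:class:`GreedyAugmenter` wraps PR-guided greedy pool selection.  Both
follow the estimator contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, input validation), so they
compose with sklearn model selection where a design matrix is the
natural interface; the function modules they wrap remain available for
row-level workflows.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import FeatureSet, TargetRow, Weights, fit_ridge
from .hessian import HessianState, build_hessian, default_ridge, rank_one_update
from .rigidity import (
    QueryVector,
    component_prediction_rigidity,
    local_prediction_rigidity,
    prediction_rigidity,
    variance_from_pr,
)
from .selection import SelectionTrace, greedy_augment

__all__ = ["RigidityRegressor", "GreedyAugmenter"]


def _rows_from_arrays(X, y=None, sample_weight=None) -> list[TargetRow]:
    n = X.shape[0]
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if y.shape != (n,) or w.shape != (n,):
        raise ValueError("y and sample_weight must match the number of rows")
    return [
        TargetRow(grad_w=X[i], weight=float(w[i]), value=float(y[i])) for i in range(n)
    ]


class RigidityRegressor(RegressorMixin, BaseEstimator):
    """Weighted ridge model with prediction-rigidity introspection.

    Parameters
    ----------
    alpha : float or None
        Ridge regularization folded into the curvature as ``alpha * I``.
        ``None`` selects a scale-aware default (1e-8 x mean diagonal of
        the data term).
    """

    def __init__(self, alpha: float | None = None):
        self.alpha = alpha

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None, sample_weight=None):
        """Fit from a design matrix of gradient rows.

        ``y=None`` builds only the loss curvature (rigidities are
        target-free); predictions then require a later ``fit`` with
        targets.
        """
        X = check_array(X, dtype=float)
        rows = _rows_from_arrays(X, y, sample_weight)
        return self.fit_rows(rows, has_targets=y is not None)

    def fit_rows(self, rows: Sequence[TargetRow], has_targets: bool = True):
        """Fit directly from assembled target rows (energy/force/stress)."""
        rows = list(rows)
        if not rows:
            raise ValueError("need at least one row")
        ridge = default_ridge(rows) if self.alpha is None else float(self.alpha)
        self.ridge_ = ridge
        self.hessian_state_ = build_hessian(rows, ridge=ridge)
        self.n_features_in_ = self.hessian_state_.d
        if has_targets:
            self.coef_ = fit_ridge(rows, ridge=ridge).w
        return self

    def add_samples(self, X, sample_weight=None):
        """Rank-one update the fitted curvature with new gradient rows
        (predictive coefficients are not refitted)."""
        check_is_fitted(self, "hessian_state_")
        X = check_array(X, dtype=float)
        h = self.hessian_state_
        for row in _rows_from_arrays(X, sample_weight=sample_weight):
            h = rank_one_update(h, row)
        self.hessian_state_ = h
        return self

    # -- prediction and rigidity ------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_

    def rigidity(self, X) -> np.ndarray:
        """Global PR of each query gradient row."""
        check_is_fitted(self, "hessian_state_")
        X = check_array(X, dtype=float)
        h = self.hessian_state_
        return np.array(
            [prediction_rigidity(h, QueryVector(g, tag="global")) for g in X]
        )

    def local_rigidity(self, fs: FeatureSet, env_ids=None) -> np.ndarray:
        """LPR of the given environments (default: all)."""
        check_is_fitted(self, "hessian_state_")
        ids = range(fs.n_env) if env_ids is None else env_ids
        h = self.hessian_state_
        return np.array([local_prediction_rigidity(h, fs, int(e)) for e in ids])

    def component_rigidity(self, fs: FeatureSet, structure_id: int, block) -> float:
        """CPR of one additive component of a structure's prediction."""
        check_is_fitted(self, "hessian_state_")
        return component_prediction_rigidity(self.hessian_state_, fs, structure_id, block)

    def predict_variance(self, X, scale: float = 1.0) -> np.ndarray:
        """Inverse-rigidity predictive variance, scaled by a calibrated
        noise variance (default 1: uncalibrated)."""
        return np.array([variance_from_pr(r, scale) for r in self.rigidity(X)])


class GreedyAugmenter(BaseEstimator):
    """PR-guided greedy selection from a candidate pool.

    Parameters
    ----------
    k : int
        Number of candidates to select.
    objective : {'mean', 'min', 'sum'}
        Aggregation of the target PRs the greedy step maximizes.
    """

    def __init__(self, k: int = 10, objective: str = "mean"):
        self.k = k
        self.objective = objective

    def fit(self, pool, targets, hessian: HessianState):
        """Run the greedy loop; records ``trace_`` and the updated
        curvature ``hessian_state_``.  ``pool`` maps candidate id ->
        list of target rows; ``targets`` are query vectors."""
        trace, h = greedy_augment(
            hessian, pool, targets, k=self.k, objective=self.objective
        )
        self.trace_: SelectionTrace = trace
        self.hessian_state_ = h
        self.chosen_ids_ = trace.chosen_ids
        return self
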