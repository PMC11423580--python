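"""Prediction rigidities: global PR, local LPR, component-wise CPR.

A prediction rigidity quantifies how strongly the training loss resists
perturbing one model prediction away from its unconstrained optimum.
For a prediction whose weight-space gradient is ``g`` and a loss with
curvature ``H`` (see :mod:`predrigid.hessian`), constraining the
prediction to move by ``delta`` raises the minimum loss by exactly

    dL = R * delta**2,      R = 1 / (g^T H^{-1} g).

``R`` is the PR.  Choosing ``g`` selects what is being assessed:

* global PR  — ``g`` is the sum of a structure's environment rows;
* LPR        — ``g`` is a single environment row (local prediction);
* CPR        — ``g`` is the global row masked to one additive component
               (e.g. a body-order or a short-/long-range block).

For deep models with a linear readout the same formulas apply to the
last-layer latent features (``last_layer_pr``), and ``1/R`` scaled by a
noise variance is a weight-posterior predictive variance
(``variance_from_pr``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .core import FeatureSet, TargetRow, Weights, loss_value
from .hessian import HessianState, build_hessian, metric_norm

__all__ = [
    "QueryVector",
    "RigidityReport",
    "CurvatureProbe",
    "ZeroQueryError",
    "global_query",
    "local_query",
    "component_query",
    "prediction_rigidity",
    "local_prediction_rigidity",
    "component_prediction_rigidity",
    "last_layer_pr",
    "last_layer_lpr",
    "variance_from_pr",
    "curvature_probe",
    "normalize_report",
    "monitor_trajectory",
]

QueryTag = Literal["global", "local", "component"]


class ZeroQueryError(ValueError):
    """A zero query gradient: the quantity is not represented by the model,
    so its rigidity is undefined (never silently infinite)."""


@dataclass
class QueryVector:
    """A prediction's weight-space gradient ``g`` with provenance."""

    g: np.ndarray
    tag: QueryTag = "global"
    block: tuple[int, int] | None = None
    subject_id: object = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1:
            raise ValueError("query gradient must be a vector")
        if self.tag == "component":
            if self.block is None:
                raise ValueError("component queries require a block range")
            start, stop = self.block
            outside = np.concatenate([self.g[:start], self.g[stop:]])
            if outside.size and np.any(outside != 0):
                raise ValueError("component query must be zero outside its block")


def global_query(fs: FeatureSet, structure_id: int) -> QueryVector:
    return QueryVector(fs.global_row(structure_id), tag="global", subject_id=structure_id)


def local_query(fs: FeatureSet, env_id: int) -> QueryVector:
    if not 0 <= env_id < fs.n_env:
        raise KeyError(f"unknown environment id {env_id}")
    return QueryVector(fs.env_features[env_id].copy(), tag="local", subject_id=env_id)


def component_query(
    fs: FeatureSet, structure_id: int, block: "str | tuple[int, int]"
) -> QueryVector:
    start, stop = fs.block_range(block)
    g = np.zeros(fs.d)
    g[start:stop] = fs.global_row(structure_id)[start:stop]
    return QueryVector(g, tag="component", block=(start, stop), subject_id=structure_id)


@dataclass
class RigidityReport:
    """Computed rigidities with normalization metadata."""

    values: dict
    tag: QueryTag = "global"
    normalization: Literal["raw", "max", "reference"] = "raw"
    reference: float | None = None
    ridge: float = 0.0
    normalized: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": k,
                "tag": self.tag,
                "value": v,
                "normalized": self.normalized.get(k, np.nan),
            }
            for k, v in self.values.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "tag": self.tag,
            "normalization": self.normalization,
            "reference": self.reference,
            "ridge": self.ridge,
            "values": {str(k): v for k, v in self.values.items()},
            "normalized": {str(k): v for k, v in self.normalized.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class CurvatureProbe:
    """Result of a constrained-refit loss probe."""

    delta: float
    delta_loss: float


def prediction_rigidity(h: HessianState, q: QueryVector) -> float:
    """``R = 1 / (g^T H^{-1} g)`` for the query's gradient."""
    if not np.any(q.g):
        raise ZeroQueryError(
            f"query {q.subject_id!r} has a zero gradient; rigidity undefined"
        )
    m = metric_norm(h, q.g)
    if m == 0.0:
        raise ZeroQueryError(
            f"query {q.subject_id!r} has zero H^-1-metric norm; rigidity undefined"
        )
    return 1.0 / m


def local_prediction_rigidity(h: HessianState, fs: FeatureSet, env_id: int) -> float:
    """LPR of one environment: PR with ``g`` = that environment's row."""
    return prediction_rigidity(h, local_query(fs, env_id))


def component_prediction_rigidity(
    h: HessianState, fs: FeatureSet, structure_id: int, block: "str | tuple[int, int]"
) -> float:
    """CPR of one additive component of a structure's global prediction."""
    return prediction_rigidity(h, component_query(fs, structure_id, block))


def last_layer_pr(F: np.ndarray, f_star: np.ndarray, ridge: float) -> float:
    """PR from last-layer features: ``1 / (f* (F^T F + ridge I)^{-1} f*)``.

    ``F`` stacks the training samples' last-layer feature rows (one row
    per training target, unit loss weight); ``f_star`` is the query
    sample's feature vector.  Equals the generic Hessian path with
    unit-weight rows.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    f_star = np.asarray(f_star, dtype=float)
    if F.size and F.shape[1] != f_star.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: F has {F.shape[1]} columns, "
            f"f_star has {f_star.shape[0]}"
        )
    rows = [TargetRow(grad_w=row, weight=1.0) for row in F] if F.size else []
    h = build_hessian(rows, ridge=ridge, dim=f_star.shape[0])
    return prediction_rigidity(h, QueryVector(f_star, tag="global"))


def last_layer_lpr(F: np.ndarray, f_j: np.ndarray, ridge: float) -> float:
    """Last-layer LPR: same form with the environment's latent features."""
    return last_layer_pr(F, f_j, ridge)


def variance_from_pr(R: float, scale: float = 1.0) -> float:
    """Predictive variance ``scale / R`` (``scale`` = calibrated noise
    variance; default 1 leaves the inverse rigidity uncalibrated)."""
    if R <= 0:
        raise ValueError("rigidity must be positive")
    return scale / R


def curvature_probe(
    rows: Sequence[TargetRow],
    ridge: float,
    w_o: Weights,
    q: QueryVector,
    delta: float,
) -> CurvatureProbe:
    """Constrained refit: move prediction ``q`` by ``delta``, re-minimize.

    Solves ``min_w L(w)  s.t.  g.w = g.w_o + delta`` through the exact
    KKT displacement ``dw = delta * H^{-1} g / (g^T H^{-1} g)`` and
    evaluates the loss at both points directly, so the returned
    ``delta_loss`` is an honest refit measurement, not the identity
    ``R * delta**2`` it is expected to reproduce.
    """
    if not np.any(q.g):
        raise ZeroQueryError("cannot constrain a prediction with zero gradient")
    h = build_hessian(rows, ridge=ridge)
    x = h.solve(q.g)
    dw = delta * x / float(q.g @ x)
    base = loss_value(rows, ridge, w_o.w)
    moved = loss_value(rows, ridge, w_o.w + dw)
    return CurvatureProbe(delta=delta, delta_loss=max(moved - base, 0.0))


def normalize_report(
    rep: RigidityReport,
    mode: Literal["max", "reference"] = "max",
    reference: float | None = None,
) -> RigidityReport:
    """Divide rigidities by the max observed value or a supplied reference."""
    if not rep.values:
        raise ValueError("cannot normalize an empty report")
    if mode == "max":
        ref = max(rep.values.values())
    elif mode == "reference":
        if reference is None or reference <= 0:
            raise ValueError("reference mode needs a positive reference value")
        ref = reference
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    normalized = {k: v / ref for k, v in rep.values.items()}
    return replace(rep, normalization=mode, reference=ref, normalized=normalized)


def monitor_trajectory(
    h: HessianState,
    frame_rows: Sequence[QueryVector],
    reference_prs: Sequence[float],
    window: int = 200,
) -> pd.DataFrame:
    """Relative PR along a trajectory with a trailing moving average.

    Each frame's PR is divided by the mean reference PR (e.g. the test
    set average); the moving average is trailing over ``window`` frames,
    with shorter prefixes averaged over the frames available.
    """
    if len(frame_rows) == 0:
        raise ValueError("empty trajectory")
    reference_prs = np.asarray(reference_prs, dtype=float)
    if reference_prs.size == 0:
        raise ValueError("need at least one reference PR")
    if window < 1:
        raise ValueError("window must be >= 1")
    prs = np.array([prediction_rigidity(h, q) for q in frame_rows])
    rel = prs / reference_prs.mean()
    series = pd.Series(rel)
    return pd.DataFrame(
        {
            "frame": np.arange(len(frame_rows)),
            "pr": prs,
            "relative_pr": rel,
            "moving_average": series.rolling(window, min_periods=1).mean().to_numpy(),
        }
    )
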