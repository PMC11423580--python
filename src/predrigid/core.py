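"""Additive linear-readout models of molecular properties.

A structure's global prediction is the sum of per-environment local
predictions, each a linear readout ``w . f_j`` of an environment feature
row ``f_j`` (a descriptor vector or the last-layer latent features of a
deep model).  This module holds the in-memory containers for such models
(:class:`FeatureSet`, :class:`TargetRow`, :class:`Weights`) and the
operations that assemble weighted regression rows for energy-like and
force-like targets and fit ridge reference weights.

Conventions
-----------
* Loss: ``L(w) = sum_i lambda_i (g_i . w - y_i)**2 + ridge * |w|**2``
  (no factor 1/2).  All rigidity magnitudes in :mod:`predrigid.rigidity`
  are stated under this convention; a loss with a global prefactor ``c``
  rescales every rigidity by ``c``.
* Forces are negative gradients of the predicted energy.
* Environments and structures are 0-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureSet",
    "TargetRow",
    "Weights",
    "RankDeficiencyError",
    "assemble_energy_row",
    "assemble_force_rows",
    "fit_ridge",
    "predict",
]

TargetKind = Literal["energy", "force", "stress", "generic"]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when an unregularized normal system is singular."""


@dataclass
class FeatureSet:
    """Per-environment feature rows plus the structure map.

    Parameters
    ----------
    env_features : (n_env, d) array
        One feature row per local environment (atom, bead, cluster).
    structure_of_env : (n_env,) int array
        Index of the structure each environment belongs to.
    blocks : mapping label -> (start, stop)
        Half-open column ranges labelling additive prediction components
        (e.g. body order ``nu`` or short-/long-range).  Ranges must be
        disjoint and tile a prefix of the columns.
    env_gradients : (n_env, n_coords, d) array, optional
        ``d f_j / d x`` per environment and structure coordinate (units
        1/length); required to assemble force rows.  Structures with
        fewer coordinates than ``n_coords`` are zero-padded.
    """

    env_features: np.ndarray
    structure_of_env: np.ndarray
    blocks: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    env_gradients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.env_features = np.asarray(self.env_features, dtype=float)
        self.structure_of_env = np.asarray(self.structure_of_env, dtype=np.intp)
        if self.env_features.ndim != 2:
            raise ValueError("env_features must be 2-D (n_env, d)")
        if self.structure_of_env.shape != (self.env_features.shape[0],):
            raise ValueError(
                "structure_of_env must have one entry per environment "
                f"(got {self.structure_of_env.shape}, need ({self.n_env},))"
            )
        self.blocks = dict(self.blocks)
        self._check_blocks()
        if self.env_gradients is not None:
            self.env_gradients = np.asarray(self.env_gradients, dtype=float)
            if self.env_gradients.ndim != 3 or self.env_gradients.shape[::2] != (
                self.n_env,
                self.d,
            ):
                raise ValueError(
                    "env_gradients must have shape (n_env, n_coords, d)="
                    f"({self.n_env}, *, {self.d}); got {self.env_gradients.shape}"
                )

    def _check_blocks(self) -> None:
        spans = sorted(self.blocks.items(), key=lambda kv: kv[1][0])
        edge = 0
        for label, (start, stop) in spans:
            if not (0 <= start < stop <= self.d):
                raise ValueError(f"block {label!r} range ({start}, {stop}) out of bounds")
            if start != edge:
                raise ValueError(
                    f"blocks must be disjoint and tile a prefix of the columns; "
                    f"gap/overlap before block {label!r} at column {start}"
                )
            edge = stop

    @property
    def n_env(self) -> int:
        return self.env_features.shape[0]

    @property
    def d(self) -> int:
        return self.env_features.shape[1]

    @property
    def structure_ids(self) -> np.ndarray:
        return np.unique(self.structure_of_env)

    def envs_of(self, structure_id: int) -> np.ndarray:
        """Environment indices belonging to ``structure_id``."""
        mask = self.structure_of_env == structure_id
        if not mask.any():
            raise KeyError(f"unknown structure id {structure_id}")
        return np.flatnonzero(mask)

    def global_row(self, structure_id: int) -> np.ndarray:
        """Sum of the structure's environment rows (gradient of the global
        prediction with respect to the weights)."""
        return self.env_features[self.envs_of(structure_id)].sum(axis=0)

    def block_range(self, block: "str | tuple[int, int]") -> tuple[int, int]:
        """Resolve a block label or explicit ``(start, stop)`` range."""
        if isinstance(block, str):
            try:
                return self.blocks[block]
            except KeyError:
                raise KeyError(
                    f"block {block!r} not declared; known: {sorted(self.blocks)}"
                ) from None
        start, stop = block
        if (start, stop) not in self.blocks.values():
            raise KeyError(f"block range {(start, stop)} not declared in this FeatureSet")
        return int(start), int(stop)


@dataclass
class TargetRow:
    """One scalar regression target: gradient row, loss weight, value."""

    grad_w: np.ndarray
    weight: float = 1.0
    kind: TargetKind = "generic"
    value: float = 0.0

    def __post_init__(self) -> None:
        self.grad_w = np.asarray(self.grad_w, dtype=float)
        if self.grad_w.ndim != 1:
            raise ValueError("grad_w must be a vector")
        if not np.all(np.isfinite(self.grad_w)):
            raise ValueError("grad_w must be finite")
        if self.weight < 0:
            raise ValueError("loss weight must be nonnegative")


@dataclass
class Weights:
    """Readout weight vector with provenance."""

    w: np.ndarray
    provenance: Literal["fitted", "supplied"] = "supplied"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")


def assemble_energy_row(
    fs: FeatureSet, structure_id: int, weight: float = 1.0, value: float = 0.0
) -> TargetRow:
    """Energy-like row: gradient is the sum of the structure's feature rows."""
    return TargetRow(
        grad_w=fs.global_row(structure_id), weight=weight, kind="energy", value=value
    )


def assemble_force_rows(
    fs: FeatureSet,
    structure_id: int,
    weight: float = 1.0,
    values: Sequence[float] | None = None,
) -> list[TargetRow]:
    """Force-like rows, one per structure coordinate.

    The row for coordinate ``a`` is ``-sum_j d f_j / d x_a`` over the
    structure's environments (force = minus the energy gradient).
    """
    if fs.env_gradients is None:
        raise ValueError("FeatureSet has no env_gradients; cannot assemble force rows")
    envs = fs.envs_of(structure_id)
    grad = -fs.env_gradients[envs].sum(axis=0)  # (n_coords, d)
    n_coords = grad.shape[0]
    if values is None:
        vals = np.zeros(n_coords)
    else:
        vals = np.asarray(values, dtype=float)
        if vals.shape != (n_coords,):
            raise ValueError(f"need {n_coords} force values, got {vals.shape}")
    return [
        TargetRow(grad_w=grad[a], weight=weight, kind="force", value=vals[a])
        for a in range(n_coords)
    ]


def _normal_system(
    rows: Sequence[TargetRow], ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    if not rows:
        raise ValueError("need at least one target row")
    G = np.stack([r.grad_w for r in rows])
    lam = np.array([r.weight for r in rows])
    y = np.array([r.value for r in rows])
    d = G.shape[1]
    A = (G.T * lam) @ G + ridge * np.eye(d)
    b = G.T @ (lam * y)
    return A, b


def fit_ridge(rows: Sequence[TargetRow], ridge: float = 0.0) -> Weights:
    """Minimize ``sum_i lambda_i (g_i.w - y_i)^2 + ridge |w|^2``.

    With ``ridge == 0`` the weighted normal matrix must be full rank;
    otherwise a :class:`RankDeficiencyError` names the deficiency.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    A, b = _normal_system(rows, ridge)
    if ridge == 0.0:
        rank = np.linalg.matrix_rank(A, hermitian=True)
        if rank < A.shape[0]:
            raise RankDeficiencyError(
                f"normal matrix is rank {rank} < {A.shape[0]}; "
                "add rows or set ridge > 0"
            )
    w = np.linalg.solve(A, b)
    return Weights(w=w, provenance="fitted")


def predict(w: Weights, g: np.ndarray) -> float:
    """Linear prediction ``g . w`` for a query gradient row ``g``."""
    g = np.asarray(g, dtype=float)
    if g.shape != w.w.shape:
        raise ValueError(f"dimension mismatch: query {g.shape} vs weights {w.w.shape}")
    return float(g @ w.w)


def loss_value(rows: Sequence[TargetRow], ridge: float, w: np.ndarray) -> float:
    """Evaluate the documented loss at ``w`` (used by curvature probes)."""
    w = np.asarray(w, dtype=float)
    total = ridge * float(w @ w)
    for r in rows:
        total += r.weight * (float(r.grad_w @ w) - r.value) ** 2
    return total
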