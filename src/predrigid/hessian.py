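"""Generalized Gauss-Newton loss Hessian: build, regularize, update, solve.

Under the package's loss convention (see :mod:`predrigid.core`) the
curvature of the quadratic loss is ``H = sum_i lambda_i g_i g_i^T +
ridge * I``: the outer-product (Gauss-Newton) form that needs only first
derivatives of the model and is exact for linear readouts.  Degenerate
(singular) ``H`` is the expected case for the partitioning problems this
package diagnoses, so the solve path is deliberate about it: a
symmetric positive-definite Cholesky factorization where possible, an
eigenvalue-clipped pseudo-solve when the unregularized system is
ill-conditioned, and an explicit error when a query vector leaves the
range of a singular Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, LinAlgError

from .core import TargetRow

__all__ = [
    "HessianState",
    "SingularHessianError",
    "build_hessian",
    "rank_one_update",
    "metric_norm",
    "default_ridge",
]

#: conditioning threshold beyond which an unregularized Hessian is treated
#: as singular and solved by eigenvalue clipping
COND_LIMIT = 1e12


class SingularHessianError(np.linalg.LinAlgError):
    """Raised when a solve against a singular Hessian is not well defined."""


@dataclass
class HessianState:
    """Symmetric PSD loss Hessian with the ridge folded in and a cached
    solve handle.

    ``matrix`` always stores the full ``H = data + ridge*I``; the factor
    is rebuilt lazily after updates so that any sequence of rank-one
    modifications stays consistent with the stored matrix.
    """

    matrix: np.ndarray
    ridge: float = 0.0
    update_count: int = 0
    _factor: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Hessian must be square")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if self.d else 0.0
        if asym > 1e-10 * max(1.0, np.max(np.abs(self.matrix))):
            raise ValueError(f"Hessian not symmetric (max asymmetry {asym:.2e})")
        # enforce exact symmetry so factorizations are well posed
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def d(self) -> int:
        return self.matrix.shape[0]

    def _get_factor(self) -> tuple:
        if self._factor is None:
            self._factor = self._factorize()
        return self._factor

    def _factorize(self) -> tuple:
        H = self.matrix
        if self.ridge > 0.0:
            try:
                return ("chol", cho_factor(H, lower=True))
            except (LinAlgError, np.linalg.LinAlgError):
                pass  # fall through to the eigen path
        vals, vecs = eigh(H)
        top = vals[-1] if len(vals) else 0.0
        if self.ridge == 0.0 and top > 0 and vals[0] > top / COND_LIMIT:
            # well-conditioned after all: use the cheap SPD path
            try:
                return ("chol", cho_factor(H, lower=True))
            except (LinAlgError, np.linalg.LinAlgError):
                pass
        clip = max(top, 0.0) / COND_LIMIT
        keep = vals > clip
        return ("eig", (vals[keep], vecs[:, keep]))

    def solve(self, b: np.ndarray, check_range: bool = True) -> np.ndarray:
        """Solve ``H x = b`` (vector or matrix right-hand side).

        On the pseudo-solve path, ``check_range`` verifies that ``b``
        lies in the numerical range of ``H`` and raises
        :class:`SingularHessianError` otherwise.
        """
        b = np.asarray(b, dtype=float)
        if b.shape[0] != self.d:
            raise ValueError(f"dimension mismatch: rhs {b.shape} vs H {self.matrix.shape}")
        kind, payload = self._get_factor()
        if kind == "chol":
            return cho_solve(payload, b)
        vals, vecs = payload
        proj = vecs.T @ b
        x = vecs @ (proj / vals[:, None] if b.ndim == 2 else proj / vals)
        if check_range:
            resid = self.matrix @ x - b
            scale = np.linalg.norm(b) or 1.0
            if np.linalg.norm(resid) > 1e-8 * scale:
                raise SingularHessianError(
                    "Hessian is singular and the right-hand side lies outside "
                    "its range; set ridge > 0 to regularize"
                )
        return x


def default_ridge(rows: Sequence[TargetRow]) -> float:
    """Scale-aware default regularization: 1e-8 x mean diagonal of the
    data term, negligible for well-posed systems."""
    if not rows:
        return 1e-8
    diag = np.zeros_like(rows[0].grad_w)
    for r in rows:
        diag += r.weight * r.grad_w**2
    mean = float(diag.mean())
    return 1e-8 * (mean if mean > 0 else 1.0)


def build_hessian(
    rows: Sequence[TargetRow], ridge: float = 0.0, dim: int | None = None
) -> HessianState:
    """Assemble ``H = sum_i lambda_i g_i g_i^T + ridge * I``.

    ``dim`` is only needed when ``rows`` is empty (pure-ridge Hessian).
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if not rows and ridge == 0.0:
        raise ValueError("need target rows or ridge > 0")
    if rows:
        d = rows[0].grad_w.shape[0]
        G = np.empty((len(rows), d))
        lam = np.empty(len(rows))
        for i, r in enumerate(rows):
            if r.grad_w.shape != (d,):
                raise ValueError(
                    f"inconsistent row dimensions: row {i} has {r.grad_w.shape}, "
                    f"expected ({d},)"
                )
            G[i] = r.grad_w
            lam[i] = r.weight
        H = (G.T * lam) @ G
    elif dim is not None:
        H = np.zeros((dim, dim))
    else:
        raise ValueError("cannot infer dimension from an empty row list; pass dim=")
    H[np.diag_indices_from(H)] += ridge
    return HessianState(matrix=H, ridge=ridge)


def rank_one_update(
    h: HessianState, row: TargetRow, weight: float | None = None
) -> HessianState:
    """Return a new state with ``H' = H + lambda g g^T``.

    ``weight`` overrides the row's loss weight; a negative value
    downdates (removes a previously added row), which is numerically
    risky near singularity and exists for exactly that bookkeeping.
    """
    g = row.grad_w
    lam = row.weight if weight is None else float(weight)
    if g.shape != (h.d,):
        raise ValueError(f"dimension mismatch: row {g.shape} vs H ({h.d}, {h.d})")
    H2 = h.matrix + lam * np.outer(g, g)
    return HessianState(matrix=H2, ridge=h.ridge, update_count=h.update_count + 1)


def metric_norm(h: HessianState, g: np.ndarray) -> float:
    """Quadratic form ``g^T H^{-1} g`` (the H^-1-metric squared norm)."""
    g = np.asarray(g, dtype=float)
    x = h.solve(g)
    val = float(g @ x)
    # symmetric PSD quadratic form: clip the tiny negative round-off
    return max(val, 0.0)
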