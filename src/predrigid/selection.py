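"""PR-guided dataset augmentation and LPR-based active-learning ranking.

Given a trained model's loss Hessian and a pool of candidate additions,
``greedy_augment`` iteratively selects the candidate that most increases
the prediction rigidity of a set of target predictions, updating the
Hessian as structures are selected.  Candidate gains are evaluated with
hypothetical low-rank (Woodbury) updates, so scoring a pool never
mutates the state; a guarantee worth knowing: adding a sample's own row
with loss weight ``lambda`` raises that sample's PR by exactly
``lambda``, so augmentation always helps the targeted prediction.

``rank_by_lpr`` orders local environments by ascending LPR (the lowest
LPR environment is the natural active-learning target), and
``lpr_enhancement`` scores named candidate-construction strategies by
the percent LPR change they would produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FeatureSet, TargetRow
from .hessian import HessianState, metric_norm, rank_one_update
from .rigidity import QueryVector, local_prediction_rigidity, prediction_rigidity

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "pr_gain",
    "prs_after",
    "greedy_augment",
    "rank_by_lpr",
    "lpr_enhancement",
]

Objective = Literal["mean", "min", "sum"]

_OBJECTIVES = {"mean": np.mean, "min": np.min, "sum": np.sum}


@dataclass
class SelectionStep:
    iteration: int
    candidate_id: object
    pr_before: dict
    pr_after: dict
    objective_value: float


@dataclass
class SelectionTrace:
    """Ordered log of greedy augmentation steps."""

    steps: list = field(default_factory=list)
    objective: Objective = "mean"
    pool_ids: list = field(default_factory=list)

    @property
    def chosen_ids(self) -> list:
        return [s.candidate_id for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {
                "iteration": s.iteration,
                "candidate_id": s.candidate_id,
                "objective_value": s.objective_value,
            }
            for k, v in s.pr_before.items():
                row[f"pr_before[{k}]"] = v
            for k, v in s.pr_after.items():
                row[f"pr_after[{k}]"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "objective": self.objective,
            "pool_ids": [str(i) for i in self.pool_ids],
            "steps": [
                {
                    "iteration": s.iteration,
                    "candidate_id": str(s.candidate_id),
                    "pr_before": {str(k): v for k, v in s.pr_before.items()},
                    "pr_after": {str(k): v for k, v in s.pr_after.items()},
                    "objective_value": s.objective_value,
                }
                for s in self.steps
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _target_key(q: QueryVector, i: int) -> object:
    return q.subject_id if q.subject_id is not None else i


def _current_prs(h: HessianState, targets: Sequence[QueryVector]) -> dict:
    return {
        _target_key(q, i): prediction_rigidity(h, q) for i, q in enumerate(targets)
    }


def prs_after(
    h: HessianState,
    candidate_rows: Sequence[TargetRow],
    targets: Sequence[QueryVector],
) -> dict:
    """Target PRs after hypothetically adding ``candidate_rows``.

    Uses the Woodbury identity on the candidate block, so ``h`` is not
    mutated and the cost is one multi-RHS solve per call.
    """
    rows = [r for r in candidate_rows if r.weight != 0.0]
    if not rows:
        return _current_prs(h, targets)
    U = np.stack([r.grad_w for r in rows])  # (k, d)
    lam = np.array([r.weight for r in rows])
    S = h.solve(U.T)  # (d, k): H^{-1} U^T
    K = np.diag(1.0 / lam) + U @ S  # (k, k) capacitance
    out = {}
    for i, q in enumerate(targets):
        m = metric_norm(h, q.g)
        c = S.T @ q.g  # (k,)
        m_new = m - float(c @ np.linalg.solve(K, c))
        if m_new <= 0:
            raise ValueError(
                "hypothetical update drove the metric norm nonpositive "
                "(downdate past singularity?)"
            )
        out[_target_key(q, i)] = 1.0 / m_new
    return out


def pr_gain(
    h: HessianState,
    candidate_rows: Sequence[TargetRow],
    targets: Sequence[QueryVector],
    objective: Objective = "mean",
) -> float:
    """Change in the PR objective from hypothetically adding the rows."""
    if not targets:
        raise ValueError("need at least one target query")
    agg = _OBJECTIVES[objective]
    before = agg(list(_current_prs(h, targets).values()))
    after = agg(list(prs_after(h, candidate_rows, targets).values()))
    return float(after - before)


def greedy_augment(
    h: HessianState,
    pool: Mapping[object, Sequence[TargetRow]],
    targets: Sequence[QueryVector],
    k: int,
    objective: Objective = "mean",
) -> tuple[SelectionTrace, HessianState]:
    """Select ``k`` pool candidates, each step taking the argmax PR gain.

    Ties are broken deterministically toward the lowest candidate id (in
    sorted-key order).  Returns the trace and the updated Hessian state.
    """
    if not pool:
        raise ValueError("empty candidate pool")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    if not targets:
        raise ValueError("need at least one target query")
    agg = _OBJECTIVES[objective]
    try:
        remaining = sorted(pool.keys())
    except TypeError:  # mixed id types
        remaining = sorted(pool.keys(), key=str)
    trace = SelectionTrace(objective=objective, pool_ids=list(remaining))
    for it in range(k):
        before = _current_prs(h, targets)
        best_id, best_after, best_val = None, None, -np.inf
        for cid in remaining:
            after = prs_after(h, pool[cid], targets)
            val = float(agg(list(after.values())))
            if val > best_val:  # strict: first (lowest) id wins ties
                best_id, best_after, best_val = cid, after, val
        for row in pool[best_id]:
            h = rank_one_update(h, row)
        remaining.remove(best_id)
        trace.steps.append(
            SelectionStep(
                iteration=it,
                candidate_id=best_id,
                pr_before=before,
                pr_after=best_after,
                objective_value=best_val,
            )
        )
    return trace, h


def rank_by_lpr(
    h: HessianState, fs: FeatureSet, env_ids: Sequence[int]
) -> list[tuple[int, float]]:
    """Environments in ascending LPR order (first = least rigid = the
    active-learning target); ties broken by ascending environment id."""
    if len(env_ids) == 0:
        raise ValueError("need at least one environment id")
    scored = [
        (int(e), local_prediction_rigidity(h, fs, int(e))) for e in env_ids
    ]
    return sorted(scored, key=lambda t: (t[1], t[0]))


def lpr_enhancement(
    h: HessianState,
    fs: FeatureSet,
    env_id: int,
    candidate_sets: Mapping[str, Sequence[TargetRow]],
    repeats: int = 1,
) -> dict[str, float]:
    """Percent LPR change of ``env_id`` for each named candidate set.

    ``repeats`` adds each set that many times (adding the same sample
    repeatedly keeps resolving the targeted degeneracy).  ``h`` is not
    mutated.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    q = QueryVector(fs.env_features[env_id].copy(), tag="local", subject_id=env_id)
    before = prediction_rigidity(h, q)
    out = {}
    for name, rows in candidate_sets.items():
        if not rows:
            raise ValueError(f"candidate set {name!r} is empty")
        scaled = [
            TargetRow(grad_w=r.grad_w, weight=repeats * r.weight, kind=r.kind, value=r.value)
            for r in rows
        ]
        after = prs_after(h, scaled, [q])[env_id]
        out[name] = 100.0 * (after - before) / before
    return out
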