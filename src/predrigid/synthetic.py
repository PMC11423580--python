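"""Synthetic feature systems emulating the experiment classes the
rigidity metrics are designed to diagnose.

Every generator is seed-deterministic (same seed, bit-identical arrays)
and produces a :class:`SyntheticSystem`: a :class:`~predrigid.core.FeatureSet`,
energy-like target rows derived from a known ground-truth weight vector
plus Gaussian noise, and scenario metadata.  The scenarios:

``gen_linear_system``
    A generic additive linear system with per-environment scale spread,
    the workhorse for calibration and committee studies.
``gen_two_domain``
    A source domain, a mixed candidate pool, and a held-out target
    domain whose feature directions the source only partially covers —
    the dataset-augmentation benchmark.
``gen_body_ordered``
    Block-structured features emulating a body-ordered descriptor whose
    blocks share a latent cluster geometry.  ``overlap_kappa`` controls
    self-interaction leakage of low-order content into higher-order
    blocks (0 = purified, orthogonal blocks).
``gen_two_scale``
    Short-range + long-range blocks for dimer-like samples.  With
    ``separated=True`` the LR block carries only the genuinely
    long-range (separation-decaying) signal; otherwise short-range
    content is double counted into the LR block.
``gen_toy_clusters`` / ``radial_descriptor``
    Random point clusters and a smooth Gaussian radial pair descriptor
    with analytic gradients, so force rows and finite-difference checks
    can run end to end.
``committee_variances``
    The subsampled-committee harness: variance of local predictions
    across ridge models trained on disjoint folds (or bootstrap
    samples), the empirical counterpart of the inverse LPR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FeatureSet, TargetRow, assemble_energy_row, fit_ridge
from .hessian import build_hessian
from .io import Structure
from .rigidity import QueryVector, component_prediction_rigidity, global_query

__all__ = [
    "SyntheticSystem",
    "TwoDomainTask",
    "gen_linear_system",
    "gen_two_domain",
    "gen_body_ordered",
    "gen_two_scale",
    "two_scale_learning_curve",
    "gen_toy_clusters",
    "radial_descriptor",
    "committee_variances",
    "selection_rmse",
]

#: body-order class labels -> correlation order (number of active blocks)
BODY_CLASSES = {"pair": 1, "triple": 2, "quad": 3, "quint": 4}


@dataclass
class SyntheticSystem:
    """A generated feature system with known ground truth."""

    featureset: FeatureSet
    rows: list  # training TargetRows
    true_weights: np.ndarray
    seed: int
    noise_sigma: float
    meta: dict = field(default_factory=dict)

    @property
    def train_structures(self) -> np.ndarray:
        return np.asarray(self.meta["train_structures"])

    @property
    def test_structures(self) -> np.ndarray:
        return np.asarray(self.meta.get("test_structures", []))


def _energy_rows(
    fs: FeatureSet, structure_ids, true_w, rng, noise_sigma
) -> list[TargetRow]:
    rows = []
    for sid in structure_ids:
        g = fs.global_row(int(sid))
        value = float(g @ true_w) + (rng.normal(0.0, noise_sigma) if noise_sigma else 0.0)
        rows.append(TargetRow(grad_w=g, weight=1.0, kind="energy", value=value))
    return rows


def gen_linear_system(
    n_structures: int = 200,
    envs_per_structure: int = 4,
    d: int = 8,
    noise_sigma: float = 0.1,
    seed: int = 0,
    env_scale_range: tuple[float, float] = (0.5, 2.0),
) -> SyntheticSystem:
    """Random additive linear system.

    Environment rows are standard normal scaled by a per-environment
    factor drawn uniformly from ``env_scale_range``; the scale spread
    produces a realistic range of local rigidities (dense vs sparse
    regions of feature space).  Energies are ``w_true . sum_j f_j``
    plus ``N(0, noise_sigma^2)`` noise.
    """
    if n_structures < 1 or envs_per_structure < 1 or d < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    n_env = n_structures * envs_per_structure
    scales = rng.uniform(*env_scale_range, size=n_env)
    feats = rng.standard_normal((n_env, d)) * scales[:, None]
    structure_of_env = np.repeat(np.arange(n_structures), envs_per_structure)
    fs = FeatureSet(env_features=feats, structure_of_env=structure_of_env)
    true_w = rng.standard_normal(d)
    rows = _energy_rows(fs, range(n_structures), true_w, rng, noise_sigma)
    return SyntheticSystem(
        featureset=fs,
        rows=rows,
        true_weights=true_w,
        seed=seed,
        noise_sigma=noise_sigma,
        meta={
            "scenario": "linear",
            "train_structures": list(range(n_structures)),
            "env_scale_range": env_scale_range,
        },
    )


@dataclass
class TwoDomainTask:
    """Augmentation benchmark: source-domain base set, mixed pool,
    held-out target domain."""

    base_rows: list
    pool: dict  # candidate id -> list[TargetRow]
    target_queries: list
    test_rows: list
    true_weights: np.ndarray
    meta: dict = field(default_factory=dict)


def _domain_features(rng, n, d, active, scale=1.0):
    X = np.zeros((n, d))
    X[:, active] = scale * rng.standard_normal((n, len(active)))
    return X


def gen_two_domain(
    n_base: int = 60,
    n_pool: int = 50,
    n_pool_target: int = 10,
    n_targets: int = 8,
    n_test: int = 30,
    d: int = 12,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> TwoDomainTask:
    """Two overlapping feature domains.

    The source domain A excites columns ``0..2d/3``; the target domain B
    excites columns ``d/3..d``, so a third of B's directions are absent
    from the base set.  The pool mixes ``n_pool - n_pool_target`` A-like
    candidates with ``n_pool_target`` B-like ones (the informative
    minority a guided strategy should find).
    """
    rng = np.random.default_rng(seed)
    third = d // 3
    active_a = list(range(0, 2 * third))
    active_b = list(range(third, d))
    true_w = rng.standard_normal(d)

    def rows_from(X):
        out = []
        for x in X:
            y = float(x @ true_w) + rng.normal(0.0, noise_sigma)
            out.append(TargetRow(grad_w=x, weight=1.0, kind="energy", value=y))
        return out

    base_rows = rows_from(_domain_features(rng, n_base, d, active_a))
    pool_feats = np.concatenate(
        [
            _domain_features(rng, n_pool - n_pool_target, d, active_a),
            _domain_features(rng, n_pool_target, d, active_b),
        ]
    )
    order = rng.permutation(n_pool)  # hide the informative candidates
    pool_rows = rows_from(pool_feats[order])
    pool = {cid: [row] for cid, row in enumerate(pool_rows)}
    target_feats = _domain_features(rng, n_targets, d, active_b)
    target_queries = [
        QueryVector(g, tag="global", subject_id=f"target{i}")
        for i, g in enumerate(target_feats)
    ]
    test_rows = rows_from(_domain_features(rng, n_test, d, active_b))
    return TwoDomainTask(
        base_rows=base_rows,
        pool=pool,
        target_queries=target_queries,
        test_rows=test_rows,
        true_weights=true_w,
        meta={
            "scenario": "two_domain",
            "seed": seed,
            "noise_sigma": noise_sigma,
            "pool_target_ids": sorted(int(np.flatnonzero(order == i)[0]) for i in range(n_pool - n_pool_target, n_pool)),
        },
    )


def selection_rmse(
    base_rows: Sequence[TargetRow],
    extra_rows: Sequence[TargetRow],
    test_rows: Sequence[TargetRow],
    ridge: float = 1e-6,
) -> float:
    """Refit ridge weights on base + extra rows; RMSE on the test rows."""
    w = fit_ridge(list(base_rows) + list(extra_rows), ridge=ridge)
    errs = [float(r.grad_w @ w.w) - r.value for r in test_rows]
    return float(np.sqrt(np.mean(np.square(errs))))


def gen_body_ordered(
    counts: Mapping[str, int],
    overlap_kappa: float = 0.0,
    block_dim: int = 4,
    noise_sigma: float = 1e-3,
    n_test: int = 20,
    seed: int = 0,
) -> SyntheticSystem:
    """Body-ordered block features with controllable self-interaction.

    Four blocks (``nu1..nu4``) of width ``block_dim``.  A class-``c``
    sample (pair/triple/quad/quint -> c = 1..4) has a shared latent
    geometry vector ``u``; its genuine content in block ``k <= c`` is
    ``R_k u`` for fixed orthogonal maps ``R_k`` (all blocks are
    functions of the same geometry, which is what leaves the energy
    partition degenerate when only high-order clusters are trained on).
    With ``overlap_kappa > 0``, blocks ``k > c`` additionally receive
    self-interaction leakage ``2*kappa * L_k u`` along fixed fresh
    directions ``L_k`` — low-order content counted again in high-order
    blocks.  ``overlap_kappa = 0`` gives strictly block-supported rows
    (the purified analogue).

    Draws are made with per-class child generators, so systems sharing a
    seed share their per-class samples regardless of the other classes'
    counts.  ``n_test`` extra quint structures are appended to the
    feature set (ids in ``meta['test_structures']``) without target rows.
    """
    if not 0.0 <= overlap_kappa <= 1.0:
        raise ValueError("overlap_kappa must lie in [0, 1]")
    unknown = set(counts) - set(BODY_CLASSES)
    if unknown:
        raise ValueError(f"unknown body-order classes: {sorted(unknown)}")
    b = block_dim
    d = 4 * b
    map_rng = np.random.default_rng([seed, 10_000])
    R = [np.linalg.qr(map_rng.standard_normal((b, b)))[0] for _ in range(4)]
    L = [np.linalg.qr(map_rng.standard_normal((b, b)))[0] for _ in range(4)]
    true_w = map_rng.standard_normal(d)
    leak = 2.0 * overlap_kappa

    feats, classes = [], []
    for cls, order in BODY_CLASSES.items():
        n = int(counts.get(cls, 0))
        if n < 0:
            raise ValueError(f"negative count for class {cls!r}")
        crng = np.random.default_rng([seed, order])
        for _ in range(n):
            u = crng.standard_normal(b)
            row = np.zeros(d)
            for k in range(4):
                if k < order:
                    row[k * b : (k + 1) * b] = R[k] @ u
                elif leak > 0.0:
                    row[k * b : (k + 1) * b] = leak * (L[k] @ u)
            feats.append(row)
            classes.append(cls)
    if not feats:
        raise ValueError("no samples requested")
    trng = np.random.default_rng([seed, 5])
    for _ in range(n_test):
        u = trng.standard_normal(b)
        row = np.concatenate([R[k] @ u for k in range(4)])
        feats.append(row)
        classes.append("quint_test")
    feats = np.array(feats)
    n_total = len(feats)
    n_train = n_total - n_test
    fs = FeatureSet(
        env_features=feats,
        structure_of_env=np.arange(n_total),
        blocks={f"nu{k+1}": (k * b, (k + 1) * b) for k in range(4)},
    )
    nrng = np.random.default_rng([seed, 7])
    rows = _energy_rows(fs, range(n_train), true_w, nrng, noise_sigma)
    return SyntheticSystem(
        featureset=fs,
        rows=rows,
        true_weights=true_w,
        seed=seed,
        noise_sigma=noise_sigma,
        meta={
            "scenario": "body_ordered",
            "overlap_kappa": overlap_kappa,
            "class_of_structure": classes,
            "train_structures": list(range(n_train)),
            "test_structures": list(range(n_train, n_total)),
        },
    )


def gen_two_scale(
    n_pairs: int = 100,
    separations: tuple[float, float] = (3.0, 10.0),
    separated: bool = True,
    sr_dim: int = 4,
    lr_dim: int = 4,
    interaction_dim: int = 2,
    noise_sigma: float = 1e-3,
    n_test: int = 20,
    n_monomers: int = 100,
    seed: int = 0,
) -> SyntheticSystem:
    """Short-range/long-range two-block systems of separated dimers.

    Each sample is a dimer of two monomer units with internal
    coordinates ``z1, z2`` and a separation ``r`` drawn from
    ``separations``.  The SR block holds the summed internal descriptor
    ``s = z1 + z2``; the genuine long-range interaction excites a
    ``interaction_dim``-dimensional subspace of the LR block with
    amplitude ``phi(r) = (3 / r)**3`` (a dispersion-like tail,
    referenced to the 3 Å short-range boundary, that vanishes as the
    units separate).  Without range separation
    (``separated=False``) the LR block double counts the short-range
    content through a fixed map ``M``: each unit recounts its own atoms
    (coefficient 0.7) and, in a dimer, its partner's (coefficient 0.3 —
    a reciprocal-space evaluation picks up every atom in the cell
    without real-space attenuation), so dimers carry ``1.0 * M s``
    while an isolated monomer carries only ``0.7 * M z``.  That
    mismatch is what makes the arbitrarily-partitioned model fail to
    transfer to monomers.

    ``meta`` carries a held-out monomer set (``monomer_features``,
    ``monomer_values``): SR block only (plus its own double count when
    not separated), with noiseless true energies for extrapolation
    scoring.
    """
    lo, hi = separations
    if lo <= 0 or hi <= lo:
        raise ValueError("separations must satisfy 0 < lo < hi")
    if not 0 < interaction_dim <= lr_dim:
        raise ValueError("interaction_dim must lie in (0, lr_dim]")
    d = sr_dim + lr_dim
    map_rng = np.random.default_rng([seed, 20_000])
    P = np.linalg.qr(map_rng.standard_normal((lr_dim, interaction_dim)))[0]
    M = map_rng.standard_normal((lr_dim, sr_dim)) / np.sqrt(sr_dim)
    w_sr = map_rng.standard_normal(sr_dim)
    w_int = map_rng.standard_normal(interaction_dim)
    true_w = np.concatenate([w_sr, P @ w_int])
    c_own, c_cross = 0.7, 0.3
    r0 = 3.0  # SR cutoff scale the LR tail is referenced to

    srng = np.random.default_rng([seed, 21])
    n_total = n_pairs + n_test
    feats = np.zeros((n_total, d))
    values = np.zeros(n_total)
    seps = srng.uniform(lo, hi, size=n_total)
    for i in range(n_total):
        z = srng.standard_normal((2, sr_dim))
        s = z.sum(axis=0)
        v = srng.standard_normal(interaction_dim)
        phi = (r0 / seps[i]) ** 3
        lr = phi * (P @ v)
        if not separated:
            lr = lr + (c_own + c_cross) * (M @ s)
        feats[i, :sr_dim] = s
        feats[i, sr_dim:] = lr
        values[i] = float(w_sr @ s) + phi * float(w_int @ v)
    nrng = np.random.default_rng([seed, 22])
    values[:n_pairs] += nrng.normal(0.0, noise_sigma, size=n_pairs) if noise_sigma else 0.0
    fs = FeatureSet(
        env_features=feats,
        structure_of_env=np.arange(n_total),
        blocks={"sr": (0, sr_dim), "lr": (sr_dim, d)},
    )
    rows = [
        TargetRow(grad_w=feats[i], weight=1.0, kind="energy", value=values[i])
        for i in range(n_pairs)
    ]
    mrng = np.random.default_rng([seed, 23])
    zm = mrng.standard_normal((n_monomers, sr_dim))
    mono = np.zeros((n_monomers, d))
    mono[:, :sr_dim] = zm
    if not separated:
        mono[:, sr_dim:] = c_own * (zm @ M.T)
    mono_values = zm @ w_sr
    return SyntheticSystem(
        featureset=fs,
        rows=rows,
        true_weights=true_w,
        seed=seed,
        noise_sigma=noise_sigma,
        meta={
            "scenario": "two_scale",
            "separated": separated,
            "separations": seps,
            "train_structures": list(range(n_pairs)),
            "test_structures": list(range(n_pairs, n_total)),
            "monomer_features": mono,
            "monomer_values": mono_values,
        },
    )


def two_scale_learning_curve(
    n_grid: Sequence[int] = (25, 50, 100, 200, 400),
    separated: bool = True,
    ridge: float = 1e-6,
    seed: int = 0,
    **gen_kwargs,
) -> pd.DataFrame:
    """CPRs and monomer-extrapolation RMSE versus training-set size.

    Training subsets are nested (the first ``n`` dimers of one system),
    so the rigidity trends are free of resampling noise.  CPRs are
    averaged over the held-out test dimers for each block.
    """
    n_grid = sorted(int(n) for n in n_grid)
    system = gen_two_scale(
        n_pairs=n_grid[-1], separated=separated, seed=seed, **gen_kwargs
    )
    fs = system.featureset
    mono = system.meta["monomer_features"]
    mono_values = system.meta["monomer_values"]
    records = []
    for n in n_grid:
        rows = system.rows[:n]
        h = build_hessian(rows, ridge=ridge)
        cpr_sr = np.mean(
            [component_prediction_rigidity(h, fs, sid, "sr") for sid in system.test_structures]
        )
        cpr_lr = np.mean(
            [component_prediction_rigidity(h, fs, sid, "lr") for sid in system.test_structures]
        )
        w = fit_ridge(rows, ridge=ridge)
        rmse = float(np.sqrt(np.mean((mono @ w.w - mono_values) ** 2)))
        records.append({"n": n, "cpr_sr": cpr_sr, "cpr_lr": cpr_lr, "rmse": rmse})
    return pd.DataFrame(records)


def gen_toy_clusters(
    n_structures: int = 10,
    atoms_range: tuple[int, int] = (2, 6),
    box: float = 4.0,
    seed: int = 0,
    species: str = "Si",
) -> list[Structure]:
    """Random non-periodic point clusters in a cubic box (Å-like units)."""
    if n_structures < 1:
        raise ValueError("need at least one structure")
    lo, hi = atoms_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid atoms_range")
    rng = np.random.default_rng(seed)
    structures = []
    for i in range(n_structures):
        n = int(rng.integers(lo, hi + 1))
        pos = rng.uniform(0.0, box, size=(n, 3))
        structures.append(
            Structure(symbols=[species] * n, positions=pos, info={"structure_id": i})
        )
    return structures


def _cutoff(r, rc):
    return np.where(r < rc, 0.5 * (np.cos(np.pi * r / rc) + 1.0), 0.0)


def _cutoff_deriv(r, rc):
    return np.where(r < rc, -0.5 * np.pi / rc * np.sin(np.pi * r / rc), 0.0)


def radial_descriptor(
    structures: "Structure | Sequence[Structure]",
    cutoff: float = 2.8,
    centers: np.ndarray | None = None,
    width: float = 0.4,
    gradients: bool = True,
) -> FeatureSet:
    """Smooth Gaussian radial pair descriptor with analytic gradients.

    Per-atom features ``f_i[k] = sum_{j != i} exp(-(r_ij - c_k)^2 /
    (2 width^2)) * fcut(r_ij)`` with a cosine cutoff at ``cutoff``.
    Translation- and permutation-invariant; an isolated atom has a zero
    row.  Gradients are with respect to the structure's flattened atom
    coordinates (zero-padded to the largest structure).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(structures, Structure):
        structures = [structures]
    if centers is None:
        centers = np.linspace(0.5, cutoff, 6)
    centers = np.asarray(centers, dtype=float)
    d = centers.size
    n_env = sum(len(s) for s in structures)
    max_coords = 3 * max(len(s) for s in structures)
    feats = np.zeros((n_env, d))
    grads = np.zeros((n_env, max_coords, d)) if gradients else None
    struct_of_env = np.zeros(n_env, dtype=np.intp)
    env = 0
    for sid, s in enumerate(structures):
        pos = s.positions
        n = len(s)
        for i in range(n):
            struct_of_env[env + i] = sid
            for j in range(n):
                if j == i:
                    continue
                dvec = pos[i] - pos[j]
                r = float(np.linalg.norm(dvec))
                if r >= cutoff or r == 0.0:
                    continue
                gauss = np.exp(-((r - centers) ** 2) / (2.0 * width**2))
                fc = float(_cutoff(np.array(r), cutoff))
                feats[env + i] += gauss * fc
                if gradients:
                    dfc = float(_cutoff_deriv(np.array(r), cutoff))
                    dh = gauss * (-(r - centers) / width**2) * fc + gauss * dfc
                    direction = dvec / r
                    contrib = np.outer(direction, dh)  # (3, d)
                    grads[env + i, 3 * i : 3 * i + 3, :] += contrib
                    grads[env + i, 3 * j : 3 * j + 3, :] -= contrib
        env += n
    return FeatureSet(
        env_features=feats, structure_of_env=struct_of_env, env_gradients=grads
    )


def committee_variances(
    system: SyntheticSystem,
    n_members: int = 10,
    subsample_fraction: float = 0.1,
    ridge: float = 1e-6,
    seed: int = 0,
    mode: str = "disjoint",
) -> dict[int, float]:
    """Variance of each environment's local prediction across a
    committee of ridge models trained on subsampled structures.

    ``mode='disjoint'`` (default) partitions the training structures
    into ``n_members`` non-overlapping folds of ``subsample_fraction``
    of the data each; ``mode='bootstrap'`` resamples with replacement.
    ``subsample_fraction >= 1`` trains every member on the full set.
    Returns population variance about the committee mean per environment.
    """
    if n_members < 2:
        raise ValueError("need at least two committee members")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    fs = system.featureset
    structures = np.asarray(system.meta["train_structures"])
    rows_by_structure = {int(s): r for s, r in zip(structures, system.rows)}
    n = len(structures)
    rng = np.random.default_rng(seed)
    if subsample_fraction >= 1.0:
        folds = [structures] * n_members
    elif mode == "disjoint":
        size = int(np.floor(n * subsample_fraction))
        if size * n_members > n:
            raise ValueError(
                f"{n_members} disjoint folds of fraction {subsample_fraction} "
                f"do not fit in {n} structures"
            )
        perm = rng.permutation(structures)
        folds = [perm[m * size : (m + 1) * size] for m in range(n_members)]
    elif mode == "bootstrap":
        size = max(int(np.floor(n * subsample_fraction)), 1)
        folds = [rng.choice(structures, size=size, replace=True) for _ in range(n_members)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    preds = np.zeros((n_members, fs.n_env))
    for m, fold in enumerate(folds):
        fold_rows = [rows_by_structure[int(s)] for s in fold]
        fit_ridge_arg = ridge
        if len(fold_rows) < fs.d and ridge == 0.0:
            warnings.warn(
                "subsample smaller than the feature dimension; "
                "falling back to a small ridge for the committee fit"
            )
            fit_ridge_arg = 1e-8
        w = fit_ridge(fold_rows, ridge=fit_ridge_arg)
        preds[m] = fs.env_features @ w.w
    var = preds.var(axis=0)  # population variance about the committee mean
    return {int(e): float(var[e]) for e in range(fs.n_env)}
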