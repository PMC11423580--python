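"""PR/LPR/CPR values, the curvature identity, last-layer equivalence,
variance calibration, normalization, trajectory monitoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predrigid.core import FeatureSet, TargetRow, fit_ridge
from predrigid.hessian import HessianState, build_hessian, rank_one_update
from predrigid.rigidity import (
    QueryVector,
    RigidityReport,
    ZeroQueryError,
    component_prediction_rigidity,
    component_query,
    curvature_probe,
    global_query,
    last_layer_pr,
    local_prediction_rigidity,
    monitor_trajectory,
    normalize_report,
    prediction_rigidity,
    variance_from_pr,
)
from helpers import random_rows


def spd_state(seed, d, ridge=0.5):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d))
    return HessianState(matrix=A @ A.T + ridge * np.eye(d), ridge=ridge), rng


class TestPredictionRigidity:
    def test_identity_hessian_unit_query(self):
        h = HessianState(np.eye(3), ridge=1.0)
        assert prediction_rigidity(h, QueryVector([1.0, 0, 0])) == pytest.approx(1.0)

    def test_diagonal_hessian(self):
        h = HessianState(np.diag([4.0, 1.0]), ridge=1.0)
        assert prediction_rigidity(h, QueryVector([1.0, 0.0])) == pytest.approx(4.0)

    def test_matches_explicit_inverse(self):
        h, rng = spd_state(13, 6)
        g = rng.standard_normal(6)
        expected = 1.0 / (g @ np.linalg.inv(h.matrix) @ g)
        assert prediction_rigidity(h, QueryVector(g)) == pytest.approx(expected, rel=1e-10)

    def test_zero_query_raises(self):
        h = HessianState(np.eye(2), ridge=1.0)
        with pytest.raises(ZeroQueryError):
            prediction_rigidity(h, QueryVector([0.0, 0.0]))


class TestLocalRigidity:
    def test_ridge_only_unit_feature(self):
        fs = FeatureSet(np.array([[1.0, 0.0]]), np.array([0]))
        h = build_hessian([], ridge=1.0, dim=2)
        assert local_prediction_rigidity(h, fs, 0) == pytest.approx(1.0)

    def test_duplicated_environment_is_more_rigid(self):
        rng = np.random.default_rng(21)
        common = rng.standard_normal(4)
        unique = rng.standard_normal(4)
        feats = np.vstack([np.tile(common, (6, 1)), unique])
        fs = FeatureSet(feats, np.arange(7))
        rows = [TargetRow(feats[i], value=0.0) for i in range(7)]
        h = build_hessian(rows, ridge=1e-3)
        assert local_prediction_rigidity(h, fs, 0) > 3 * local_prediction_rigidity(h, fs, 6)

    def test_invariant_under_storage_order(self):
        rng = np.random.default_rng(2)
        feats = rng.standard_normal((5, 3))
        fs = FeatureSet(feats, np.zeros(5, dtype=int))
        h = build_hessian([TargetRow(feats.sum(axis=0))], ridge=0.1)
        perm = rng.permutation(5)
        fs_p = FeatureSet(feats[perm], np.zeros(5, dtype=int))
        for new_pos, old in enumerate(perm):
            assert local_prediction_rigidity(h, fs_p, new_pos) == pytest.approx(
                local_prediction_rigidity(h, fs, old), rel=1e-12
            )

    def test_unknown_env(self):
        fs = FeatureSet(np.eye(2), np.array([0, 1]))
        with pytest.raises(KeyError):
            local_prediction_rigidity(HessianState(np.eye(2), 1.0), fs, 5)


class TestComponentRigidity:
    def test_block_diagonal_reduces_to_block_problem(self):
        rng = np.random.default_rng(5)
        rows_a = [TargetRow(np.r_[rng.standard_normal(2), 0, 0]) for _ in range(5)]
        rows_b = [TargetRow(np.r_[0, 0, rng.standard_normal(2)]) for _ in range(5)]
        ridge = 0.2
        h = build_hessian(rows_a + rows_b, ridge=ridge)
        feats = np.r_[rng.standard_normal(2), rng.standard_normal(2)][None, :]
        fs = FeatureSet(feats, np.array([0]), blocks={"A": (0, 2), "B": (2, 4)})
        cpr = component_prediction_rigidity(h, fs, 0, "A")
        # oracle: PR inside the 2x2 block submatrix alone
        Hblk = h.matrix[:2, :2]
        g = feats[0, :2]
        assert cpr == pytest.approx(1.0 / (g @ np.linalg.inv(Hblk) @ g), rel=1e-10)

    def test_fully_degenerate_partition_has_tiny_cprs(self):
        """Training rows all (1,1): how the total splits between the two
        columns is arbitrary, so both CPRs sit at the ridge floor while
        the global PR grows with the sample count."""
        n, ridge = 50, 1e-6
        rows = [TargetRow([1.0, 1.0]) for _ in range(n)]
        h = build_hessian(rows, ridge=ridge)
        fs = FeatureSet(
            np.array([[1.0, 1.0]]), np.array([0]), blocks={"c0": (0, 1), "c1": (1, 2)}
        )
        # closed-form 2x2 inverse oracle for H = n*ones + ridge*I
        H = n * np.ones((2, 2)) + ridge * np.eye(2)
        Hinv = np.linalg.inv(H)
        for blk, e in (("c0", np.array([1.0, 0.0])), ("c1", np.array([0.0, 1.0]))):
            cpr = component_prediction_rigidity(h, fs, 0, blk)
            assert cpr == pytest.approx(1.0 / (e @ Hinv @ e), rel=1e-9)
            assert cpr < 4 * ridge  # ridge-order small
        g = np.array([1.0, 1.0])
        global_pr = prediction_rigidity(h, global_query(fs, 0))
        # cond(H) ~ n/ridge, so only ~cond*eps digits are meaningful here
        assert global_pr == pytest.approx(1.0 / (g @ Hinv @ g), rel=1e-6)
        assert global_pr > 0.5 * n

    def test_block_exercising_row_resolves_component(self):
        n, ridge = 50, 1e-6
        rows = [TargetRow([1.0, 1.0]) for _ in range(n)]
        fs = FeatureSet(
            np.array([[1.0, 1.0]]), np.array([0]), blocks={"c0": (0, 1), "c1": (1, 2)}
        )
        before = component_prediction_rigidity(build_hessian(rows, ridge), fs, 0, "c1")
        after = component_prediction_rigidity(
            build_hessian(rows + [TargetRow([0.0, 1.0])], ridge), fs, 0, "c1"
        )
        assert after > 1e3 * before

    def test_undeclared_block_raises(self):
        fs = FeatureSet(np.ones((1, 2)), np.array([0]), blocks={"a": (0, 2)})
        with pytest.raises(KeyError, match="not declared"):
            component_query(fs, 0, "zzz")


class TestLastLayer:
    def test_counted_basis_rows(self):
        F = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert last_layer_pr(F, np.array([1.0, 0.0]), 0.0) == pytest.approx(2.0)
        assert last_layer_pr(F, np.array([0.0, 1.0]), 0.0) == pytest.approx(1.0)

    def test_ridge_only(self):
        f = np.array([2.0, 0.0, 0.0])  # |f|^2 = 4
        assert last_layer_pr(np.empty((0, 3)), f, 1.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_generic_hessian_path(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((12, 5))
        f = rng.standard_normal(5)
        ridge = 10.0 ** rng.uniform(-6, 0)
        rows = [TargetRow(row) for row in F]
        generic = prediction_rigidity(build_hessian(rows, ridge), QueryVector(f))
        assert last_layer_pr(F, f, ridge) == pytest.approx(generic, rel=1e-12)


class TestVariance:
    def test_inverse_scaling(self):
        assert variance_from_pr(4.0) == pytest.approx(0.25)
        assert variance_from_pr(4.0, scale=2.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            variance_from_pr(0.0)


class TestCurvatureProbe:
    def make(self, seed=37, n=8, d=3, ridge=0.3):
        rows = random_rows(seed, n, d)
        w = fit_ridge(rows, ridge=ridge)
        return rows, ridge, w

    def test_zero_delta_zero_loss(self):
        rows, ridge, w = self.make()
        probe = curvature_probe(rows, ridge, w, QueryVector(rows[0].grad_w), 0.0)
        assert probe.delta_loss == 0.0

    def test_quadratic_in_delta(self):
        rows, ridge, w = self.make()
        q = QueryVector(rows[0].grad_w)
        l1 = curvature_probe(rows, ridge, w, q, 0.05).delta_loss
        l2 = curvature_probe(rows, ridge, w, q, 0.10).delta_loss
        assert l2 == pytest.approx(4 * l1, rel=1e-7)

    def test_matches_penalty_method_oracle(self):
        rows, ridge, w = self.make()
        rng = np.random.default_rng(8)
        g = rng.standard_normal(3)
        delta = 0.2
        probe = curvature_probe(rows, ridge, w, QueryVector(g), delta)
        # penalty-method constrained minimization
        G = np.stack([r.grad_w for r in rows])
        lam = np.array([r.weight for r in rows])
        y = np.array([r.value for r in rows])
        mu = 1e10
        t = g @ w.w + delta
        A = (G.T * lam) @ G + ridge * np.eye(3) + mu * np.outer(g, g)
        b = G.T @ (lam * y) + mu * t * g
        w_pen = np.linalg.solve(A, b)
        from predrigid.core import loss_value

        oracle = loss_value(rows, ridge, w_pen) - loss_value(rows, ridge, w.w)
        assert probe.delta_loss == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("tag", ["global", "local", "component"])
    def test_loss_increase_equals_rigidity_times_delta_squared(self, tag):
        """The defining identity dL = R * delta^2, for all query types."""
        rng = np.random.default_rng(99)
        feats = rng.standard_normal((6, 4))
        fs = FeatureSet(
            feats, np.array([0, 0, 1, 1, 2, 2]), blocks={"a": (0, 2), "b": (2, 4)}
        )
        rows = [
            TargetRow(fs.global_row(s), value=rng.standard_normal()) for s in range(3)
        ]
        ridge = 0.05
        w = fit_ridge(rows, ridge=ridge)
        h = build_hessian(rows, ridge=ridge)
        queries = {
            "global": global_query(fs, 1),
            "local": QueryVector(feats[3], tag="local", subject_id=3),
            "component": component_query(fs, 2, "b"),
        }
        q = queries[tag]
        delta = 0.07
        probe = curvature_probe(rows, ridge, w, q, delta)
        R = prediction_rigidity(h, q)
        assert probe.delta_loss == pytest.approx(R * delta**2, rel=1e-9)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
def test_scale_invariance_without_ridge(seed, c):
    """Multiplying every feature (training and query) by c leaves PR
    unchanged when there is no ridge."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((8, 4))
    g = rng.standard_normal(4)
    h1 = build_hessian([TargetRow(row) for row in G], ridge=0.0)
    h2 = build_hessian([TargetRow(c * row) for row in G], ridge=0.0)
    r1 = prediction_rigidity(h1, QueryVector(g))
    r2 = prediction_rigidity(h2, QueryVector(c * g))
    assert r2 == pytest.approx(r1, rel=1e-8)


class TestReports:
    def test_max_normalization(self):
        rep = normalize_report(RigidityReport(values={"a": 2.0, "b": 4.0}), "max")
        assert rep.normalized == {"a": 0.5, "b": 1.0}

    def test_reference_normalization(self):
        rep = normalize_report(
            RigidityReport(values={"a": 2.0, "b": 4.0}), "reference", reference=2.0
        )
        assert rep.normalized == {"a": 1.0, "b": 2.0}

    def test_max_mode_idempotent(self):
        rep = normalize_report(RigidityReport(values={"a": 2.0, "b": 4.0}), "max")
        rep2 = normalize_report(
            RigidityReport(values=rep.normalized), "max"
        )
        assert rep2.normalized == rep.normalized

    def test_empty_report_raises(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_report(RigidityReport(values={}), "max")

    def test_round_trip_csv(self, tmp_path):
        import pandas as pd

        rep = normalize_report(RigidityReport(values={1: 2.0, 2: 4.0}, tag="local"), "max")
        rep.to_csv(tmp_path / "r.csv")
        frame = pd.read_csv(tmp_path / "r.csv")
        assert list(frame["subject_id"]) == [1, 2]
        np.testing.assert_allclose(frame["normalized"], [0.5, 1.0])


class TestMonitor:
    def test_constant_frames_constant_series(self):
        h = HessianState(np.diag([4.0, 1.0]), ridge=1.0)
        q = QueryVector([1.0, 0.0])
        out = monitor_trajectory(h, [q] * 5, reference_prs=[2.0, 6.0], window=3)
        np.testing.assert_allclose(out["relative_pr"], 1.0)  # PR=4, mean ref=4
        np.testing.assert_allclose(out["moving_average"], 1.0)

    def test_window_one_is_raw_series(self):
        h, rng = spd_state(44, 4)
        frames = [QueryVector(rng.standard_normal(4)) for _ in range(6)]
        out = monitor_trajectory(h, frames, reference_prs=[1.0], window=1)
        np.testing.assert_allclose(out["moving_average"], out["relative_pr"])

    def test_out_of_span_frame_flags_low_relative_pr(self):
        rng = np.random.default_rng(55)
        rows = [TargetRow(np.r_[rng.standard_normal(3), 0.0]) for _ in range(10)]
        h = build_hessian(rows, ridge=1e-8)
        ref = [prediction_rigidity(h, QueryVector(r.grad_w)) for r in rows[:3]]
        stray = QueryVector(np.array([0.0, 0.0, 0.0, 1.0]))  # outside training span
        out = monitor_trajectory(h, [stray], ref, window=1)
        assert out["relative_pr"].iloc[0] < 1e-3

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError, match="empty"):
            monitor_trajectory(HessianState(np.eye(2), 1.0), [], [1.0], 1)
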