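"""Kalman filter, Hungarian assignment, merge resolution and lifecycle."""

import itertools
import math

import numpy as np
import pytest

import flytrack as ft
from flytrack.config import PipelineConfig
from flytrack.detection import Component, ValidationContext
from flytrack.tracking import _IdCounter, lifecycle_step


def tracker(id=0, state=(0, 0, 0, 0, 0, 0), p=None, **kw):
    P = np.diag([1.0, 1.0, 1.0, 1.0, 0.1, 0.1]) if p is None else p
    return ft.TrackerState(id=id, x_state=np.array(state, float), P=P, **kw)


def det_at(x, y, theta=0.0, a=6.0, b=3.0):
    return ft.EllipseDetection(x=x, y=y, theta=theta, a=a, b=b)


class TestKalman:
    def test_zero_velocity_prediction_keeps_position(self):
        # with no velocity uncertainty the transition is the identity on P too
        t = tracker(state=(5, 7, 0, 0, 1.0, 0),
                    p=np.diag([1.0, 1.0, 0.0, 0.0, 0.1, 0.0]))
        Q = np.eye(6) * 0.1
        out = ft.kalman_predict(t, 1.0, Q)
        assert np.allclose(out.x_state, t.x_state)
        assert np.allclose(out.P, t.P + Q)

    def test_unit_velocity_moves_position(self):
        out = ft.kalman_predict(tracker(state=(0, 0, 1, 0, 0, 0)))
        assert np.isclose(out.x_state[0], 1.0) and np.isclose(out.x_state[1], 0.0)

    def test_angle_wraps_into_pi_interval(self):
        out = ft.kalman_predict(tracker(state=(0, 0, 0, 0, 3.0, 0.3)))
        assert np.isclose(out.x_state[4], 3.3 - 2 * math.pi)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            ft.kalman_predict(tracker(), 0.0)

    def test_zero_innovation_keeps_state_and_shrinks_P(self):
        t = tracker(state=(3, 4, 1, 0, 0.5, 0))
        out = ft.kalman_update(t, t.x_state.copy(), np.eye(6) * 0.25)
        assert np.allclose(out.x_state, t.x_state)
        assert np.trace(out.P) < np.trace(t.P)

    def test_inflated_R_pins_posterior_to_prediction(self):
        t = tracker(state=(100, 100, 1, 1, 0, 0))
        z = t.x_state + np.array([2, 2, 0.5, 0.5, 0.1, 0.1])
        out = ft.kalman_update(t, z, np.eye(6) * 0.25 * 100)
        assert np.all(np.abs(out.x_state[:2] - t.x_state[:2])
                      <= 0.01 * np.abs(t.x_state[:2]))

    def test_non_pd_R_rejected(self):
        with pytest.raises(ValueError):
            ft.kalman_update(tracker(), np.zeros(6), -np.eye(6))

    def test_covariance_stays_symmetric_psd_through_cycles(self, rng):
        t = tracker()
        Q = np.diag([0.25, 0.25, 1, 1, 0.01, 0.01])
        R = np.diag([0.25, 0.25, 1, 1, 0.01, 0.04])
        for _ in range(50):
            t = ft.kalman_predict(t, 1.0, Q)
            z = t.x_state + rng.normal(0, 0.5, 6)
            t = ft.kalman_update(t, z, R)
            assert np.allclose(t.P, t.P.T)
            assert np.linalg.eigvalsh(t.P).min() > -1e-9

    def test_noiseless_constant_velocity_prediction_converges(self):
        t = tracker(p=np.diag([1.0, 1.0, 25.0, 25.0, 1.0, 1.0]))
        Q = np.diag([0.25, 0.25, 1, 1, 0.01, 0.01])
        R = np.diag([0.25, 0.25, 1, 1, 0.01, 0.04])
        hist, errs = [], []
        for k in range(50):
            x, y = 1.5 * k, 0.7 * k
            t = ft.kalman_predict(t, 1.0, Q)
            errs.append(math.hypot(t.x_state[0] - x, t.x_state[1] - y))
            hist.append([x, y, 0.0])
            v = ft.smooth_velocity(np.array(hist), 5)
            t = ft.kalman_update(t, np.array([x, y, v[0], v[1], 0, v[2]]), R)
        assert max(errs[-10:]) < 0.1

    def test_filter_beats_raw_measurements_under_noise(self, rng):
        # constant-velocity truth + measurement noise: corrected trajectory
        # RMSE must not exceed the raw measured RMSE
        t = tracker(p=np.diag([1.0, 1.0, 25.0, 25.0, 1.0, 1.0]))
        Q = np.diag([0.05, 0.05, 0.1, 0.1, 0.01, 0.01])
        R = np.diag([1.0, 1.0, 1, 1, 0.01, 0.04])
        hist = []
        err_f, err_m = [], []
        for k in range(200):
            x, y = 1.2 * k, -0.4 * k
            zx, zy = x + rng.normal(0, 1.0), y + rng.normal(0, 1.0)
            t = ft.kalman_predict(t, 1.0, Q)
            hist.append([zx, zy, 0.0])
            v = ft.smooth_velocity(np.array(hist), 5)
            t = ft.kalman_update(t, np.array([zx, zy, v[0], v[1], 0, v[2]]), R)
            if k > 20:
                err_f.append((t.x_state[0] - x) ** 2 + (t.x_state[1] - y) ** 2)
                err_m.append((zx - x) ** 2 + (zy - y) ** 2)
        assert np.mean(err_f) <= np.mean(err_m)


class TestSmoothVelocity:
    def test_constant_velocity_is_exact(self):
        h = np.array([[i * 2.0, i * -1.0, 0.0] for i in range(6)])
        assert np.allclose(ft.smooth_velocity(h, 5), [2.0, -1.0, 0.0])

    def test_outlier_pulled_toward_median_of_differences(self):
        xs = [0, 1, 2, 3, 4, 15]  # last difference is an outlier jump of 11
        h = np.array([[x, 0.0, 0.0] for x in xs])
        v = ft.smooth_velocity(h, 5)[0]
        assert abs(v - 1.0) < abs(11.0 - 1.0)

    def test_window_one_is_raw_difference(self):
        h = np.array([[0, 0, 0], [3.0, 1.0, 0.2]])
        assert np.allclose(ft.smooth_velocity(h, 1), [3.0, 1.0, 0.2])

    def test_single_entry_gives_zero(self):
        assert np.allclose(ft.smooth_velocity(np.array([[5.0, 5.0, 0.0]]), 5), 0.0)


class TestAssignmentCost:
    def test_zero_offset_gives_density_peak(self):
        assert np.isclose(
            ft.assignment_cost((0, 0, 2.0, 3.0), (0, 0)), 1 / (2 * math.pi * 6.0)
        )

    def test_unit_offset_hand_value(self):
        v = ft.assignment_cost((0, 0, 1.0, 1.0), (1, 0))
        assert np.isclose(v, math.exp(-0.5) / (2 * math.pi))

    def test_monotone_decrease_with_offset(self):
        vals = [ft.assignment_cost((0, 0, 1, 1), (x, 0)) for x in (0, 0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            ft.assignment_cost((0, 0, 0.0, 1.0), (0, 0))


class TestAssignIdentities:
    def test_single_pair_within_gate(self):
        res = ft.assign_identities([tracker(id=3, state=(10, 10, 0, 0, 0, 0))],
                                   [det_at(11, 10)])
        assert res.pairs == {3: 0}
        assert not res.merged_groups and not res.unassigned_detections

    def test_far_detection_spawns_nothing(self):
        res = ft.assign_identities([tracker(id=0)], [det_at(500, 500)])
        assert res.pairs == {}
        assert res.unassigned_trackers == [0]
        assert res.unassigned_detections == [0]

    def test_two_trackers_one_detection_form_merged_group(self):
        trks = [tracker(id=0, state=(10, 10, 0, 0, 0, 0)),
                tracker(id=1, state=(13, 10, 0, 0, 0, 0))]
        res = ft.assign_identities(trks, [det_at(11.5, 10)])
        assert res.merged_groups == {0: {0, 1}}
        assert res.pairs == {}

    def test_hungarian_equals_brute_force_product(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 7))
            S = rng.uniform(0.01, 1.0, (n, n))
            tot = np.prod([S[i, j] for i, j in ft.solve_assignment(S)])
            best = max(
                np.prod([S[i, p[i]] for i in range(n)])
                for p in itertools.permutations(range(n))
            )
            assert np.isclose(tot, best)

    def test_categories_are_exclusive_and_exhaustive(self, rng):
        trks = [tracker(id=i, state=(rng.uniform(0, 50), rng.uniform(0, 50),
                                     0, 0, 0, 0)) for i in range(5)]
        dets = [det_at(rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(4)]
        res = ft.assign_identities(trks, dets)
        cats = (set(res.pairs) | set(res.unassigned_trackers)
                | set().union(*res.merged_groups.values()) if res.merged_groups
                else set(res.pairs) | set(res.unassigned_trackers))
        assert cats == {t.id for t in trks}
        in_pairs = set(res.pairs.values())
        assert not (in_pairs & set(res.merged_groups))


class TestResolveMerge:
    def make_ctx(self, sep):
        yy, xx = np.mgrid[0:60, 0:60]

        def depth(cx):
            return 120 * np.exp(-0.5 * (((xx - cx) / 3.0) ** 2 + ((yy - 30) / 1.5) ** 2))

        d = depth(30 - sep / 2) + depth(30 + sep / 2)
        mask = d > 10
        rows, cols = np.nonzero(mask)
        comp = Component(rows=rows, cols=cols, values=d[rows, cols])
        ctx = ValidationContext(diff=d, sigma=np.ones_like(d), n_sigma=10.0)
        e = ctx.fit(comp)
        return ctx, e

    def test_split_succeeds_and_reassigns_by_score(self):
        ctx, e = self.make_ctx(sep=9.0)
        cfg = PipelineConfig()
        trks = {0: tracker(id=0, state=(25.5, 30, 0, 0, 0, 0)),
                1: tracker(id=1, state=(34.5, 30, 0, 0, 0, 0))}
        model = ft.AreaModel(mu_areas=e.area / 2, sigma_areas=0.15 * e.area / 2)
        out = ft.resolve_merge({0, 1}, e, ctx, trks, model, cfg)
        assert out[0][0] == "measured" and out[1][0] == "measured"
        assert out[0][1].x < 30 < out[1][1].x

    def test_unsplittable_moving_cluster_coasts(self):
        ctx, e = self.make_ctx(sep=0.5)  # fully overlapped: no split
        cfg = PipelineConfig()
        trks = {0: tracker(id=0, state=(29, 30, 2, 0, 0, 0)),
                1: tracker(id=1, state=(31, 30, -2, 0, 0, 0))}
        model = ft.AreaModel(mu_areas=e.area, sigma_areas=0.15 * e.area)
        out = ft.resolve_merge({0, 1}, e, ctx, trks, model, cfg)
        assert {v[0] for v in out.values()} == {"coast"}

    def test_static_cluster_waits(self):
        ctx, e = self.make_ctx(sep=0.5)
        cfg = PipelineConfig()
        trks = {0: tracker(id=0, state=(29, 30, 0, 0, 0, 0)),
                1: tracker(id=1, state=(31, 30, 0, 0, 0, 0))}
        out = ft.resolve_merge({0, 1}, e, ctx, trks,
                               ft.AreaModel(mu_areas=e.area, sigma_areas=10.0), cfg)
        assert {v[0] for v in out.values()} == {"waiting"}


class TestLifecycle:
    def test_unassigned_detection_spawns_tracker(self):
        cfg = PipelineConfig()
        res = ft.AssignmentResult(unassigned_detections=[0])
        out = lifecycle_step([], res, [det_at(5, 5)], 0, cfg, _IdCounter())
        assert len(out) == 1 and out[0].id == 0

    def test_provisional_loss_retires_immediately(self):
        cfg = PipelineConfig()
        t = tracker(id=0, age_frames=10)
        res = ft.AssignmentResult(unassigned_trackers=[0])
        out = lifecycle_step([t], res, [], 5, cfg, _IdCounter())
        assert out == []

    def test_mature_tracker_coasts_then_waits_then_retires(self):
        cfg = PipelineConfig(probation=5, max_coast=3, max_wait=4)
        t = tracker(id=0, age_frames=100, last_known_position=(7.0, 8.0))
        statuses = []
        for k in range(10):
            t.frames_since_seen = k + 1
            res = ft.AssignmentResult(unassigned_trackers=[0])
            kept = lifecycle_step([t], res, [], k, cfg, _IdCounter())
            statuses.append(kept[0].status if kept else "retired")
        assert statuses[:3] == ["coasting"] * 3
        assert "waiting" in statuses
        assert statuses[-1] == "retired"

    def test_ids_never_reused(self):
        cfg = PipelineConfig()
        ids = _IdCounter()
        res1 = ft.AssignmentResult(unassigned_detections=[0])
        out = lifecycle_step([], res1, [det_at(1, 1)], 0, cfg, ids)
        res2 = ft.AssignmentResult(unassigned_trackers=[0])
        out = lifecycle_step(out, res2, [], 1, cfg, ids)  # retired (provisional)
        res3 = ft.AssignmentResult(unassigned_detections=[0])
        out = lifecycle_step(out, res3, [det_at(1, 1)], 2, cfg, ids)
        assert out[0].id == 1


class TestTrackSequence:
    def test_zero_flies_yields_empty_table(self):
        scene = ft.SceneConfig(width=200, height=200, plate_radius=80,
                               n_flies=0, seed=2)
        frames = ft.render_sequence(ft.simulate_trajectories(scene, 30), scene)
        cfg = PipelineConfig(plate=(99.5, 99.5, 80.0), warmup_frames=20)
        results, table = ft.track_sequence(frames, cfg)
        assert len(table) == 0
        assert list(table.columns) == ft.tracking.TRAJECTORY_COLUMNS

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ft.track_sequence([], PipelineConfig())

    def test_single_fly_single_persistent_tracker(self):
        scene = ft.SceneConfig(width=200, height=200, plate_radius=80,
                               n_flies=1, seed=4)
        truth = ft.simulate_trajectories(scene, 150)
        frames = ft.render_sequence(truth, scene)
        cfg = PipelineConfig(plate=(99.5, 99.5, 80.0))
        results, table = ft.track_sequence(frames, cfg)
        assert table.track_id.nunique() == 1
        assert len(table) == 150
        score = ft.score_against_truth(table, truth.to_dataframe())
        assert tuple(score) == (0, 0, 0)

    def test_angle_continuity_no_pi_jumps(self):
        scene = ft.SceneConfig(width=200, height=200, plate_radius=80,
                               n_flies=1, seed=4)
        frames = ft.render_sequence(ft.simulate_trajectories(scene, 120), scene)
        _, table = ft.track_sequence(frames, PipelineConfig(plate=(99.5, 99.5, 80.0)))
        th = table.sort_values("frame").theta_rad.to_numpy()
        jumps = np.abs(np.diff(np.unwrap(th)))
        assert np.all(jumps <= math.pi)

    def test_determinism_same_input_same_table(self):
        scene = ft.SceneConfig(width=200, height=200, plate_radius=80,
                               n_flies=2, seed=6)
        frames = ft.render_sequence(ft.simulate_trajectories(scene, 80), scene)
        cfg = PipelineConfig(plate=(99.5, 99.5, 80.0), warmup_frames=40)
        _, t1 = ft.track_sequence(frames, cfg)
        _, t2 = ft.track_sequence(frames, cfg)
        assert t1.equals(t2)
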