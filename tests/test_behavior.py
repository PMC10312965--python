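"""Behavioural derivations: visits, strategy, zones, angles, velocity."""

import numpy as np
import pytest

from mesostate import MazeGeometry
from mesostate.behavior import (StrategyClassifier, Trajectory, assign_zone,
                                classify_strategy, detect_hole_visits,
                                heading_angles, primary_metrics, velocity,
                                ZONE_APPROACH, ZONE_CENTRAL, ZONE_SERIAL)
from mesostate.synthetic import simulate_trajectory


def _traj_from_nose(nose, fps=15.0):
    nose = np.asarray(nose, dtype=float)
    return Trajectory(t=np.arange(len(nose)) / fps, nose=nose,
                      head=nose - [10, 0], body=nose - [20, 0])


def _dwell_path(points_with_dwell):
    out = []
    for p, n in points_with_dwell:
        out.extend([p] * n)
    return out


class TestHoleVisits:
    def test_visit_order_preserved(self, geom):
        h = geom.hole_centers
        nose = _dwell_path([(geom.center, 4), (h[5], 4), (geom.center, 4),
                            (h[7], 4), (geom.center, 4),
                            (h[geom.goal_index], 4)])
        visits = detect_hole_visits(_traj_from_nose(nose), geom)
        assert [v.hole for v in visits] == [5, 7, geom.goal_index]

    def test_no_disc_contact_no_visits(self, geom):
        nose = [geom.center] * 30
        assert detect_hole_visits(_traj_from_nose(nose), geom) == []

    def test_single_frame_jitter_rejected(self, geom):
        h5 = geom.hole_centers[5]
        outside = h5 + [geom.hole_radius + 5, 0]
        nose = _dwell_path([(h5, 1), (outside, 1)] * 8)
        assert detect_hole_visits(_traj_from_nose(nose), geom) == []

    def test_brief_exits_merged_into_one_visit(self, geom):
        h5 = geom.hole_centers[5]
        outside = h5 + [geom.hole_radius + 5, 0]
        nose = _dwell_path([(h5, 4), (outside, 3), (h5, 4)])  # gap 0.2 s
        visits = detect_hole_visits(_traj_from_nose(nose), geom)
        assert len(visits) == 1 and visits[0].hole == 5


class TestStrategyRules:
    def test_direct_goal_path_is_spatial(self, geom):
        g = geom.goal_index
        nose = _dwell_path([(geom.center, 10), (geom.hole_centers[g], 5)])
        traj = _traj_from_nose(nose)
        visits = detect_hole_visits(traj, geom)
        strat, matched, reached = classify_strategy(visits, traj, geom)
        assert (strat, matched, reached) == ("spatial", True, True)

    def test_three_sequential_holes_before_goal_is_serial(self, geom):
        g = geom.goal_index
        h = geom.hole_centers
        seq = [(h[(g - 3) % 20], 4), (h[(g - 2) % 20], 4),
               (h[(g - 1) % 20], 4), (h[g], 4)]
        traj = _traj_from_nose(_dwell_path([(geom.center, 8)] + seq))
        visits = detect_hole_visits(traj, geom)
        assert classify_strategy(visits, traj, geom)[0] == "serial"

    def test_nonsequential_quadrants_is_random(self, geom):
        g = geom.goal_index
        h = geom.hole_centers
        # holes in goal-anchored sectors 1, 3, 2 then the goal (sector 0)
        seq = [(h[(g + 5) % 20], 4), (h[(g + 15) % 20], 4),
               (h[(g + 10) % 20], 4), (h[g], 4)]
        traj = _traj_from_nose(_dwell_path([(geom.center, 8)] + seq))
        visits = detect_hole_visits(traj, geom)
        strat, matched, _ = classify_strategy(visits, traj, geom)
        assert (strat, matched) == ("random", True)

    def test_no_goal_visit_flagged(self, geom):
        nose = _dwell_path([(geom.center, 10), (geom.hole_centers[5], 5)])
        traj = _traj_from_nose(nose)
        visits = detect_hole_visits(traj, geom)
        strat, _matched, reached = classify_strategy(visits, traj, geom)
        assert not reached

    @pytest.mark.parametrize("strategy", ["spatial", "serial"])
    def test_archetypal_generators_classified_perfectly(self, geom, strategy):
        clf = StrategyClassifier()
        trajs = [simulate_trajectory(strategy, geom, s, n_frames=900)
                 for s in range(10)]
        assert np.all(clf.predict(trajs, geom) == strategy)

    def test_random_generator_classified_random(self, geom):
        clf = StrategyClassifier()
        trajs = [simulate_trajectory("random", geom, 1000 + s, n_frames=900)
                 for s in range(30)]
        pred = clf.predict(trajs, geom)
        assert np.mean(pred == "random") >= 0.95


class TestZones:
    def test_boundaries(self, geom):
        c = np.asarray(geom.center)
        pts = np.stack([c, c + [geom.radius - 10, 0], c + [geom.radius / 2, 0]])
        traj = Trajectory(t=np.arange(3) / 15.0, nose=pts, head=pts + [10, 0],
                          body=pts)
        zone = assign_zone(traj, geom)
        assert list(zone) == [ZONE_CENTRAL, ZONE_SERIAL, ZONE_APPROACH]

    def test_zones_partition_the_maze(self, geom, rng):
        r = np.sqrt(rng.uniform(0, 1, 200)) * geom.radius
        th = rng.uniform(0, 2 * np.pi, 200)
        pts = np.asarray(geom.center) + np.stack([r * np.cos(th),
                                                  r * np.sin(th)], axis=1)
        traj = Trajectory(t=np.arange(200) / 15.0, nose=pts, head=pts + [5, 0],
                          body=pts)
        zone = assign_zone(traj, geom)
        assert set(zone) <= {ZONE_CENTRAL, ZONE_APPROACH, ZONE_SERIAL}


class TestHeadingAngles:
    def test_aligned_perpendicular_collinear(self, geom):
        c = np.asarray(geom.center)
        g = geom.goal_center
        u = (g - c) / np.linalg.norm(g - c)
        perp = np.array([-u[1], u[0]])
        mid = c + 0.5 * (g - c)
        body = np.stack([c, c, mid])
        head = np.stack([c + 30 * u, c + 30 * perp, mid + 30 * u])
        traj = Trajectory(t=np.arange(3) / 15.0, nose=head + 10 * u,
                          head=head, body=body)
        om, ph = heading_angles(traj, geom)
        assert abs(om[0]) < 1e-9 and abs(ph[0]) < 1e-9
        assert abs(abs(om[1]) - 90.0) < 1e-9
        assert abs(om[2]) < 1e-9 and abs(ph[2]) < 1e-9

    def test_global_rotation_invariance(self, geom, rng):
        traj = simulate_trajectory("serial", geom, 3, n_frames=450)
        om0, ph0 = heading_angles(traj, geom)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(geom.center)
        rot = lambda p: (p - c) @ R.T + c
        geom_r = MazeGeometry(center=geom.center, radius=geom.radius,
                              hole_centers=rot(geom.hole_centers),
                              hole_radius=geom.hole_radius,
                              goal_index=geom.goal_index,
                              px_per_cm=geom.px_per_cm,
                              mouse_length=geom.mouse_length)
        traj_r = Trajectory(t=traj.t, nose=rot(traj.nose), head=rot(traj.head),
                            body=rot(traj.body))
        om1, ph1 = heading_angles(traj_r, geom_r)
        assert np.allclose(om0, om1, atol=1e-9)
        assert np.allclose(ph0, ph1, atol=1e-9)

    def test_degenerate_body_head_gives_nan(self, geom):
        c = np.tile(np.asarray(geom.center), (3, 1))
        traj = Trajectory(t=np.arange(3) / 15.0, nose=c + [30, 0],
                          head=c, body=c)
        om, ph = heading_angles(traj, geom)
        assert np.all(np.isnan(om)) and np.all(np.isnan(ph))


class TestVelocity:
    def test_stationary_zero(self, geom):
        pts = np.tile(np.asarray(geom.center), (30, 1))
        traj = Trajectory(t=np.arange(30) / 15.0, nose=pts + [30, 0],
                          head=pts + [15, 0], body=pts)
        assert np.allclose(velocity(traj, geom), 0.0)

    def test_uniform_linear_motion(self, geom):
        # 10 px/frame at 15 FPS with 6 px/cm -> 25 cm/s
        pts = np.asarray(geom.center) + np.outer(np.arange(40) * 10.0, [1, 0])
        traj = Trajectory(t=np.arange(40) / 15.0, nose=pts + [30, 0],
                          head=pts + [15, 0], body=pts)
        v = velocity(traj, geom)
        assert np.allclose(v[5:-5], 25.0, atol=1e-9)

    def test_circular_motion_constant_speed(self, geom):
        r, w = 150.0, 0.8  # rad/s
        t = np.arange(300) / 15.0
        pts = np.asarray(geom.center) + r * np.stack(
            [np.cos(w * t), np.sin(w * t)], axis=1)
        traj = Trajectory(t=t, nose=pts + [30, 0], head=pts + [15, 0], body=pts)
        v = velocity(traj, geom)
        expect = r * w / geom.px_per_cm
        assert np.allclose(v[10:-10], expect, rtol=0.02)


class TestPrimaryMetrics:
    def test_errors_and_latency(self, geom):
        g = geom.goal_index
        h = geom.hole_centers
        nose = _dwell_path([(geom.center, 10), (h[5], 4), (geom.center, 4),
                            (h[7], 4), (geom.center, 4), (h[g], 4)])
        traj = _traj_from_nose(nose)
        visits = detect_hole_visits(traj, geom)
        latency, errors, reached = primary_metrics(visits, traj, g)
        assert errors == 2 and reached
        assert latency == pytest.approx(visits[-1].start_frame / 15.0)

    def test_direct_goal_zero_errors(self, geom):
        g = geom.goal_index
        nose = _dwell_path([(geom.center, 45), (geom.hole_centers[g], 4)])
        traj = _traj_from_nose(nose)
        visits = detect_hole_visits(traj, geom)
        latency, errors, _ = primary_metrics(visits, traj, g)
        assert errors == 0 and latency == pytest.approx(3.0)

    def test_repeat_visits_count_separately(self, geom):
        g = geom.goal_index
        h5 = geom.hole_centers[5]
        nose = _dwell_path([(geom.center, 8), (h5, 4), (geom.center, 12),
                            (h5, 4), (geom.center, 12),
                            (geom.hole_centers[g], 4)])
        traj = _traj_from_nose(nose)
        visits = detect_hole_visits(traj, geom)
        _, errors, _ = primary_metrics(visits, traj, g)
        assert errors == 2

    def test_no_goal_latency_is_trial_duration(self, geom):
        nose = _dwell_path([(geom.center, 60)])
        traj = _traj_from_nose(nose)
        latency, _, reached = primary_metrics([], traj, geom.goal_index)
        assert not reached
        assert latency == pytest.approx(traj.t[-1])


class TestDlcRoundtrip:
    def test_csv_roundtrip_and_likelihood_threshold(self, geom, tmp_path):
        from mesostate.io import read_dlc_csv, write_dlc_csv

        traj = simulate_trajectory("spatial", geom, 0, n_frames=300)
        traj.likelihood[10, 1] = 0.2     # one bad head point
        path = tmp_path / "track.csv"
        write_dlc_csv(path, traj)
        # header follows the DeepLabCut dialect
        lines = path.read_text().splitlines()
        assert lines[0].split(",")[:2] == ["scorer", "mesostate-synthetic"]
        assert lines[1].split(",")[:4] == ["bodyparts", "nose", "nose", "nose"]
        assert lines[2].split(",")[:4] == ["coords", "x", "y", "likelihood"]
        back = read_dlc_csv(path)
        assert np.allclose(back.nose, traj.nose, atol=1e-6)
        assert not back.valid[10]
        assert back.valid.sum() == 299
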