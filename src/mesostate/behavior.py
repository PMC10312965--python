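"""Trial-level behaviour from pose tracking on the Barnes maze.

From nose/head/body tracking aligned to the 15 FPS calcium frames we
derive: hole-visit sequences, the search-strategy class (random, serial
or spatial), primary latency and primary errors, radial zone occupancy,
instantaneous velocity, and the allocentric (omega) and egocentric (phi)
heading angles relative to the goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import MazeGeometry, N_HOLES

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "serial", "spatial")

ZONE_CENTRAL = "central"
ZONE_APPROACH = "approach"
ZONE_SERIAL = "serial_exploration"
ZONE_INVALID = "invalid"


@dataclass
class Trajectory:
    """Nose/head/body tracking for one trial, 1:1 with calcium frames."""

    t: np.ndarray                       # seconds
    nose: np.ndarray                    # (T, 2) px
    head: np.ndarray
    body: np.ndarray
    likelihood: np.ndarray | None = None  # (T, 3) per-part confidence
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("nose", "head", "body"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class HoleVisit:
    hole: int
    start_frame: int
    end_frame: int          # inclusive


@dataclass
class TrialBehavior:
    """All per-trial behavioural quantities."""

    strategy: str
    strategy_rule_matched: bool         # False when the random fallback fired
    hole_visits: list[HoleVisit]
    primary_latency_s: float
    primary_errors: int
    reached_goal: bool
    velocity: np.ndarray                # cm/s per frame
    omega: np.ndarray                   # degrees, NaN where undefined
    phi: np.ndarray
    zone: np.ndarray                    # per-frame zone label (object array)


# ---------------------------------------------------------------------------
# hole visits
# ---------------------------------------------------------------------------

def detect_hole_visits(
    traj: Trajectory,
    geom: MazeGeometry,
    min_frames: int = 2,
    merge_gap_s: float = 0.5,
) -> list[HoleVisit]:
    """Ordered hole-visit events from the nose trace.

    A visit opens when the nose stays inside a hole disc for at least
    ``min_frames`` consecutive frames and closes on exit; consecutive
    visits to the same hole separated by less than ``merge_gap_s`` are
    merged (boundary jitter).
    """
    d = np.linalg.norm(traj.nose[:, None, :] - geom.hole_centers[None, :, :], axis=2)
    inside = (d < geom.hole_radius) & traj.valid[:, None]
    multi = inside.sum(axis=1) > 1
    if multi.any():
        raise ValueError(
            f"nose inside two hole discs at frame {int(np.flatnonzero(multi)[0])}: "
            "hole geometry invalid")
    hole = np.where(inside.any(axis=1), np.argmax(inside, axis=1), -1)

    visits: list[HoleVisit] = []
    i = 0
    T = hole.size
    while i < T:
        if hole[i] < 0:
            i += 1
            continue
        j = i
        while j + 1 < T and hole[j + 1] == hole[i]:
            j += 1
        if j - i + 1 >= min_frames:
            visits.append(HoleVisit(hole=int(hole[i]), start_frame=i, end_frame=j))
        i = j + 1

    fps = traj.fps
    merged: list[HoleVisit] = []
    for v in visits:
        if (merged and merged[-1].hole == v.hole
                and (v.start_frame - merged[-1].end_frame) / fps < merge_gap_s):
            merged[-1] = HoleVisit(v.hole, merged[-1].start_frame, v.end_frame)
        else:
            merged.append(v)
    return merged


# ---------------------------------------------------------------------------
# strategy classification
# ---------------------------------------------------------------------------

def _sector_runs(traj: Trajectory, geom: MazeGeometry, upto: int) -> np.ndarray:
    """Run-length-compressed goal-anchored sector sequence (outside centre)."""
    body = traj.body[:upto]
    ok = traj.valid[:upto].copy()
    r = np.linalg.norm(body - np.asarray(geom.center), axis=1)
    ok &= r >= geom.mouse_length / 2.0     # central circle has no sector
    sec = geom.sector_of(body)[ok]
    if sec.size == 0:
        return sec
    keep = np.concatenate(([True], np.diff(sec) != 0))
    return sec[keep]


def _adjacent(a: int, b: int) -> bool:
    return (a - b) % 4 in (1, 3)


def classify_strategy(
    visits: list[HoleVisit],
    traj: Trajectory,
    geom: MazeGeometry,
) -> tuple[str, bool, bool]:
    """Search-strategy class of the trial's primary phase.

    The primary phase runs until the first goal visit (the whole trial,
    flagged, when the goal is never found). Rules, most specific first:

    * spatial — at most one 90-degree sector traversed, and every
      pre-goal hole visited lies immediately adjacent to the goal (no
      more than one sequential hole on either side);
    * serial — at most two sectors traversed with every sector change
      between angularly adjacent sectors, and at least three consecutive
      holes covered on one side of the goal;
    * random — three or more sectors crossed non-sequentially (some
      sector change skips a sector);
    * anything else falls back to random.

    Returns (strategy, explicit_rule_matched, reached_goal).
    """
    g = geom.goal_index
    goal_pos = [i for i, v in enumerate(visits) if v.hole == g]
    reached = bool(goal_pos)
    upto = visits[goal_pos[0]].start_frame if reached else traj.n_frames
    if not reached:
        logger.info("no goal visit: classifying on full trajectory")
    pre = visits[: goal_pos[0]] if reached else visits
    holes = {v.hole for v in pre}

    runs = _sector_runs(traj, geom, upto)
    distinct = np.unique(runs).size if runs.size else 0
    transitions_adjacent = all(_adjacent(int(a), int(b))
                               for a, b in zip(runs[:-1], runs[1:]))

    adj = {(g - 1) % N_HOLES, (g + 1) % N_HOLES}
    if distinct <= 1 and holes <= adj:
        return "spatial", True, reached
    for side in (1, -1):
        run3 = {(g + side * k) % N_HOLES for k in (1, 2, 3)}
        if distinct <= 2 and transitions_adjacent and run3 <= holes:
            return "serial", True, reached
    if distinct >= 3 and not transitions_adjacent:
        return "random", True, reached
    return "random", False, reached


class StrategyClassifier:
    """Rule-based search-strategy classifier (scikit-learn style).

    A pure function of the hole-visit sequence and the goal-anchored
    sector sequence; ``predict`` maps trajectories to strategy labels.
    """

    def __init__(self, min_visit_frames: int = 2, merge_gap_s: float = 0.5) -> None:
        self.min_visit_frames = min_visit_frames
        self.merge_gap_s = merge_gap_s

    def get_params(self, deep: bool = True) -> dict:
        return {"min_visit_frames": self.min_visit_frames,
                "merge_gap_s": self.merge_gap_s}

    def set_params(self, **params) -> "StrategyClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "StrategyClassifier":
        return self  # stateless rule set

    def predict(self, trajectories: list[Trajectory], geom: MazeGeometry) -> np.ndarray:
        out = []
        for traj in trajectories:
            visits = detect_hole_visits(traj, geom, self.min_visit_frames,
                                        self.merge_gap_s)
            out.append(classify_strategy(visits, traj, geom)[0])
        return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# zones, angles, velocity, primary metrics
# ---------------------------------------------------------------------------

def assign_zone(traj: Trajectory, geom: MazeGeometry,
                out_of_maze_tolerance: float = 0.05) -> np.ndarray:
    """Radial zone of the body point on each frame.

    central: within half a mouse length of the maze centre; serial
    exploration: within one mouse length of the maze edge; approach: the
    annulus between. Frames with the body outside the maze disc by more
    than ``out_of_maze_tolerance`` of the radius are flagged invalid.
    """
    r = np.linalg.norm(traj.body - np.asarray(geom.center), axis=1)
    L = geom.mouse_length
    zone = np.full(traj.n_frames, ZONE_APPROACH, dtype=object)
    zone[r < L / 2.0] = ZONE_CENTRAL
    zone[r > geom.radius - L] = ZONE_SERIAL
    zone[r > geom.radius * (1 + out_of_maze_tolerance)] = ZONE_INVALID
    zone[~traj.valid] = ZONE_INVALID
    return zone


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from v to u, degrees in (-180, 180]."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = (u * v).sum(axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    return np.where(ang <= -180.0, 180.0, ang)


def heading_angles(traj: Trajectory, geom: MazeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Allocentric (omega) and egocentric (phi) heading angles, degrees.

    omega: angle between the body->head vector and the fixed centre->goal
    vector. phi: angle between the body->head vector and the instantaneous
    body->goal vector. Frames with a degenerate body-head vector (or an
    undefined body->goal vector) are NaN, not an error.
    """
    bh = traj.head - traj.body
    goal = geom.goal_center
    cg = np.tile(goal - np.asarray(geom.center), (traj.n_frames, 1))
    bg = goal[None, :] - traj.body
    omega = _signed_angle_deg(bh, cg)
    phi = _signed_angle_deg(bh, bg)
    bad = (np.linalg.norm(bh, axis=1) == 0) | ~traj.valid
    omega[bad | (np.linalg.norm(cg, axis=1) == 0)] = np.nan
    phi[bad | (np.linalg.norm(bg, axis=1) == 0)] = np.nan
    return omega, phi


def velocity(traj: Trajectory, geom: MazeGeometry,
             smooth_frames: int = 5) -> np.ndarray:
    """Body-point speed in cm/s: central differences + moving average.

    Central differences at interior frames, one-sided at the ends,
    smoothed with a ``smooth_frames`` boxcar (~333 ms at 15 FPS by
    default; the window is a tunable, not a measured constant).
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for velocity")
    p = traj.body
    v = np.gradient(p, traj.t, axis=0)        # px/s, central differences
    speed = np.linalg.norm(v, axis=1) / geom.px_per_cm
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = smooth_frames // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")[: traj.n_frames]
    return speed


def primary_metrics(
    visits: list[HoleVisit],
    traj: Trajectory,
    goal_index: int,
) -> tuple[float, int, bool]:
    """Primary latency (s) and primary errors.

    Latency: time from the first tracked frame to the opening of the
    first goal visit (trial duration, flagged, when the goal is never
    visited). Errors: the number of non-goal visit events before that
    time; repeat visits to the same wrong hole count separately.
    """
    goal_pos = [i for i, v in enumerate(visits) if v.hole == goal_index]
    if goal_pos:
        k = goal_pos[0]
        latency = traj.t[visits[k].start_frame] - traj.t[0]
        return float(latency), k, True
    logger.info("no goal visit: latency set to trial duration")
    return float(traj.t[-1] - traj.t[0]), len(visits), False


def compute_trial_behavior(traj: Trajectory, geom: MazeGeometry,
                           smooth_frames: int = 5) -> TrialBehavior:
    """Assemble every behavioural quantity for one trial."""
    visits = detect_hole_visits(traj, geom)
    strategy, matched, reached = classify_strategy(visits, traj, geom)
    latency, errors, _ = primary_metrics(visits, traj, geom.goal_index)
    omega, phi = heading_angles(traj, geom)
    return TrialBehavior(
        strategy=strategy,
        strategy_rule_matched=matched,
        hole_visits=visits,
        primary_latency_s=latency,
        primary_errors=errors,
        reached_goal=reached,
        velocity=velocity(traj, geom, smooth_frames),
        omega=omega,
        phi=phi,
        zone=assign_zone(traj, geom),
    )
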