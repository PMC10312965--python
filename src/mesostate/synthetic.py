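"""Synthetic widefield cohorts with planted ground truth.

Generates everything the analysis consumes — interleaved dual-
illumination movies, DeepLabCut-style tracking tables, and maze
geometry — with known state labels, transition structure, planted
frontal-state episodes and archetypal search trajectories, so that every
downstream stage can be scored against a planted truth.

The movies are a small library of spatial activation templates (frontal
pair, midline, lateral pair, posterior pair — mimicking the recurring
cortical motifs) switching under a semi-Markov dwell process at
0.2-1 s timescales, on a constant baseline with pixel noise and a slow
multiplicative illumination drift shared by both channels. The green
(reference) channel carries the drift and noise but no template signal,
which is exactly what the divisive DF/F correction assumes it can
remove. Serial- and spatial-strategy trials get a frontal dwell longer
than 1 s planted within the first 5 s of the trial, mirroring the
prevalence of early frontal activation in non-random searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import fsa_candidate_events
from .geometry import MazeGeometry, N_HOLES
from .behavior import Trajectory
from .preprocess import FrameStack

FRONTAL_TEMPLATES = (0, 1)     # template ids planted as the frontal pair
BLUE_BASELINE = 2000.0         # counts
GREEN_BASELINE = 1000.0
DRIFT_PERIOD_S = 30.0

# blob centres as (row, col) fractions of the FOV for the 7-motif library;
# frontal pair first (anterior = top). Pairwise centre distances >= 0.3 of
# the FOV, which with the default blob width keeps template correlations
# well below the 0.3 construction bound.
_MOTIF_CENTERS_7 = (
    (0.25, 0.32), (0.25, 0.68),        # frontal L/R
    (0.50, 0.50),                      # midline
    (0.52, 0.15), (0.52, 0.85),        # lateral L/R
    (0.78, 0.35), (0.78, 0.65),        # posterior L/R
)


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Noise and contrast defaults are calibrated so that, after the full
    preprocessing chain, within-state frame correlations sit near 0.6.
    """

    n_mice: int = 3
    trials_per_mouse: int = 6
    fov_shape: tuple[int, int] = (64, 64)
    n_states: int = 7
    fps_per_channel: float = 15.0
    dwell_range: tuple[float, float] = (0.2, 1.0)
    template_contrast: float = 0.15
    pixel_noise_sd: float = 0.045       # relative to baseline
    drift_amplitude: float = 0.02
    strategy_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    maze_diameter_px: float = 600.0
    trial_duration_s: float = 60.0
    blob_sigma_fraction: float = 0.085
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.strategy_mix) - 1.0) > 1e-9:
            raise ValueError("strategy_mix must sum to 1")
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if self.dwell_range[0] <= 1.0 / self.fps_per_channel:
            raise ValueError("minimum dwell must exceed one frame period")
        if self.fov_shape[0] < 32 or self.fov_shape[1] < 32:
            raise ValueError("FOV must be at least 32x32")


@dataclass
class SyntheticGroundTruth:
    """Planted truth for one trial."""

    frame_labels: np.ndarray
    trajectory_archetype: str
    fsa_planted: list[tuple[int, int]]


@dataclass
class TrialData:
    mouse: int
    trial: int
    stack: FrameStack
    trajectory: Trajectory
    strategy: str
    truth: SyntheticGroundTruth


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    templates: np.ndarray
    mask: np.ndarray
    roi_labels: np.ndarray
    geometry: MazeGeometry
    trials: list[list[TrialData]]
    transition_matrix_true: np.ndarray


# ---------------------------------------------------------------------------
# templates, mask, ROI parcellation
# ---------------------------------------------------------------------------

def cortex_mask(fov_shape: tuple[int, int]) -> np.ndarray:
    """Elliptical cortex mask centred in the FOV."""
    H, W = fov_shape
    r, c = np.mgrid[0:H, 0:W]
    return (((r - (H - 1) / 2) / (0.46 * H)) ** 2
            + ((c - (W - 1) / 2) / (0.46 * W)) ** 2) <= 1.0


def _blob_centers(n_states: int) -> list[tuple[float, float]]:
    if n_states == 2:
        return [(0.22, 0.5), (0.78, 0.5)]   # opposite FOV ends
    if n_states <= 7:
        return list(_MOTIF_CENTERS_7[:n_states])
    # beyond the 7-motif library: add a ring of extra centres
    extra = n_states - 7
    ang = 2 * np.pi * np.arange(extra) / max(extra, 1)
    ring = [(0.5 + 0.33 * np.sin(a), 0.5 + 0.33 * np.cos(a)) for a in ang]
    return list(_MOTIF_CENTERS_7) + ring


def make_templates(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spatial activation templates and the cortex mask.

    Each template is a Gaussian blob (peak 1) at a distinct centre,
    zeroed outside the elliptical mask; disjoint centres keep pairwise
    Pearson correlations below 0.3 by construction.
    """
    if config.template_contrast <= 0:
        raise ValueError("template_contrast must be positive")
    H, W = config.fov_shape
    mask = cortex_mask(config.fov_shape)
    sigma = config.blob_sigma_fraction * min(H, W)
    r, c = np.mgrid[0:H, 0:W]
    templates = np.zeros((config.n_states, H, W))
    for i, (fr, fc) in enumerate(_blob_centers(config.n_states)):
        blob = np.exp(-(((r - fr * (H - 1)) ** 2 + (c - fc * (W - 1)) ** 2)
                        / (2 * sigma ** 2)))
        blob[~mask] = 0.0
        templates[i] = blob
    return templates, mask


def make_roi_labels(fov_shape: tuple[int, int]) -> tuple[np.ndarray, dict[int, tuple[str, str]]]:
    """Synthetic cortical parcellation (Allen-style label image).

    Six ROIs — frontal L/R, lateral L/R, midline, posterior — chosen to
    overlay the template motif centres. Returns the label image (0 =
    background) and a map id -> (roi name, roi group).
    """
    H, W = fov_shape
    mask = cortex_mask(fov_shape)
    r, c = np.mgrid[0:H, 0:W]
    rf, cf = r / (H - 1), c / (W - 1)
    labels = np.zeros(fov_shape, dtype=int)
    left = cf < 0.5
    frontal = rf < 0.38
    posterior = rf > 0.66
    lateral = (~frontal) & (~posterior) & ((cf < 0.30) | (cf > 0.70))
    midline = (~frontal) & (~posterior) & ~lateral
    labels[frontal & left] = 1
    labels[frontal & ~left] = 2
    labels[lateral & left] = 3
    labels[lateral & ~left] = 4
    labels[midline] = 5
    labels[posterior] = 6
    labels[~mask] = 0
    names = {1: ("frontal-left", "frontal"), 2: ("frontal-right", "frontal"),
             3: ("lateral-left", "lateral"), 4: ("lateral-right", "lateral"),
             5: ("midline", "midline"), 6: ("posterior", "posterior")}
    return labels, names


# ---------------------------------------------------------------------------
# state label sequences
# ---------------------------------------------------------------------------

def _semi_markov_labels(rng: np.random.Generator, n_frames: int,
                        n_states: int, dwell_range: tuple[float, float],
                        fps: float) -> np.ndarray:
    """Uniform-dwell semi-Markov chain, uniform next state excluding self."""
    labels = np.empty(n_frames, dtype=int)
    t = 0
    state = int(rng.integers(n_states))
    while t < n_frames:
        dwell = int(round(rng.uniform(*dwell_range) * fps))
        dwell = max(dwell, 1)
        labels[t:t + dwell] = state
        t += dwell
        nxt = int(rng.integers(n_states - 1))
        state = nxt + (nxt >= state)
    return labels


def simulate_labels(
    rng: np.random.Generator,
    config: SyntheticConfig,
    strategy: str,
    plant_onset_range_s: tuple[float, float] = (0.5, 3.5),
    plant_duration_range_s: tuple[float, float] = (1.2, 2.2),
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Frame labels for one trial; serial/spatial get a planted FSA dwell.

    The planted dwell of a frontal template lasts longer than 1 s and
    starts inside the first 5 s. The returned event list contains every
    episode satisfying the detector definition (>1 s span, excursions of
    at most 4 frames), computed on the true labels.
    """
    fps = config.fps_per_channel
    n_frames = int(round(config.trial_duration_s * fps))
    labels = _semi_markov_labels(rng, n_frames, config.n_states,
                                 config.dwell_range, fps)
    if strategy not in ("random", "serial", "spatial"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in ("serial", "spatial"):
        onset = int(round(rng.uniform(*plant_onset_range_s) * fps))
        dur = int(round(rng.uniform(*plant_duration_range_s) * fps))
        state = FRONTAL_TEMPLATES[int(rng.integers(len(FRONTAL_TEMPLATES)))]
        labels[onset:onset + dur] = state
    frontal = [f for f in FRONTAL_TEMPLATES if f < config.n_states]
    events = fsa_candidate_events(labels, frontal, fps=fps)
    planted = [(ev.onset_frame, ev.end_frame) for ev in events]
    return labels, planted


def true_transition_matrix(n_states: int) -> np.ndarray:
    """Row-stochastic next-state law of the dwell process (uniform, no self)."""
    P = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(P, 0.0)
    return P


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def simulate_trial_movie(
    templates: np.ndarray,
    mask: np.ndarray,
    config: SyntheticConfig,
    strategy: str,
    rng_seed: int | np.random.Generator,
) -> tuple[FrameStack, SyntheticGroundTruth]:
    """Raw interleaved dual-illumination stack for one trial.

    Blue frames carry baseline x (1 + contrast * template) x drift plus
    pixel noise; green frames carry baseline x drift plus noise only.
    Frames are quantised to unsigned 16-bit counts. Blue comes first in
    the interleave; timestamps tick at twice the per-channel rate.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    labels, planted = simulate_labels(rng, config, strategy)
    T = labels.size
    H, W = config.fov_shape
    fps2 = 2 * config.fps_per_channel
    ts = np.arange(2 * T) / fps2
    phase = rng.uniform(0, 2 * np.pi)
    drift = 1.0 + config.drift_amplitude * np.sin(
        2 * np.pi * ts / DRIFT_PERIOD_S + phase)

    frames = np.empty((2 * T, H, W), dtype=np.uint16)
    signal = 1.0 + config.template_contrast * templates[labels]   # (T, H, W)
    noise_b = rng.normal(0.0, config.pixel_noise_sd * BLUE_BASELINE,
                         size=(T, H, W)) if config.pixel_noise_sd > 0 else 0.0
    noise_g = rng.normal(0.0, config.pixel_noise_sd * GREEN_BASELINE,
                         size=(T, H, W)) if config.pixel_noise_sd > 0 else 0.0
    blue = BLUE_BASELINE * signal * drift[0::2, None, None] + noise_b
    green = GREEN_BASELINE * drift[1::2, None, None] * np.ones((T, H, W)) + noise_g
    frames[0::2] = np.clip(np.rint(blue), 0, 65535).astype(np.uint16)
    frames[1::2] = np.clip(np.rint(green), 0, 65535).astype(np.uint16)

    truth = SyntheticGroundTruth(frame_labels=labels,
                                 trajectory_archetype=strategy,
                                 fsa_planted=planted)
    return FrameStack(frames=frames, timestamps=ts), truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_SPEED_CM_S = 18.0          # travel speed of the synthetic mouse
_NOSE_OFFSET = 0.55         # nose = body + 0.55 L along heading
_HEAD_OFFSET = 0.30


class _PathBuilder:
    """Waypoint walker emitting body positions and look targets per frame."""

    def __init__(self, start: np.ndarray, fps: float, step_px: float):
        self.points = [np.asarray(start, dtype=float)]
        self.targets = [np.asarray(start, dtype=float) + np.array([1.0, 0.0])]
        self.fps = fps
        self.step = step_px

    def dwell(self, n: int, look_at: np.ndarray) -> None:
        for _ in range(n):
            self.points.append(self.points[-1].copy())
            self.targets.append(np.asarray(look_at, dtype=float))

    def go(self, dest: np.ndarray) -> None:
        dest = np.asarray(dest, dtype=float)
        pos = self.points[-1]
        dist = np.linalg.norm(dest - pos)
        n = max(int(np.ceil(dist / self.step)), 1)
        for i in range(1, n + 1):
            self.points.append(pos + (dest - pos) * i / n)
            self.targets.append(dest)


def _hole_approach_point(geom: MazeGeometry, hole: int) -> np.ndarray:
    """Body position from which the nose lands on the hole centre."""
    hc = geom.hole_centers[hole]
    u = (hc - np.asarray(geom.center))
    u = u / np.linalg.norm(u)
    return hc - _NOSE_OFFSET * geom.mouse_length * u


def _visit(pb: _PathBuilder, geom: MazeGeometry, hole: int, dwell: int = 4) -> None:
    pb.go(_hole_approach_point(geom, hole))
    pb.dwell(dwell, geom.hole_centers[hole])


def simulate_trajectory(
    strategy: str,
    geom: MazeGeometry,
    rng_seed: int | np.random.Generator,
    n_frames: int | None = None,
    fps: float = 15.0,
    jitter_px: float = 0.8,
) -> Trajectory:
    """Archetypal search trajectory of the requested strategy.

    random: scattered hole visits across three non-goal quadrants in a
    non-sequential order before the goal. serial: centre -> edge, then
    consecutive perimeter holes towards the goal. spatial: centre ->
    direct goal approach with at most one adjacent-hole check. All start
    within the central circle; nose/head/body stay collinear along the
    instantaneous heading with the head between nose and body.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    g = geom.goal_index
    step = _SPEED_CM_S * geom.px_per_cm / fps
    center = np.asarray(geom.center, dtype=float)
    start = center + rng.uniform(-8, 8, size=2)
    pb = _PathBuilder(start, fps, step)
    pb.dwell(int(rng.integers(8, 15)), center + np.array([0.0, 1.0]))

    if strategy == "spatial":
        if rng.random() < 0.4:
            side = int(rng.choice([-1, 1]))
            _visit(pb, geom, (g + side) % N_HOLES)
        _visit(pb, geom, g, dwell=6)
    elif strategy == "serial":
        side = int(rng.choice([-1, 1]))
        first = int(rng.integers(3, 6))
        for k in range(first, 0, -1):
            _visit(pb, geom, (g - side * k) % N_HOLES, dwell=3)
        _visit(pb, geom, g, dwell=6)
    elif strategy == "random":
        orders = [(1, 3, 2), (3, 1, 2), (2, 1, 3), (2, 3, 1)]
        order = orders[int(rng.integers(len(orders)))]
        sectors = geom.sector_of(geom.hole_centers)
        for sec in order:
            options = np.flatnonzero(sectors == sec)
            hole = int(rng.choice(options))
            _visit(pb, geom, hole, dwell=3)
        _visit(pb, geom, g, dwell=6)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    body = np.stack(pb.points)
    targets = np.stack(pb.targets)
    if n_frames is not None:
        if body.shape[0] > n_frames:
            raise ValueError(
                f"trajectory needs {body.shape[0]} frames but trial has {n_frames}")
        pad = n_frames - body.shape[0]
        body = np.concatenate([body, np.tile(body[-1], (pad, 1))])
        targets = np.concatenate([targets, np.tile(targets[-1], (pad, 1))])

    look = targets - body
    norms = np.linalg.norm(look, axis=1)
    # carry the previous heading through dwells at the target itself
    heading = np.zeros_like(look)
    prev = np.array([1.0, 0.0])
    for i in range(look.shape[0]):
        if norms[i] > 1e-9:
            prev = look[i] / norms[i]
        heading[i] = prev

    body_j = body + rng.normal(0.0, jitter_px, size=body.shape)
    L = geom.mouse_length
    nose = body_j + _NOSE_OFFSET * L * heading
    head = body_j + _HEAD_OFFSET * L * heading
    T = body_j.shape[0]
    return Trajectory(
        t=np.arange(T) / fps,
        nose=nose, head=head, body=body_j,
        likelihood=rng.uniform(0.95, 1.0, size=(T, 3)),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _strategy_schedule(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    """Per-trial strategies honouring the mix (largest-remainder rounding)."""
    n = config.trials_per_mouse
    raw = np.array(config.strategy_mix) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    sched = (["random"] * counts[0] + ["serial"] * counts[1]
             + ["spatial"] * counts[2])
    rng.shuffle(sched)
    return sched


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Full multi-mouse dataset: movies, tracking, geometry, ground truth.

    Deterministic in ``config.seed``: per-trial RNG streams are spawned
    from one root seed sequence.
    """
    root = np.random.SeedSequence(config.seed)
    templates, mask = make_templates(config)
    roi_labels, _ = make_roi_labels(config.fov_shape)
    geom = MazeGeometry.standard(diameter_px=config.maze_diameter_px)
    trials: list[list[TrialData]] = []
    n_frames = int(round(config.trial_duration_s * config.fps_per_channel))
    mice_seeds = root.spawn(config.n_mice)
    for mi in range(config.n_mice):
        sched_rng = np.random.default_rng(mice_seeds[mi])
        sched = _strategy_schedule(config, sched_rng)
        mouse_trials = []
        trial_seeds = mice_seeds[mi].spawn(config.trials_per_mouse)
        for ti in range(config.trials_per_mouse):
            ss = trial_seeds[ti].spawn(2)
            stack, truth = simulate_trial_movie(
                templates, mask, config, sched[ti], np.random.default_rng(ss[0]))
            traj = simulate_trajectory(
                sched[ti], geom, np.random.default_rng(ss[1]),
                n_frames=n_frames, fps=config.fps_per_channel)
            mouse_trials.append(TrialData(mouse=mi, trial=ti, stack=stack,
                                          trajectory=traj, strategy=sched[ti],
                                          truth=truth))
        trials.append(mouse_trials)
    return SyntheticCohort(
        config=config, templates=templates, mask=mask, roi_labels=roi_labels,
        geometry=geom, trials=trials,
        transition_matrix_true=true_transition_matrix(config.n_states),
    )
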