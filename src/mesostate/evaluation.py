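"""Recovery benchmarks: score the pipeline against planted ground truth.

Each routine builds the synthetic inputs it needs, runs the relevant
pipeline stage(s) from scratch, and measures how well the planted
structure is recovered. They are used both by the test suite and by the
reproduction script, and are ordinary package functionality: the same
checks apply whenever the generator's conditions are changed.

Desk-scale compute settings (k-means replicates, frame stride, block
matrix size) are arguments with defaults chosen so every benchmark runs
in minutes on one CPU; the study conditions themselves (cohort sizes,
noise, dwell statistics) come from :class:`SyntheticConfig` defaults.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .annotate import annotate_consensus, resolve_frontal_ids
from .behavior import StrategyClassifier, Trajectory, heading_angles
from .dynamics import (StateSeries, activation_probability, bootstrap_histogram,
                       bootstrap_null, detect_fsa, detect_fsa_reference,
                       peri_event_histogram, significance, transition_matrix)
from .geometry import MazeGeometry
from .preprocess import (DffPreprocessor, FrameStack, bandpass, bin_labels,
                         compute_dff, spatial_smooth)
from .states import (ConsensusStates, CorrelationStateClustering, select_k,
                     t_distance)
from .synthetic import (FRONTAL_TEMPLATES, SyntheticConfig, make_roi_labels,
                        simulate_cohort, simulate_trajectory)


# ---------------------------------------------------------------------------
# state recovery (planted templates -> consensus labels)
# ---------------------------------------------------------------------------

def preprocess_cohort(cohort, preprocessor: DffPreprocessor | None = None):
    """Per-mouse lists of DF/F movies for a synthetic cohort."""
    pre = preprocessor or DffPreprocessor()
    return [[pre.transform(t.stack, cohort.mask) for t in mt]
            for mt in cohort.trials]


def state_recovery_benchmark(
    config: SyntheticConfig | None = None,
    n_seeds: int = 10,
    replicates: int = 5,
    max_iter: int = 300,
    stride: int = 6,
    k_range: tuple[int, int] = (2, 15),
    base_seed: int = 0,
) -> dict:
    """Planted-template recovery on a synthetic cohort.

    Generates the cohort, preprocesses every trial, and per mouse runs
    t-distance model selection under ``n_seeds`` different k-means seeds;
    then builds the consensus space (first seed) and scores frame-level
    ARI of consensus labels against planted labels per mouse.

    Returns k values per (mouse, seed), the fraction equal to the planted
    count, and per-mouse ARI.
    """
    config = config or SyntheticConfig()
    cohort = simulate_cohort(replace(config, seed=config.seed + base_seed))
    movies = preprocess_cohort(cohort)
    true_k = config.n_states

    k_values = np.zeros((config.n_mice, n_seeds), dtype=int)
    models = []
    for mi in range(config.n_mice):
        for si in range(n_seeds):
            est = CorrelationStateClustering(
                k_range=k_range, replicates=replicates, max_iter=max_iter,
                stride=stride, random_state=base_seed + si)
            est.fit(movies[mi])
            k_values[mi, si] = est.k_
            if si == 0:
                models.append(est)
    cons = ConsensusStates(n_consensus=true_k, replicates=max(replicates, 20),
                           max_iter=max_iter,
                           random_state=base_seed).fit(models, models[0].mask_)
    aris = []
    for mi, est in enumerate(models):
        lab = cons.relabel(mi, est.labels_)
        truth = np.concatenate([t.truth.frame_labels for t in cohort.trials[mi]])
        aris.append(adjusted_rand_score(truth, lab))
    return {
        "k_values": k_values,
        "k_recovery_fraction": float(np.mean(k_values == true_k)),
        "ari_per_mouse": np.asarray(aris),
        "min_ari": float(np.min(aris)),
    }


# ---------------------------------------------------------------------------
# model selection on planted block matrices
# ---------------------------------------------------------------------------

def planted_block_matrix(rng: np.random.Generator, n_blocks: int = 3,
                         block_size: int = 30, within: float = 0.9,
                         across: float = 0.0, noise_sd: float = 0.05) -> np.ndarray:
    """Symmetric correlation-like matrix with planted diagonal blocks."""
    N = n_blocks * block_size
    lab = np.repeat(np.arange(n_blocks), block_size)
    C = np.where(lab[:, None] == lab[None, :], within, across).astype(float)
    noise = rng.normal(0, noise_sd, size=(N, N))
    C = C + (noise + noise.T) / np.sqrt(2)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def block_selection_benchmark(
    n_seeds: int = 20,
    k_range: tuple[int, int] = (2, 8),
    replicates: int = 10,
    seed: int = 0,
) -> dict:
    """t-distance model selection on 3-block planted matrices.

    Per seed, draws a fresh noisy block matrix, runs select_k, and also
    evaluates the t-distance of the planted k=3 and k=2 labellings
    directly (3 blocks must always beat 2).
    """
    ks, t3_gt_t2 = [], []
    for si in range(n_seeds):
        rng = np.random.default_rng(seed + si)
        C = planted_block_matrix(rng)
        k, _, _ = select_k(C, k_range=k_range, seed=seed + si,
                           replicates=replicates, max_iter=300)
        ks.append(k)
        lab3 = np.repeat(np.arange(3), 30)
        lab2 = np.repeat([0, 0, 1], 30)
        t3_gt_t2.append(t_distance(C, lab3) > t_distance(C, lab2))
    ks = np.asarray(ks)
    return {
        "k_values": ks,
        "fraction_k3": float(np.mean(ks == 3)),
        "t3_greater_than_t2_all": bool(np.all(t3_gt_t2)),
    }


# ---------------------------------------------------------------------------
# FSA detector vs brute-force reference
# ---------------------------------------------------------------------------

def fsa_oracle_benchmark(
    n_sequences: int = 1000,
    length: int = 450,
    n_states: int = 7,
    seed: int = 0,
    fps: float = 15.0,
) -> dict:
    """Exact agreement of the production FSA detector with the reference.

    Random i.i.d. state sequences; presence, onset and end must all match
    the brute-force scan on every sequence.
    """
    rng = np.random.default_rng(seed)
    frontal = list(FRONTAL_TEMPLATES)
    mismatches = []
    for i in range(n_sequences):
        states = rng.integers(n_states, size=length)
        ser = StateSeries(states=states, fps=fps)
        ev = detect_fsa(ser, frontal)
        ref = detect_fsa_reference(states, frontal, fps=fps)
        got = None if ev is None else (ev.onset_frame, ev.end_frame)
        if got != ref:
            mismatches.append((i, got, ref))
    return {
        "n_sequences": n_sequences,
        "n_mismatches": len(mismatches),
        "agreement_fraction": 1.0 - len(mismatches) / n_sequences,
        "mismatches": mismatches[:10],
    }


# ---------------------------------------------------------------------------
# conservation checks
# ---------------------------------------------------------------------------

def conservation_benchmark(
    n_trials: int = 20,
    length: int = 450,
    n_states: int = 7,
    n_boot: int = 20,
    seed: int = 0,
) -> dict:
    """Probability-conservation deviations on arbitrary random series."""
    rng = np.random.default_rng(seed)
    series = [StateSeries(states=rng.integers(n_states, size=length),
                          fps=15.0, trial_id=str(i)) for i in range(n_trials)]
    act = activation_probability(series, n_states)
    psum = act[[f"P{s}" for s in range(n_states)]].sum(axis=1).to_numpy()
    act_dev = float(np.max(np.abs(psum - 1.0)))

    tm = transition_matrix(series, n_states)
    rowsum = tm.probabilities.sum(axis=1)
    tm_dev = float(np.max(np.abs(rowsum[~tm.zero_rows] - 1.0))) if np.any(~tm.zero_rows) else 0.0
    zero_rows_all_zero = bool(np.all(tm.probabilities[tm.zero_rows] == 0))

    reps = bootstrap_null(series, n_boot=n_boot, seed=seed)
    count_dev = 0
    for rep in reps:
        for ser, perm in zip(series, rep):
            a = np.bincount(ser.states, minlength=n_states)
            b = np.bincount(perm, minlength=n_states)
            count_dev = max(count_dev, int(np.abs(a - b).max()))
    return {
        "activation_sum_max_dev": act_dev,
        "transition_rowsum_max_dev": tm_dev,
        "zero_rows_flagged": zero_rows_all_zero,
        "bootstrap_count_max_dev": count_dev,
    }


# ---------------------------------------------------------------------------
# behaviour classifier and heading angles
# ---------------------------------------------------------------------------

def classifier_benchmark(
    n_archetypal: int = 10,
    n_random: int = 100,
    seed: int = 0,
) -> dict:
    """Archetypal-trajectory classification accuracy."""
    geom = MazeGeometry.standard()
    clf = StrategyClassifier()
    out = {}
    for strat, n in (("spatial", n_archetypal), ("serial", n_archetypal),
                     ("random", n_random)):
        trajs = [simulate_trajectory(strat, geom, seed * 10007 + i, n_frames=900)
                 for i in range(n)]
        pred = clf.predict(trajs, geom)
        out[f"{strat}_correct"] = int(np.sum(pred == strat))
        out[f"{strat}_total"] = n
        bad = [i for i, p in enumerate(pred) if p != strat]
        if bad:
            out[f"{strat}_failed_seeds"] = [seed * 10007 + i for i in bad]
    return out


def heading_exactness() -> dict:
    """Max |error| of omega/phi on the three analytic geometries.

    aligned: body at centre, head toward the goal (omega = phi = 0);
    perpendicular: body-head vector orthogonal to centre->goal
    (|omega| = 90); collinear: body on the centre-goal segment, head at
    the goal (omega = phi = 0 regardless of body position).
    """
    geom = MazeGeometry.standard(goal_index=3)   # goal off-axis
    c = np.asarray(geom.center)
    g = geom.goal_center
    u = (g - c) / np.linalg.norm(g - c)
    perp = np.array([-u[1], u[0]])
    mid = c + 0.5 * (g - c)
    body = np.stack([c, c, mid])
    head = np.stack([c + 30 * u, c + 30 * perp, mid + 30 * u])
    traj = Trajectory(t=np.arange(3) / 15.0, nose=head + 10 * (head - body),
                      head=head, body=body)
    om, ph = heading_angles(traj, geom)
    err = max(abs(om[0]), abs(ph[0]), abs(abs(om[1]) - 90.0),
              abs(om[2]), abs(ph[2]))
    return {"max_abs_error_deg": float(err)}


# ---------------------------------------------------------------------------
# preprocessing contracts
# ---------------------------------------------------------------------------

def preprocessing_contracts(seed: int = 0) -> dict:
    """Filter, smoothing and drift-cancellation contract measurements."""
    fps, T = 15.0, 900
    t = np.arange(T) / fps
    mask1 = np.ones((1, 1), dtype=bool)

    def amp(f_hz):
        x = np.sin(2 * np.pi * f_hz * t)[:, None, None]
        y, _ = bandpass(x, mask1, fps=fps)
        mid = y[T // 4: 3 * T // 4, 0, 0]
        return float(np.max(np.abs(mid)))

    a1, a001, a7 = amp(1.0), amp(0.01), amp(7.0)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=T)[:, None, None]
    y_fwd, _ = bandpass(x, mask1, fps=fps)
    y_rev, _ = bandpass(x[::-1], mask1, fps=fps)
    revsym = float(np.max(np.abs(y_rev[::-1] - y_fwd)))

    # spatial smoothing vs per-pixel loop oracle
    H = W = 20
    mask = np.zeros((H, W), dtype=bool)
    mask[2:18, 3:17] = True
    img = rng.normal(size=(H, W))
    sm = spatial_smooth(img, mask)
    from .preprocess import SMOOTH_OFFSETS
    oracle = np.zeros_like(img)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            vals = [img[r + dr, c + dc] for dr, dc in SMOOTH_OFFSETS
                    if 0 <= r + dr < H and 0 <= c + dc < W and mask[r + dr, c + dc]]
            oracle[r, c] = np.mean(vals)
    smooth_dev = float(np.max(np.abs(sm - oracle)))

    # drift cancellation: both channels carry the same per-pair drift value
    # (each green frame shares its paired blue frame's illumination state)
    drift = 1.0 + 0.05 * np.sin(2 * np.pi * t / 20.0)
    mask2 = np.ones((4, 4), dtype=bool)
    blue = FrameStack(frames=2000.0 * drift[:, None, None] * np.ones((T, 4, 4)),
                      timestamps=t)
    green = FrameStack(frames=1000.0 * drift[:, None, None] * np.ones((T, 4, 4)),
                       timestamps=t + 1.0 / 60.0)
    dff = compute_dff(blue, green, mask2)
    drift_dev = float(np.max(np.abs(dff)))

    return {
        "attenuation_1hz_db": float(-20 * np.log10(a1)),
        "attenuation_0p01hz_db": float(-20 * np.log10(max(a001, 1e-300))),
        "attenuation_7hz_db": float(-20 * np.log10(max(a7, 1e-300))),
        "reversal_symmetry_max_dev": revsym,
        "spatial_smooth_max_dev": smooth_dev,
        "drift_cancellation_max_abs_dff": drift_dev,
    }


# ---------------------------------------------------------------------------
# significance calibration
# ---------------------------------------------------------------------------

def _run_structured_series(rng, n_trials, length, n_states, fps=15.0,
                           dwell_range=(0.2, 1.0)):
    from .synthetic import _semi_markov_labels

    return [StateSeries(states=_semi_markov_labels(rng, length, n_states,
                                                   dwell_range, fps),
                        fps=fps, trial_id=str(i)) for i in range(n_trials)]


def significance_calibration(
    n_repeats: int = 100,
    n_trials: int = 20,
    length: int = 450,
    n_states: int = 7,
    n_boot: int = 100,
    planted_state: int | None = None,
    planted_prob: float = 0.6,
    planted_frames: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error (null) or power (planted) of the peri-event ANOVA.

    Null: dwell-structured random sequences aligned at random anchor
    frames — no state is preferentially active anywhere, so any
    significant cell is a false positive; the family-wise error is the
    fraction of repeats flagging anything. Planted: before each anchor,
    ``planted_state`` is drawn with probability ``planted_prob`` for
    ``planted_frames`` frames; power is the fraction of repeats flagging
    that state in the pre-onset window.
    """
    from .dynamics import FsaEvent

    rng = np.random.default_rng(seed)
    fps = 15.0
    hits = 0
    for _ in range(n_repeats):
        series = _run_structured_series(rng, n_trials, length, n_states, fps)
        anchors = rng.integers(60, length - 60, size=n_trials)
        if planted_state is not None:
            for ser, anc in zip(series, anchors):
                sel = rng.random(planted_frames) < planted_prob
                window = ser.states[anc - planted_frames: anc]
                repl = rng.integers(n_states - 1, size=planted_frames)
                repl = repl + (repl >= planted_state)
                window[sel] = planted_state
                window[~sel] = repl[~sel]
        events = [FsaEvent(onset_frame=int(a), end_frame=int(a) + 15, fps=fps)
                  for a in anchors]
        hist = peri_event_histogram(series, events, n_states)
        hist = bootstrap_histogram(hist, series, events, n_states,
                                   n_boot=n_boot, seed=rng)
        hist = significance(hist, alpha=alpha)
        if planted_state is None:
            if hist.significant_05.any():
                hits += 1
        else:
            pre = hist.offsets < 0
            recent = hist.offsets >= -planted_frames
            if hist.significant_05[planted_state][pre & recent].any():
                hits += 1
    rate = hits / n_repeats
    mc_sd = float(np.sqrt(max(rate * (1 - rate), alpha * (1 - alpha)) / n_repeats))
    return {"rate": rate, "n_repeats": n_repeats, "mc_sd": mc_sd}


# ---------------------------------------------------------------------------
# directional FSA reproduction
# ---------------------------------------------------------------------------

def fsa_strategy_benchmark(
    config: SyntheticConfig | None = None,
    replicates: int = 5,
    stride: int = 4,
    seed: int = 0,
) -> dict:
    """FSA detection fraction per search strategy, full pipeline.

    Generates a cohort whose serial and spatial trials carry planted
    early frontal dwells (the random trials rely on chance frontal
    episodes only), runs preprocessing, per-mouse clustering at the
    planted state count, the cross-mouse consensus, automatic frontal
    annotation, and the FSA detector; reports the detected fraction per
    strategy.
    """
    config = config or SyntheticConfig(
        n_mice=3, trials_per_mouse=12, trial_duration_s=30.0, seed=seed)
    cohort = simulate_cohort(config)
    movies = preprocess_cohort(cohort)
    models = []
    for mi in range(config.n_mice):
        est = CorrelationStateClustering(
            k=config.n_states, replicates=replicates, max_iter=300,
            stride=stride, random_state=seed)
        est.fit(movies[mi])
        models.append(est)
    cons = ConsensusStates(n_consensus=config.n_states, replicates=20,
                           random_state=seed).fit(models, models[0].mask_)
    roi_small = bin_labels(cohort.roi_labels, 0.8)
    _, roi_names = make_roi_labels(config.fov_shape)
    ann = annotate_consensus(cons.consensus_maps_, roi_small, roi_names)
    frontal = resolve_frontal_ids(ann, "auto")

    detected = {"random": [0, 0], "serial": [0, 0], "spatial": [0, 0]}
    for mi, est in enumerate(models):
        lab = cons.relabel(mi, est.labels_)
        pos = 0
        for t, movie in zip(cohort.trials[mi], movies[mi]):
            n = int(movie.valid.sum())
            states = np.full(movie.n_frames, -1, dtype=int)
            states[np.flatnonzero(movie.valid)] = lab[pos:pos + n]
            pos += n
            ser = StateSeries(states=states, fps=movie.fps, strategy=t.strategy)
            ev = detect_fsa(ser, frontal)
            detected[t.strategy][1] += 1
            if ev is not None:
                detected[t.strategy][0] += 1
    return {
        "frontal_ids": frontal,
        "state_names": ann.names,
        "fractions": {k: (v[0] / v[1] if v[1] else np.nan)
                      for k, v in detected.items()},
        "counts": detected,
    }
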