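"""Standard-format I/O: TIFF/HDF5 stacks, DeepLabCut CSV, JSON artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .behavior import Trajectory, TrialBehavior
from .dynamics import FsaEvent, StateSeries, TransitionMatrix
from .preprocess import DffMovie, FrameStack

DLC_SCORER = "mesostate-synthetic"
DLC_PARTS = ("nose", "head", "body")


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_stack_tiff(path: str | Path, stack: FrameStack) -> None:
    tifffile.imwrite(path, stack.frames, metadata={
        "timestamps": stack.timestamps.tolist()})


def read_stack_tiff(path: str | Path, fps_total: float = 30.0) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    ts = meta.get("timestamps")
    ts = (np.asarray(ts, dtype=float) if ts is not None
          else np.arange(frames.shape[0]) / fps_total)
    return FrameStack(frames=frames, timestamps=ts)


def write_stack_h5(path: str | Path, stack: FrameStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames, compression="gzip")
        f.create_dataset("timestamps", data=stack.timestamps)


def read_stack_h5(path: str | Path) -> FrameStack:
    with h5py.File(path, "r") as f:
        return FrameStack(frames=f["frames"][()], timestamps=f["timestamps"][()])


def write_dff_movie(path: str | Path, movie: DffMovie) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=movie.data, compression="gzip")
        f.create_dataset("mask", data=movie.mask)
        f.create_dataset("valid", data=movie.valid)
        f.attrs["fps"] = movie.fps
        f.attrs["filtered"] = movie.filtered
        if movie.roi_labels is not None:
            f.create_dataset("roi_labels", data=movie.roi_labels)


def read_dff_movie(path: str | Path) -> DffMovie:
    with h5py.File(path, "r") as f:
        roi = f["roi_labels"][()] if "roi_labels" in f else None
        return DffMovie(data=f["data"][()], mask=f["mask"][()].astype(bool),
                        valid=f["valid"][()].astype(bool),
                        fps=float(f.attrs["fps"]),
                        roi_labels=roi, filtered=bool(f.attrs["filtered"]))


# ---------------------------------------------------------------------------
# DeepLabCut-dialect tracking tables
# ---------------------------------------------------------------------------

def write_dlc_csv(path: str | Path, traj: Trajectory,
                  scorer: str = DLC_SCORER) -> None:
    """Tracking table in the DeepLabCut CSV dialect.

    Three header rows (scorer / bodyparts / coords) and one x, y,
    likelihood column triple per body part.
    """
    cols = pd.MultiIndex.from_product([[scorer], DLC_PARTS, ["x", "y", "likelihood"]],
                                      names=["scorer", "bodyparts", "coords"])
    lk = (traj.likelihood if traj.likelihood is not None
          else np.ones((traj.n_frames, 3)))
    data = np.empty((traj.n_frames, 9))
    for i, part in enumerate(DLC_PARTS):
        xy = getattr(traj, part)
        data[:, 3 * i] = xy[:, 0]
        data[:, 3 * i + 1] = xy[:, 1]
        data[:, 3 * i + 2] = lk[:, i]
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")


def read_dlc_csv(path: str | Path, fps: float = 15.0,
                 likelihood_threshold: float = 0.9) -> Trajectory:
    """Read a DeepLabCut CSV; frames with any part below threshold are invalid."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    parts = {}
    lk = np.ones((len(df), 3))
    for i, part in enumerate(DLC_PARTS):
        sub = df[scorer][part]
        parts[part] = sub[["x", "y"]].to_numpy(dtype=float)
        if "likelihood" in sub:
            lk[:, i] = sub["likelihood"].to_numpy(dtype=float)
    valid = (lk >= likelihood_threshold).all(axis=1)
    return Trajectory(t=np.arange(len(df)) / fps, nose=parts["nose"],
                      head=parts["head"], body=parts["body"],
                      likelihood=lk, valid=valid)


# ---------------------------------------------------------------------------
# analysis artifacts
# ---------------------------------------------------------------------------

def write_state_series_csv(path: str | Path, series: list[StateSeries]) -> None:
    rows = []
    for ser in series:
        for f, s in enumerate(ser.states):
            rows.append({"trial": ser.trial_id, "frame": f,
                         "time_s": f / ser.fps, "consensus_state": int(s),
                         "strategy": ser.strategy})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_state_series_csv(path: str | Path, fps: float = 15.0) -> list[StateSeries]:
    df = pd.read_csv(path)
    out = []
    for trial, sub in df.groupby("trial", sort=False):
        strat = sub["strategy"].iloc[0]
        out.append(StateSeries(states=sub["consensus_state"].to_numpy(),
                               fps=fps, trial_id=str(trial),
                               strategy=None if pd.isna(strat) else strat))
    return out


def write_events_json(path: str | Path, events: dict[str, FsaEvent | None]) -> None:
    payload = {
        tid: (None if ev is None else {
            "onset_frame": int(ev.onset_frame), "end_frame": int(ev.end_frame),
            "onset_time_s": float(ev.onset_time_s),
            "duration_s": float(ev.duration_s),
            "jitter_frames_used": int(ev.jitter_frames_used)})
        for tid, ev in events.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def write_transition_csv(path: str | Path, tm: TransitionMatrix) -> None:
    n = tm.probabilities.shape[0]
    df = pd.DataFrame(tm.probabilities,
                      index=[f"from_{i}" for i in range(n)],
                      columns=[f"to_{i}" for i in range(n)])
    df.to_csv(path)


def write_behavior_json(path: str | Path, beh: TrialBehavior) -> None:
    payload = {
        "strategy": beh.strategy,
        "strategy_rule_matched": beh.strategy_rule_matched,
        "reached_goal": beh.reached_goal,
        "primary_latency_s": beh.primary_latency_s,
        "primary_errors": beh.primary_errors,
        "hole_visits": [{"hole": v.hole, "start_frame": v.start_frame,
                         "end_frame": v.end_frame} for v in beh.hole_visits],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
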