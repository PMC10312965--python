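"""End-to-end pipeline: config, staging, caching, manifest.

Stages run in fixed order — synth (optional) -> preprocess -> behavior
-> cluster -> dynamics -> report — with each stage's outputs cached on
disk under the output directory and keyed by a hash of the parameters it
depends on, so re-running with an unchanged config is a no-op and
changing, say, only the dynamics block recomputes only dynamics. The
manifest records config hashes, seeds and per-stage output checksums;
any result is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .annotate import annotate_consensus, resolve_frontal_ids
from .behavior import compute_trial_behavior
from .dynamics import (StateSeries, activation_probability, bootstrap_histogram,
                       detect_fsa, peri_event_histogram, significance,
                       transition_matrix)
from .preprocess import DffPreprocessor
from .states import ConsensusStates, CorrelationStateClustering
from .synthetic import SyntheticConfig, make_roi_labels, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "behavior", "cluster", "dynamics", "report")


@dataclass
class PreprocessingConfig:
    bin_factor: float = 0.8
    low_hz: float = 0.1
    high_hz: float = 5.0
    fps: float = 15.0
    filter_order: int = 3
    ripple_db: float = 0.5
    likelihood_threshold: float = 0.9


@dataclass
class ClusteringConfig:
    k_range: tuple[int, int] = (2, 15)
    replicates: int = 500
    max_iter: int = 5000
    n_consensus: int = 7
    stride: int = 1
    seed: int = 0


@dataclass
class DynamicsConfig:
    frontal_ids: list[int] | str = "auto"
    max_jitter: int = 4
    search_window_s: float = 10.0
    min_duration_s: float = 1.0
    n_boot: int = 100
    alpha: float = 0.05
    window_s: tuple[float, float] = (-3.0, 3.0)


@dataclass
class PipelineConfig:
    output_dir: str = "mesostate_output"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(tp, d):
            fields = {f.name for f in dataclasses.fields(tp)}
            unknown = set(d) - fields
            if unknown:
                raise ValueError(f"unknown config keys for {tp.__name__}: {unknown}")
            kw = {}
            for f in dataclasses.fields(tp):
                if f.name in d:
                    v = d[f.name]
                    if isinstance(v, list) and f.name in (
                            "fov_shape", "dwell_range", "strategy_mix",
                            "k_range", "window_s"):
                        v = tuple(v)
                    kw[f.name] = v
            return tp(**kw)

        return cls(
            output_dir=raw.get("output_dir", "mesostate_output"),
            seed=int(raw.get("seed", 0)),
            synthetic=build(SyntheticConfig, raw.get("synthetic", {})),
            preprocessing=build(PreprocessingConfig, raw.get("preprocessing", {})),
            clustering=build(ClusteringConfig, raw.get("clustering", {})),
            dynamics=build(DynamicsConfig, raw.get("dynamics", {})),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one root seed (< 2**31)."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage} failed: {message}")
        self.stage = stage


class Pipeline:
    """Stage runner with on-disk caching and a reproducibility manifest."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else {"stages": {}})
        for h in list(logger.handlers):       # one log file per output dir
            if getattr(h, "_mesostate_log", False):
                logger.removeHandler(h)
                h.close()
        fh = logging.FileHandler(self.out / "pipeline.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        fh._mesostate_log = True
        logger.addHandler(fh)
        logger.setLevel(logging.INFO)

    # dependency chain: a stage's hash covers its own block plus everything
    # upstream, so an upstream change invalidates all downstream caches
    def _stage_hash(self, stage: str) -> str:
        c = self.config
        blocks = {
            "synth": [asdict(c.synthetic), c.seed],
            "preprocess": [asdict(c.synthetic), asdict(c.preprocessing), c.seed],
            "behavior": [asdict(c.synthetic), asdict(c.preprocessing), c.seed],
            "cluster": [asdict(c.synthetic), asdict(c.preprocessing),
                        asdict(c.clustering), c.seed],
            "dynamics": [asdict(c.synthetic), asdict(c.preprocessing),
                         asdict(c.clustering), asdict(c.dynamics), c.seed],
            "report": [asdict(c.synthetic), asdict(c.preprocessing),
                       asdict(c.clustering), asdict(c.dynamics), c.seed],
        }
        return _hash_obj(blocks[stage])

    def _is_cached(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if rec is None or rec.get("hash") != self._stage_hash(stage):
            return False
        return all(Path(p).exists() for p in rec.get("outputs", []))

    def _record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "hash": self._stage_hash(stage),
            "outputs": [str(p) for p in outputs],
            "checksums": {p.name: _file_checksum(p) for p in outputs},
            "seed": stage_seed(self.config.seed, stage),
        }
        self.manifest["config"] = self.config.to_dict()
        self.manifest_path.write_text(
            json.dumps(self.manifest, indent=2, default=str))

    # -- stages -------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> dict:
        ran = {}
        for stage in stages:
            if self._is_cached(stage):
                logger.info("stage %s: cached, skipping", stage)
                ran[stage] = "cached"
                continue
            try:
                getattr(self, f"_run_{stage}")()
            except Exception as exc:  # partial outputs retained
                self.manifest["stages"].pop(stage, None)
                self.manifest["failed_stage"] = stage
                self.manifest_path.write_text(
                    json.dumps(self.manifest, indent=2, default=str))
                raise PipelineError(stage, str(exc)) from exc
            ran[stage] = "ran"
        return ran

    def _run_synth(self) -> None:
        c = self.config
        cohort = simulate_cohort(dataclasses.replace(
            c.synthetic, seed=stage_seed(c.seed, "synth")))
        d = self.out / "raw"
        d.mkdir(exist_ok=True)
        outputs = []
        for mt in cohort.trials:
            for t in mt:
                base = d / f"m{t.mouse}_t{t.trial}"
                mio.write_stack_h5(base.with_suffix(".h5"), t.stack)
                mio.write_dlc_csv(base.with_suffix(".csv"), t.trajectory)
                outputs += [base.with_suffix(".h5"), base.with_suffix(".csv")]
        np.save(d / "mask.npy", cohort.mask)
        np.save(d / "roi_labels.npy", cohort.roi_labels)
        cohort.geometry.to_json(d / "geometry.json")
        mio.write_json(d / "ground_truth.json", {
            "strategies": [[t.strategy for t in mt] for mt in cohort.trials],
            "frame_labels": [[t.truth.frame_labels for t in mt]
                             for mt in cohort.trials],
            "fsa_planted": [[t.truth.fsa_planted for t in mt]
                            for mt in cohort.trials],
            "transition_matrix_true": cohort.transition_matrix_true,
        })
        outputs += [d / "mask.npy", d / "roi_labels.npy", d / "geometry.json",
                    d / "ground_truth.json"]
        self._record("synth", outputs)

    def _iter_raw(self):
        c = self.config.synthetic
        d = self.out / "raw"
        for mi in range(c.n_mice):
            for ti in range(c.trials_per_mouse):
                yield mi, ti, d / f"m{mi}_t{ti}.h5", d / f"m{mi}_t{ti}.csv"

    def _run_preprocess(self) -> None:
        p = self.config.preprocessing
        d = self.out / "dff"
        d.mkdir(exist_ok=True)
        mask = np.load(self.out / "raw" / "mask.npy")
        roi = np.load(self.out / "raw" / "roi_labels.npy")
        pre = DffPreprocessor(bin_factor=p.bin_factor, low_hz=p.low_hz,
                              high_hz=p.high_hz, fps=p.fps,
                              filter_order=p.filter_order, ripple_db=p.ripple_db)
        outputs = []
        for mi, ti, h5, _csv in self._iter_raw():
            stack = mio.read_stack_h5(h5)
            movie = pre.transform(stack, mask, roi_labels=roi)
            out = d / f"m{mi}_t{ti}.h5"
            mio.write_dff_movie(out, movie)
            pre.audit_.to_csv(d / f"m{mi}_t{ti}_audit.csv", index=False)
            outputs += [out, d / f"m{mi}_t{ti}_audit.csv"]
        self._record("preprocess", outputs)

    def _run_behavior(self) -> None:
        from .geometry import MazeGeometry

        p = self.config.preprocessing
        geom = MazeGeometry.from_json(self.out / "raw" / "geometry.json")
        d = self.out / "behavior"
        d.mkdir(exist_ok=True)
        outputs = []
        for mi, ti, _h5, csv in self._iter_raw():
            traj = mio.read_dlc_csv(csv, fps=p.fps,
                                    likelihood_threshold=p.likelihood_threshold)
            beh = compute_trial_behavior(traj, geom)
            out = d / f"m{mi}_t{ti}.json"
            mio.write_behavior_json(out, beh)
            outputs.append(out)
        self._record("behavior", outputs)

    def _run_cluster(self) -> None:
        cl = self.config.clustering
        d = self.out / "states"
        d.mkdir(exist_ok=True)
        c = self.config.synthetic
        seed = stage_seed(self.config.seed, "cluster")
        models, all_movies = [], []
        for mi in range(c.n_mice):
            movies = [mio.read_dff_movie(self.out / "dff" / f"m{mi}_t{ti}.h5")
                      for ti in range(c.trials_per_mouse)]
            est = CorrelationStateClustering(
                k_range=cl.k_range, replicates=cl.replicates,
                max_iter=cl.max_iter, stride=cl.stride, random_state=seed)
            est.fit(movies)
            models.append(est)
            all_movies.append(movies)
        cons = ConsensusStates(n_consensus=cl.n_consensus,
                               replicates=cl.replicates, max_iter=cl.max_iter,
                               random_state=seed).fit(models, models[0].mask_)
        series = []
        for mi, est in enumerate(models):
            lab = cons.relabel(mi, est.labels_)
            # split back into per-trial series via the frame index
            for ti in range(c.trials_per_mouse):
                sel = [j for j, (t, _f) in enumerate(est.frame_index_) if t == ti]
                movie = all_movies[mi][ti]
                full = np.full(movie.n_frames, -1, dtype=int)
                full[np.flatnonzero(movie.valid)] = lab[sel]
                series.append(StateSeries(states=full, fps=movie.fps,
                                          trial_id=f"m{mi}_t{ti}"))
        import h5py

        with h5py.File(d / "models.h5", "w") as f:
            for mi, est in enumerate(models):
                g = f.create_group(f"mouse_{mi}")
                g.create_dataset("labels", data=est.labels_)
                g.create_dataset("mean_maps", data=est.mean_maps_)
                g.create_dataset("tdist_k", data=sorted(est.tdist_curve_))
                g.create_dataset(
                    "tdist", data=[est.tdist_curve_[k]
                                   for k in sorted(est.tdist_curve_)])
                g.attrs["k"] = est.k_
            g = f.create_group("consensus")
            g.create_dataset("maps", data=cons.consensus_maps_)
            g.create_dataset("map_labels", data=cons.map_labels_)
        mio.write_state_series_csv(d / "state_series.csv", series)
        self._record("cluster", [d / "models.h5", d / "state_series.csv"])

    def _run_dynamics(self) -> None:
        import h5py

        from .geometry import MazeGeometry

        dy = self.config.dynamics
        c = self.config.synthetic
        p = self.config.preprocessing
        d = self.out / "dynamics"
        d.mkdir(exist_ok=True)
        geom = MazeGeometry.from_json(self.out / "raw" / "geometry.json")
        series = mio.read_state_series_csv(
            self.out / "states" / "state_series.csv", fps=p.fps)
        with h5py.File(self.out / "states" / "models.h5", "r") as f:
            consensus_maps = f["consensus/maps"][()]
        roi = np.load(self.out / "raw" / "roi_labels.npy")
        from .preprocess import bin_labels
        from .synthetic import make_roi_labels as _mk

        _, roi_names = _mk(c.fov_shape)
        ann = annotate_consensus(consensus_maps,
                                 bin_labels(roi, p.bin_factor), roi_names)
        frontal = resolve_frontal_ids(ann, dy.frontal_ids)

        # attach strategies from the behavior stage
        strategies = {}
        for mi in range(c.n_mice):
            for ti in range(c.trials_per_mouse):
                beh = json.loads(
                    (self.out / "behavior" / f"m{mi}_t{ti}.json").read_text())
                strategies[f"m{mi}_t{ti}"] = beh["strategy"]
        for ser in series:
            ser.strategy = strategies.get(ser.trial_id)

        n_states = self.config.clustering.n_consensus
        events = [detect_fsa(ser, frontal, search_window_s=dy.search_window_s,
                             min_duration_s=dy.min_duration_s,
                             max_jitter=dy.max_jitter) for ser in series]
        act = activation_probability(series, n_states)
        tm_all = transition_matrix(series, n_states)
        hist = peri_event_histogram(series, events, n_states,
                                    window_s=dy.window_s)
        hist = bootstrap_histogram(hist, series, events, n_states,
                                   n_boot=dy.n_boot,
                                   seed=stage_seed(self.config.seed, "dynamics"))
        hist = significance(hist, alpha=dy.alpha)

        act.to_csv(d / "activation.csv", index=False)
        mio.write_transition_csv(d / "transition_all.csv", tm_all)
        for strat in ("serial", "spatial"):
            sel = [s for s in series if s.strategy == strat]
            if sel:
                mio.write_transition_csv(
                    d / f"transition_{strat}.csv",
                    transition_matrix(sel, n_states, condition=strat))
        mio.write_events_json(
            d / "fsa_events.json",
            {ser.trial_id: ev for ser, ev in zip(series, events)})
        with h5py.File(d / "peri_event.h5", "w") as f:
            f.create_dataset("offsets", data=hist.offsets)
            f.create_dataset("p_obs", data=hist.p_obs)
            f.create_dataset("p_boot", data=hist.p_boot)
            f.create_dataset("significant_05", data=hist.significant_05)
            f.create_dataset("significant_01", data=hist.significant_01)
        mio.write_json(d / "annotation.json", {
            "names": ann.names, "frontal_ids": ann.frontal_ids})
        self._record("dynamics", [
            d / "activation.csv", d / "transition_all.csv",
            d / "fsa_events.json", d / "peri_event.h5", d / "annotation.json"])

    def _run_report(self) -> None:
        import h5py
        import pandas as pd

        from .plotting import plot_peri_event, plot_state_maps

        d = self.out
        act = pd.read_csv(d / "dynamics" / "activation.csv")
        events = json.loads((d / "dynamics" / "fsa_events.json").read_text())
        ann = json.loads((d / "dynamics" / "annotation.json").read_text())
        figs = d / "figures"
        figs.mkdir(exist_ok=True)
        with h5py.File(d / "states" / "models.h5", "r") as f:
            cmaps = f["consensus/maps"][()]
        mask = cmaps.std(axis=0) > 0
        plot_state_maps(cmaps, mask, names=ann["names"],
                        path=figs / "consensus_states.png")
        with h5py.File(d / "dynamics" / "peri_event.h5", "r") as f:
            plot_peri_event(f["offsets"][()], f["p_obs"][()],
                            significant=f["significant_05"][()],
                            fps=self.config.preprocessing.fps,
                            path=figs / "peri_event.png")
        lines = ["# mesostate pipeline report", ""]
        lines.append(f"Trials analysed: {len(act)}")
        lines.append(f"Consensus state names: {ann['names']}")
        lines.append(f"Frontal state ids: {ann['frontal_ids']}")
        lines.append("")
        lines.append("## Mean state activation probability")
        pcols = [c for c in act.columns if c.startswith("P")]
        for c in sorted(pcols):
            lines.append(f"- {c}: {act[c].mean():.3f} +/- {act[c].std():.3f}")
        lines.append("")
        lines.append("## FSA events per strategy")
        strat_counts: dict[str, list[int]] = {}
        for tid, ev in events.items():
            strat = act.loc[act.trial_id == tid, "strategy"]
            key = strat.iloc[0] if len(strat) else "unknown"
            strat_counts.setdefault(key, [0, 0])
            strat_counts[key][1] += 1
            if ev is not None:
                strat_counts[key][0] += 1
        for k, (n_ev, n_tot) in sorted(strat_counts.items()):
            lines.append(f"- {k}: {n_ev}/{n_tot} trials with an FSA event")
        out = d / "report.md"
        out.write_text("\n".join(lines) + "\n")
        self._record("report", [out])


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the pipeline; returns a stage -> {"ran","cached"} map."""
    return Pipeline(config).run(stages)
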