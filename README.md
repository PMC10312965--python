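# mesostate

Cortical activation-state analysis of mesoscale widefield calcium
imaging during Barnes-maze navigation.

When a head-mounted widefield miniscope records bulk GCaMP fluorescence
across most of dorsal cortex while a mouse searches a Barnes maze for
its escape hole, the movie is dominated by a handful of recurring
spatial activation patterns that switch on ~0.2–1 s timescales. This
package provides, for systems neuroscientists working with such
recordings, a tested end-to-end pipeline that:

- converts raw dual-illumination (blue calcium / green reference)
  stacks into masked, band-passed, z-scored ΔF/F movies;
- decomposes each mouse's movie into cortical activation **states**:
  every frame is Pearson-correlated with every other frame, k-means
  clusters the rows of the correlation matrix, and the number of states
  k is chosen by a **t-distance** criterion (per-cluster Welch t
  contrasting within- versus across-cluster correlations, maximised
  over k);
- merges the per-mouse states into a cross-mouse **consensus state
  space** by clustering the correlation matrix of the per-state mean
  activity maps, and names the consensus states (frontal, posterior,
  lateral, midline, …) from an ROI parcellation;
- classifies each trial's search strategy — *random*, *serial* or
  *spatial* — from nose/head/body tracking (DeepLabCut CSV dialect)
  using quadrant-coverage and hole-adjacency rules, plus primary
  latency/errors, radial zones, velocity, and the allocentric (ω) and
  egocentric (φ) goal-heading angles;
- detects the **frontal-state activation (FSA) event**: an episode
  longer than 1 s near trial start in which a frontal state is active,
  tolerating excursions of ≤ 4 frames into other states; and
- computes the state-sequence statistics around it: activation and
  transition probabilities, peri-event state probability histograms
  against a run-permutation bootstrap null with Bonferroni-corrected
  ANOVA significance, and heading-conditioned state probabilities
  compared between strategies by Wilcoxon rank-sum.

No public recording accompanies the analysis, so the package ships a
first-class synthetic generator (`mesostate.synthetic`) that emulates
the assumed data structure — template-switching movies with shared
illumination drift, archetypal search trajectories, planted frontal
dwells — with full ground truth, and a benchmark module
(`mesostate.evaluation`) that scores every stage against it.

## Worked example

Simulate a two-mouse cohort, preprocess it, recover its state space and
ask how often the FSA event occurs under each search strategy:

```python
import numpy as np
from mesostate import (SyntheticConfig, DffPreprocessor,
                       CorrelationStateClustering, ConsensusStates,
                       StateSeries, detect_fsa, activation_probability,
                       annotate_consensus)
from mesostate.synthetic import simulate_cohort, make_roi_labels
from mesostate.preprocess import bin_labels

config = SyntheticConfig(n_mice=2, trials_per_mouse=6,
                         trial_duration_s=30.0, seed=42)
cohort = simulate_cohort(config)

pre = DffPreprocessor()
movies = [[pre.transform(t.stack, cohort.mask) for t in mouse]
          for mouse in cohort.trials]

models = []
for mouse_movies in movies:
    est = CorrelationStateClustering(k_range=(2, 12), replicates=5,
                                     max_iter=300, stride=4, random_state=0)
    models.append(est.fit(mouse_movies))
print("states per mouse:", [m.k_ for m in models])

cons = ConsensusStates(n_consensus=7, replicates=20, random_state=0)
cons.fit(models, models[0].mask_)

roi_labels, roi_names = make_roi_labels(config.fov_shape)
ann = annotate_consensus(cons.consensus_maps_,
                         bin_labels(roi_labels, 0.8), roi_names)
print("consensus state names:", ann.names)
print("frontal ids:", ann.frontal_ids)

series = []
for mi, est in enumerate(models):
    labels = cons.relabel(mi, est.labels_)
    pos = 0
    for trial, movie in zip(cohort.trials[mi], movies[mi]):
        n = movie.n_frames
        series.append(StateSeries(states=labels[pos:pos + n], fps=15.0,
                                  trial_id=f"m{mi}t{trial.trial}",
                                  strategy=trial.strategy))
        pos += n

table = activation_probability(series, 7)
print("mean activation probability per state:",
      np.round([table[f"P{s}"].mean() for s in range(7)], 3))

for strat in ("random", "serial", "spatial"):
    sel = [s for s in series if s.strategy == strat]
    hits = sum(detect_fsa(s, ann.frontal_ids) is not None for s in sel)
    print(f"FSA events in {strat} trials: {hits}/{len(sel)}")
```

Output:

```
states per mouse: [7, 7]
consensus state names: ['posterior', 'lateral', 'frontal', 'midline', 'posterior', 'lateral', 'frontal']
frontal ids: [2, 6]
mean activation probability per state: [0.114 0.143 0.162 0.128 0.153 0.134 0.166]
FSA events in random trials: 1/4
FSA events in serial trials: 4/4
FSA events in spatial trials: 4/4
```

The t-distance criterion recovers the seven planted templates in both
mice; the consensus annotation identifies the two frontal-blob states
(here consensus ids 2 and 6); activation probability is spread across
states (11–17% each, none dominant); and the FSA event appears in every
serial and spatial trial — where the generator plants an early frontal
dwell — but in only a quarter of random trials, whose frontal episodes
arise by chance. That strategy dependence of early frontal activation
is the qualitative finding the pipeline is built to expose.

The same analysis runs from the shell, stage by stage with caching and
a reproducibility manifest:

```sh
mesostate all --seed 42 --output-dir out/
cat out/report.md
```

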