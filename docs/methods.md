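# Methods

`mesostate` reimplements, as a tested pipeline over synthetic data with
planted ground truth, an analysis of mesoscale widefield calcium imaging
recorded while mice navigate a Barnes maze: cortical activity is
decomposed into a small set of recurring activation *states* by
clustering the frame-by-frame image correlation matrix; tracking data
classifies each trial's search strategy; and the statistics of the state
sequence — in particular the prolonged frontal-state activation (FSA)
episode near trial start — are related to strategy, position and
heading. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic cohorts do and do not
establish.

## Preprocessing

Raw stacks interleave blue (calcium-dependent) and green (reference)
illumination frames at 30 FPS total (15 FPS per channel). The chain is
fixed-order: channel demultiplexing → optional motion-correction hook →
bilinear binning → cortex masking → global-illumination DF/F → temporal
band-pass → spatial smoothing → per-pixel z-score. Every stage is
mask-closed (out-of-mask pixels are exactly 0 throughout) and dropped
frames propagate as invalid slots so behavioural tables stay aligned.

- **Channel classification.** Two-cluster k-means on per-frame mean
  intensities; the brighter cluster is the calcium channel. Frames more
  than 4 cluster standard deviations from both centroids are dropped.
  Gross artifacts are trimmed by a robust median/MAD rule *before*
  clustering — an extreme outlier would otherwise capture a centroid of
  its own — and are then flagged by the 4-sd rule like any other
  unclassifiable frame.
- **Binning.** Each dimension is resampled to `round(0.8 × size)` pixels
  by bilinear interpolation in the pixel-centre convention
  (output centre *i* maps to input coordinate `(i+0.5)/f − 0.5`), so
  constant images are preserved exactly. "80%" is read per-dimension.
- **DF/F.** The exact published correction algorithm is not reprinted in
  the analysis protocol, so the simplest contract satisfying "corrected
  for global illumination fluctuations" is used: each blue frame is
  divided by its paired green frame's mean-normalised in-mask spatial
  mean (divisive drift correction), then converted per pixel to
  `(F − F0)/F0` with `F0` the pixel's trial mean. Multiplicative drift
  shared by the channels cancels to machine precision; whether the
  original correction was regression-based instead is unknowable from
  the protocol and is left as a swappable step.
- **Band-pass.** Chebyshev type-I, 0.1–5 Hz, applied forward–backward
  (zero-phase). Order 3 with 0.5 dB passband ripple: the order and
  ripple are unstated in the protocol, and order 3 is the choice that
  meets all the stated contracts with margin (≤0.1 dB at 1 Hz, >40 dB at
  0.01 Hz and 7 Hz after the double pass); order 4 at 0.5 dB ripple
  leaves only ~1 dB at the passband ripple trough and fails the 1 Hz
  contract on finite 60 s signals. Edge handling uses Gustafsson initial
  conditions, which make the operator exactly time-reversal symmetric
  (default padding does not), and each trace is demeaned first — DC is
  deep in the stopband, so this changes nothing in the ideal response
  but suppresses edge transients. Trials shorter than three filter
  settle lengths (81 frames) are passed through unfiltered with a flag.
- **Spatial smoothing.** "7-pixel nearest-neighbour average" is not a
  standard kernel; it is read as the pixel, its 4-neighbourhood, and the
  two first diagonals in (row, col) order — a deterministic choice that
  makes the per-pixel oracle test exact. Near the mask edge the average
  runs over the available in-mask subset. The 3×3-minus-corners
  alternative would differ only in which two diagonals enter.
- **Z-score.** Per pixel over valid frames, sample (n−1) standard
  deviation.

## State decomposition

Every valid frame's in-mask pixels are Pearson-correlated with every
other frame of the same mouse across trials. K-means (Lloyd, 500
restarts × 5000 iterations in the production configuration) clusters
the *rows* of this matrix — each frame's correlation profile — and the
number of clusters is chosen by t-distance over k = 2…15.

**t-distance.** For each cluster, a Welch t-statistic contrasts the
off-diagonal within-cluster correlations against the correlations
between that cluster's frames and all others. The published source for
the exact formula is not reprinted; this package combines the
per-cluster statistics as their **mean** (the sum normalised by the
number of clusters). The raw sum was tried first and cannot select a
cluster number here: carving a small splinter off a true cluster adds a
positive term with almost no penalty, so the sum plateaus or rises past
the true k (observed selections up to k = 15 on 7-template data); the
normalised form recovers the planted k across every mouse and seed
tried, and behaves identically on planted block matrices. Ties break to
the smaller k (parsimony). A perfectly separated, zero-variance
comparison contributes a capped sentinel (1e6); clusters with fewer than
2 members contribute 0 with a warning. K-means-optimised partitions of a
*structureless* matrix reach t ≈ 5 (random labels stay below 3, real
structure reaches hundreds), so fits with a peak below 10 are flagged
low-separation.

**Frame stride.** The correlation matrix and k-means may run on every
`stride`-th frame; the remaining frames are then assigned to the nearest
cluster centre in correlation-profile space (profiles taken against the
strided frame set). `stride=1` reproduces the monolithic computation
exactly; frames within a state are exchangeable under the generative
model, so subsampling costs statistical efficiency, not correctness.
The matrix can also be computed in row blocks with bit-identical
results.

**Consensus space.** Per-mouse states are averaged into mean activity
maps; all mice's maps are correlated into a second matrix (51×51 in the
original cohort of 8 mice) and k-means-clustered into 7 consensus
states. Every (mouse, state) pair maps to exactly one consensus id, and
per-trial frame labels are relabelled through that map. Consensus ids
are arbitrary; anatomical names (frontal, posterior, lateral, midline,
hemispheric) are attached *after* clustering by comparing each consensus
map's mean z-score per ROI against a parcellation, with ambiguous maps
left unassigned. The frontal-named ids feed the FSA detector when set to
"auto".

## Behaviour

Tracking (nose/head/body, DeepLabCut CSV dialect, likelihood < 0.9 →
invalid frame) is aligned 1:1 with calcium frames.

- **Hole visits** open when the nose stays inside a hole disc ≥ 2
  consecutive frames; same-hole visits separated by < 0.5 s merge.
- **Strategy.** Quadrants are four 90° sectors anchored so the
  centre-to-goal ray bisects one sector, making the rules invariant to
  maze rotation; frames inside the central circle carry no sector. Rules
  are evaluated most-specific-first on the primary phase (up to the
  first goal visit): *spatial* — at most one sector traversed and every
  pre-goal visit at a hole immediately adjacent to the goal; *serial* —
  at most two sectors, all sector changes between adjacent sectors, and
  at least three consecutive holes covered on one side of the goal (the
  one-side reading of "on either end"); *random* — three or more
  sectors crossed with a non-adjacent transition; anything else falls
  back to random. Repeat visits to the same wrong hole count as separate
  primary errors.
- **Zones.** central: within half a mouse length (30 px) of the centre;
  serial exploration: within one mouse length (60 px) of the edge;
  approach: between.
- **Heading.** ω is the signed angle from the fixed centre→goal vector
  to the body→head vector; φ the signed angle from the instantaneous
  body→goal vector to the body→head vector; both in (−180°, 180°], NaN
  when body and head coincide.
- **Velocity.** Central differences of the body point, converted to
  cm/s, smoothed with a 5-frame (~333 ms) boxcar; the window is a
  configuration parameter, chosen for a stable peak-velocity statistic.
- **Primary latency** runs from the first tracked frame (whether the
  original clock started at cylinder removal is unstated) to the first
  goal-visit opening.

## State dynamics

- **Activation probability** per trial is the fraction of valid frames
  (optionally under a zone/heading/window condition) in each state;
  conditioned-empty trials are excluded and logged.
- **Transitions** are counted at state changes only (self-transitions
  excluded — dwell would dominate the diagonal otherwise; a
  frame-to-frame variant sits behind `include_self`). Runs interrupted
  by invalid frames do not create a transition; rows without departures
  stay zero and are flagged.
- **FSA detection.** An episode is a maximal run of frontal-state frames
  in which every excursion into other states lasts ≤ 4 consecutive
  frames (the per-excursion reading of the jitter rule; a total-budget
  variant would be stricter). It qualifies when its total span exceeds
  1 s (> 15 frames at 15 FPS), and the first qualifying episode with
  onset inside a 10 s search window ("near the start of the trial";
  configurable) is the trial's event. A brute-force reference detector
  (`detect_fsa_reference`) walks every admissible span explicitly and is
  used as the equivalence oracle.
- **Peri-event histograms** align all trials' state indicators to event
  onset or end over a ±3 s window (single-frame bins); bins with fewer
  than 3 contributing trials are masked.
- **Bootstrap null.** Each replicate permutes the order of each trial's
  dwell runs, conserving per-state frame counts and the dwell-length
  multiset exactly while destroying event-aligned timing — the weakest
  null consistent with "bootstrapping the time series of states" (a
  circular-shift alternative would preserve ordering as well).
- **Significance.** Per state × time bin, a one-way ANOVA compares the
  observed per-trial indicators against the pooled bootstrap indicators,
  Bonferroni-corrected over all tested cells, with two tiers (0.05,
  0.01). The denominator degrees of freedom are capped at one less than
  the smaller group: the indicators are binary and the observed group is
  small, so the nominal F tail (df in the thousands from the pooled
  bootstrap) understates the binomial right tail exactly where the
  Bonferroni threshold lives — measured family-wise error 0.18 under the
  null, versus 0.04 with the cap, at no measurable cost in power against
  a planted enrichment.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the biophysics. Defaults are the study conditions used throughout
the tests.

- **Movies.** A library of `n_states = 7` Gaussian-blob templates
  (frontal pair, midline, lateral pair, posterior pair — echoing the
  recurring motifs; pairwise correlation < 0.3 by disjoint centres)
  switches under a semi-Markov process: dwell ~ Uniform(0.2–1.0 s) (the
  reported switching timescale), next state uniform excluding the
  current one. Blue frames are baseline × (1 + 0.15 × template) ×
  drift + noise; green frames carry the same slow multiplicative drift
  (±2%, 30 s period) and noise but no signal — exactly the structure the
  divisive DF/F correction assumes. Quantisation to uint16 counts.
  `pixel_noise_sd = 0.045` (relative to baseline) was calibrated once so
  that within-state frame correlations after preprocessing sit near 0.6;
  the in-vivo within-state correlation level is not reported, so this is
  a package choice, tunable in `SyntheticConfig`.
- **Planted events.** Serial and spatial trials receive a frontal dwell
  of 1.2–2.2 s starting within the first 5 s (mirroring the prevalence
  of early frontal activation in non-random searches); random trials
  rely on chance frontal episodes, which the dwell process produces at a
  lower rate. The per-trial ground-truth event list is computed by the
  detector's own definition on the true labels, so planted events
  satisfy it exactly.
- **Trajectories** are waypoint walks at 18 cm/s with ~1 px positional
  jitter, emitted at 15 FPS 1:1 with blue frames, starting inside the
  central circle: spatial — direct goal approach (optionally one
  adjacent-hole check); serial — centre → edge, then 3–5 consecutive
  perimeter holes into the goal; random — three scattered holes across
  non-goal sectors in a non-sequential order, then the goal. The mouse
  body is 60 px (10 cm at 6 px/cm on a 600 px maze); head and nose lie
  along the heading with the head between body and nose.
- **What the synthetic cohorts do not show.** No GCaMP kinetics,
  hemodynamic contamination, motion artifacts, cross-mouse anatomical
  variability, or realistic pose-estimation noise. Passing recovery
  tests therefore demonstrates that the pipeline's inference is correct
  when its assumptions hold, not that those assumptions hold in vivo,
  and the published in-vivo percentages are not reproduction targets —
  only directional relationships (e.g. FSA more frequent in serial and
  spatial than in random trials) are asserted.

## Problem sizes and defaults

Production defaults follow the published protocol (k-means 500
replicates × 5000 iterations, k = 2…15, 7 consensus states, 100
bootstraps, ±3 s windows). The recovery benchmarks run the same code at
desk scale as their own configuration: 3 mice × 6 trials × 60 s at
64×64 FOV, frame stride 6, 5–10 k-means restarts, 20-seed block-matrix
and 100-repeat calibration studies. With well-separated planted
structure the restart count does not change the optima found; the full
benchmark suite completes in a few minutes on one CPU.

## Known limitations

- The t-distance normalisation and the DF/F correction are explicit
  package choices standing in for formulas the protocol references but
  does not reprint; both are isolated behind single functions.
- The strategy rules are not provably exhaustive as written; the random
  fallback makes the classifier total, and the `strategy_rule_matched`
  flag records when the fallback fired.
- Cross-mouse consensus assumes a shared pixel grid (true for synthetic
  cohorts); registering real mice to a common atlas is out of scope.
- The FSA search window, jitter rule variant, and bootstrap scheme are
  configurable; results in the report are sensitive to these choices
  and the manifest records them.
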