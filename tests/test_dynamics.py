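"""State-sequence statistics: probabilities, transitions, FSA, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesostate.dynamics import (FsaEvent, StateSeries, activation_probability,
                                bootstrap_histogram, bootstrap_null,
                                detect_fsa, detect_fsa_reference,
                                heading_conditioned_probability,
                                peri_event_histogram, permute_runs,
                                significance, transition_matrix)

F = [0, 1]   # frontal ids used throughout


def _ser(states, strategy=None, trial_id="t"):
    return StateSeries(states=np.asarray(states), fps=15.0,
                       trial_id=trial_id, strategy=strategy)


class TestActivationProbability:
    def test_half_and_half(self):
        tab = activation_probability([_ser([3] * 10 + [6] * 10)], 7)
        row = tab.iloc[0]
        assert row["P3"] == 0.5 and row["P6"] == 0.5
        assert sum(row[f"P{s}"] for s in range(7)) == pytest.approx(1.0)

    def test_empty_condition_excludes_trial(self):
        masks = [np.zeros(10, dtype=bool)]
        tab = activation_probability([_ser([1] * 10)], 7, condition_masks=masks)
        assert len(tab) == 0

    def test_matches_counting_oracle(self, rng):
        series = [_ser(rng.integers(7, size=60), trial_id=str(i))
                  for i in range(8)]
        tab = activation_probability(series, 7)
        for i, ser in enumerate(series):
            for s in range(7):
                expect = np.sum(ser.states == s) / 60
                assert tab.iloc[i][f"P{s}"] == pytest.approx(expect, abs=1e-12)

    def test_invalid_frames_excluded(self):
        tab = activation_probability([_ser([2, 2, -1, -1, 5])], 7)
        assert tab.iloc[0]["P2"] == pytest.approx(2 / 3)
        assert tab.iloc[0]["P5"] == pytest.approx(1 / 3)


class TestTransitionMatrix:
    def test_constant_series_all_zero_flagged(self):
        tm = transition_matrix([_ser([1, 1, 1, 1])], 7)
        assert tm.counts.sum() == 0
        assert tm.zero_rows.all()

    def test_alternation(self):
        tm = transition_matrix([_ser([1, 2, 1, 2, 1])], 7)
        assert tm.probabilities[1, 2] == 1.0
        assert tm.probabilities[2, 1] == 1.0

    def test_matches_pairwise_loop_oracle(self, rng):
        series = [_ser(rng.integers(5, size=40)) for _ in range(10)]
        tm = transition_matrix(series, 5)
        counts = np.zeros((5, 5), dtype=int)
        for ser in series:
            s = ser.states
            for a, b in zip(s[:-1], s[1:]):
                if a != b:
                    counts[a, b] += 1
        assert np.array_equal(tm.counts, counts)

    def test_invalid_frames_break_runs(self):
        tm = transition_matrix([_ser([1, -1, 2])], 7)
        assert tm.counts.sum() == 0   # no transition across the gap

    def test_include_self_variant_counts_dwells(self):
        tm = transition_matrix([_ser([1, 1, 2])], 7, include_self=True)
        assert tm.counts[1, 1] == 1 and tm.counts[1, 2] == 1

    def test_rows_sum_to_one_or_flagged(self, rng):
        tm = transition_matrix([_ser(rng.integers(7, size=300))], 7)
        sums = tm.probabilities.sum(axis=1)
        ok = ~tm.zero_rows
        assert np.allclose(sums[ok], 1.0, atol=1e-12)
        assert np.all(sums[~ok] == 0.0)


class TestDetectFsa:
    def test_long_run_detected(self):
        ev = detect_fsa(_ser([1] * 20 + [5] * 10), F)
        assert (ev.onset_frame, ev.end_frame) == (0, 19)
        assert ev.jitter_frames_used == 0
        assert ev.duration_s > 1.0

    def test_short_run_rejected(self):
        assert detect_fsa(_ser([1] * 10 + [5] * 20), F) is None

    def test_excursion_bridged(self):
        # one frontal state, a 3-frame excursion, then the other frontal state
        ev = detect_fsa(_ser([1] * 10 + [5] * 3 + [0] * 10 + [6] * 5), F)
        assert (ev.onset_frame, ev.end_frame) == (0, 22)
        assert ev.jitter_frames_used == 3

    def test_five_frame_excursion_splits(self):
        states = [1] * 10 + [5] * 5 + [2] * 10
        assert detect_fsa(_ser(states), F) is None   # both halves <= 15 frames

    def test_onset_outside_window_ignored(self):
        states = [5] * 200 + [1] * 30
        assert detect_fsa(_ser(states), F, search_window_s=10.0) is None
        ev = detect_fsa(_ser(states), F, search_window_s=20.0)
        assert ev.onset_frame == 200

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(300):
            states = rng.integers(7, size=150)
            ev = detect_fsa(_ser(states), F)
            ref = detect_fsa_reference(states, F)
            got = None if ev is None else (ev.onset_frame, ev.end_frame)
            assert got == ref

    def test_empty_frontal_ids_rejected(self):
        with pytest.raises(ValueError):
            detect_fsa(_ser([1] * 30), [])


class TestBootstrap:
    def test_single_run_invariant(self, rng):
        out = permute_runs(np.array([3, 3, 3]), rng)
        assert np.array_equal(out, [3, 3, 3])

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=120),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conserves_per_state_frame_counts(self, states, seed):
        states = np.asarray(states)
        out = permute_runs(states, np.random.default_rng(seed))
        assert np.array_equal(np.bincount(states, minlength=5),
                              np.bincount(out, minlength=5))

    def test_every_replicate_conserves_per_state_counts(self, rng):
        series = [_ser(rng.integers(7, size=100), trial_id=str(i))
                  for i in range(5)]
        for rep in bootstrap_null(series, n_boot=20, seed=3):
            for ser, perm in zip(series, rep):
                assert np.array_equal(np.bincount(ser.states, minlength=7),
                                      np.bincount(perm, minlength=7))


class TestPeriEvent:
    def test_known_offset_probability(self):
        series = [_ser([5] * 10 + [1] * 30, trial_id=str(i)) for i in range(4)]
        events = [detect_fsa(s, F) for s in series]
        hist = peri_event_histogram(series, events, 7, window_s=(-0.5, 0.5))
        b = np.flatnonzero(hist.offsets == -3)[0]
        assert hist.p_obs[5, b] == 1.0

    def test_probabilities_partition(self, rng):
        series = [_ser(rng.integers(7, size=120), trial_id=str(i))
                  for i in range(6)]
        events = [FsaEvent(onset_frame=60, end_frame=80) for _ in series]
        hist = peri_event_histogram(series, events, 7)
        sums = np.nansum(hist.p_obs, axis=0)
        assert np.allclose(sums[hist.bin_mask], 1.0, atol=1e-12)

    def test_hand_computed_five_trial_fixture(self):
        # offset -1: states (2, 2, 3, 3, 3) -> P2=0.4, P3=0.6
        base = [[2, 1, 1], [2, 1, 1], [3, 1, 1], [3, 1, 1], [3, 1, 1]]
        series = [_ser([0] * 5 + b + [1] * 20, trial_id=str(i))
                  for i, b in enumerate(base)]
        events = [FsaEvent(onset_frame=6, end_frame=27) for _ in series]
        hist = peri_event_histogram(series, events, 7, window_s=(-0.2, 0.2))
        b = np.flatnonzero(hist.offsets == -1)[0]
        assert hist.p_obs[2, b] == pytest.approx(0.4)
        assert hist.p_obs[3, b] == pytest.approx(0.6)

    def test_sparse_bins_masked(self):
        series = [_ser([1] * 40, trial_id="a"), _ser([1] * 40, trial_id="b")]
        events = [detect_fsa(s, F) for s in series]
        hist = peri_event_histogram(series, events, 7, min_trials=3)
        assert not hist.bin_mask.any()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            peri_event_histogram([_ser([5] * 20)], [None], 7)


class TestSignificance:
    def test_no_difference_nothing_significant(self):
        # observed == every bootstrap (single-run trials are permutation
        # invariant), so the ANOVA must flag nothing
        series = [_ser([s % 7] * 60, trial_id=str(s)) for s in range(6)]
        events = [FsaEvent(onset_frame=30, end_frame=45) for _ in series]
        hist = peri_event_histogram(series, events, 7, window_s=(-1, 1))
        hist = bootstrap_histogram(hist, series, events, 7, n_boot=10, seed=0)
        hist = significance(hist)
        assert not hist.significant_05.any()

    def test_requires_bootstrap_first(self):
        series = [_ser([1] * 40, trial_id=str(i)) for i in range(4)]
        events = [detect_fsa(s, F) for s in series]
        hist = peri_event_histogram(series, events, 7)
        with pytest.raises(ValueError, match="bootstrap"):
            significance(hist)

    def test_strict_tier_is_subset(self, rng):
        series = [_ser(rng.integers(7, size=200), trial_id=str(i))
                  for i in range(8)]
        events = [FsaEvent(onset_frame=100, end_frame=120) for _ in series]
        hist = peri_event_histogram(series, events, 7)
        hist = bootstrap_histogram(hist, series, events, 7, n_boot=30, seed=1)
        hist = significance(hist)
        assert np.all(hist.significant_05 | ~hist.significant_01)


class TestHeadingConditioned:
    def test_always_oriented_single_state(self):
        ser = _ser([3] * 30 + [1] * 30, strategy="spatial")
        ev = detect_fsa(ser, F)
        table, _ = heading_conditioned_probability(
            [ser], [np.zeros(60)], [ev], 7)
        assert table.iloc[0]["P3"] == 1.0

    def test_vacuous_threshold_reduces_to_unconditioned(self, rng):
        states = rng.integers(2, 7, size=60).tolist() + [1] * 30
        ser = _ser(states, strategy="serial")
        ev = detect_fsa(ser, F)
        angles = [rng.uniform(-179, 179, size=90)]
        table, _ = heading_conditioned_probability([ser], angles, [ev], 7,
                                                   threshold_deg=180.0)
        pre = np.asarray(states[:ev.onset_frame])
        for s in range(7):
            assert table.iloc[0][f"P{s}"] == pytest.approx(
                np.mean(pre == s), abs=1e-12)

    def test_planted_spatial_enrichment_detected_by_ranksum(self, rng):
        series, angles, events = [], [], []
        for i in range(12):
            strategy = "spatial" if i % 2 else "serial"
            pre = rng.integers(2, 7, size=90)
            ang = rng.uniform(-170, 170, size=120)
            if strategy == "spatial":
                oriented = np.abs(ang[:90]) < 45
                pre[oriented] = 3      # state 3 only while goal-oriented
            ser = _ser(pre.tolist() + [1] * 30, strategy=strategy,
                       trial_id=str(i))
            series.append(ser)
            angles.append(ang)
            events.append(detect_fsa(ser, F))
        _table, stats_tab = heading_conditioned_probability(
            series, angles, events, 7)
        row = stats_tab[stats_tab.state == 3].iloc[0]
        assert row["mean_spatial"] > row["mean_serial"]
        assert row["p"] < 0.05
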