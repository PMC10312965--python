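"""Frame-correlation clustering, t-distance selection, consensus space."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mesostate.preprocess import DffMovie
from mesostate.states import (ConsensusStates, CorrelationStateClustering,
                              T_DISTANCE_CAP, cluster_correlation,
                              frame_correlation_matrix, select_k, t_distance)


def _movie_from_frames(frames, mask=None):
    frames = np.asarray(frames, dtype=float)
    if mask is None:
        mask = np.ones(frames.shape[1:], dtype=bool)
    return DffMovie(data=frames, mask=mask,
                    valid=np.ones(frames.shape[0], dtype=bool), fps=15.0)


def _block_matrix(rng, n_blocks=3, block=30, within=0.9, across=0.0, sd=0.05):
    N = n_blocks * block
    lab = np.repeat(np.arange(n_blocks), block)
    C = np.where(lab[:, None] == lab[None, :], within, across).astype(float)
    noise = rng.normal(0, sd, (N, N))
    C += (noise + noise.T) / np.sqrt(2)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1, 1), lab


class TestCorrelationMatrix:
    def test_self_and_negation(self, rng):
        f = rng.normal(size=(1, 6, 6))
        movie = _movie_from_frames(np.concatenate([f, -f]))
        C = frame_correlation_matrix(movie)
        assert C.values[0, 0] == pytest.approx(1.0)
        assert C.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self, rng):
        frames = rng.normal(size=(50, 5, 5))
        C = frame_correlation_matrix(_movie_from_frames(frames)).values
        X = frames.reshape(50, -1)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert C[i, j] == pytest.approx(r, abs=1e-10)

    def test_blocked_computation_bit_identical(self, rng):
        frames = rng.normal(size=(40, 6, 6))
        movie = _movie_from_frames(frames)
        a = frame_correlation_matrix(movie).values
        b = frame_correlation_matrix(movie, block_rows=7).values
        assert np.array_equal(a, b)

    def test_scale_freedom(self, rng):
        frames = rng.normal(size=(30, 6, 6))
        a = frame_correlation_matrix(_movie_from_frames(frames)).values
        b = frame_correlation_matrix(_movie_from_frames(frames * 2.0)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_variance_frame_rejected(self, rng):
        frames = rng.normal(size=(10, 4, 4))
        frames[3] = 5.0
        with pytest.raises(ValueError, match="row 3"):
            frame_correlation_matrix(_movie_from_frames(frames))

    def test_mask_mismatch_rejected(self, rng):
        m1 = _movie_from_frames(rng.normal(size=(5, 4, 4)))
        mask2 = np.ones((4, 4), dtype=bool)
        mask2[0, 0] = False
        m2 = _movie_from_frames(rng.normal(size=(5, 4, 4)), mask2)
        with pytest.raises(ValueError, match="mask"):
            frame_correlation_matrix([m1, m2])


class TestClusterCorrelation:
    def test_perfect_blocks_recovered(self, rng):
        C, lab = _block_matrix(rng, n_blocks=2, within=0.9, sd=0.0)
        got, _ = cluster_correlation(C, 2, seed=0, replicates=5, max_iter=100)
        assert adjusted_rand_score(lab, got) == 1.0

    def test_k_equals_n_each_frame_alone(self, rng):
        C, _ = _block_matrix(rng, n_blocks=2, block=4, sd=0.01)
        got, _ = cluster_correlation(C, 8, seed=0, replicates=5, max_iter=100)
        assert np.unique(got).size == 8

    def test_noisy_three_blocks_ari(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            C, lab = _block_matrix(rng)
            got, _ = cluster_correlation(C, 3, seed=seed, replicates=10,
                                         max_iter=300)
            hits += adjusted_rand_score(lab, got) == 1.0
        assert hits >= 19

    def test_fixed_seed_reproducible(self, rng):
        C, _ = _block_matrix(rng)
        a, _ = cluster_correlation(C, 3, seed=5, replicates=5, max_iter=100)
        b, _ = cluster_correlation(C, 3, seed=5, replicates=5, max_iter=100)
        assert np.array_equal(a, b)


class TestTDistance:
    def test_perfect_separation_capped(self):
        C, lab = _block_matrix(np.random.default_rng(0), n_blocks=2,
                               within=0.9, across=0.0, sd=0.0)
        td = t_distance(C, lab)
        assert td == pytest.approx(T_DISTANCE_CAP)

    def test_random_labels_on_structureless_matrix_near_zero(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.05, (40, 40))
            C = (noise + noise.T) / np.sqrt(2)
            np.fill_diagonal(C, 1.0)
            vals.append(t_distance(C, rng.integers(3, size=40)))
        assert np.max(np.abs(vals)) < 3.0

    def test_true_partition_beats_merged(self, rng):
        C, lab = _block_matrix(rng)
        merged = np.where(lab == 2, 1, lab)
        assert t_distance(C, lab) > t_distance(C, merged)

    def test_tiny_cluster_contributes_zero_with_warning(self, rng):
        C, lab = _block_matrix(rng, n_blocks=2, block=10, sd=0.01)
        lab = lab.copy()
        lab[0] = 2     # singleton cluster
        with pytest.warns(UserWarning, match="< 2 members"):
            t_distance(C, lab)


class TestSelectK:
    def test_three_blocks_selects_three(self, rng):
        C, _ = _block_matrix(rng)
        k, _, curve = select_k(C, k_range=(2, 8), seed=0, replicates=10,
                               max_iter=300)
        assert k == 3
        assert curve[3] > curve[2]

    def test_homogeneous_matrix_falls_back_to_smallest_k(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, (60, 60))
        C = (noise + noise.T) / np.sqrt(2)
        np.fill_diagonal(C, 1.0)
        k, _, curve = select_k(C, k_range=(2, 5), seed=0, replicates=5,
                               max_iter=100)
        assert k == 2                       # tie rule: smallest k wins
        from mesostate.states import LOW_SEPARATION_T
        assert max(curve.values()) < LOW_SEPARATION_T


class TestEstimator:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort):
        from mesostate.evaluation import preprocess_cohort

        movies = preprocess_cohort(small_cohort)
        models = []
        for mi in range(small_cohort.config.n_mice):
            est = CorrelationStateClustering(k=7, replicates=3, max_iter=200,
                                             stride=4, random_state=0)
            models.append(est.fit(movies[mi]))
        return small_cohort, movies, models

    def test_mean_maps_reconstruction(self, fitted):
        cohort, movies, models = fitted
        est = models[0]
        X = np.concatenate([m.data[:, est.mask_] for m in movies[0]])
        for c in range(est.k_):
            recon = X[est.labels_ == c].mean(axis=0)
            assert np.allclose(recon, est.mean_maps_[c][est.mask_], atol=1e-9)

    def test_fit_deterministic(self, fitted):
        cohort, movies, _ = fitted
        a = CorrelationStateClustering(k=7, replicates=3, max_iter=200,
                                       stride=4, random_state=0).fit(movies[0])
        b = CorrelationStateClustering(k=7, replicates=3, max_iter=200,
                                       stride=4, random_state=0).fit(movies[0])
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.mean_maps_, b.mean_maps_)

    def test_stride_one_matches_direct_kmeans_labels(self, small_cohort):
        from mesostate.evaluation import preprocess_cohort

        movies = preprocess_cohort(small_cohort)[0][:1]
        est = CorrelationStateClustering(k=5, replicates=3, max_iter=200,
                                         stride=1, random_state=0).fit(movies)
        C = frame_correlation_matrix(movies)
        direct, _ = cluster_correlation(C, 5, seed=0, replicates=3, max_iter=200)
        assert np.array_equal(est.labels_, direct)

    def test_get_set_params_roundtrip(self):
        est = CorrelationStateClustering()
        p = est.get_params()
        est.set_params(**p)
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_scale_freedom_of_labels(self, fitted):
        cohort, movies, models = fitted
        doubled = [DffMovie(data=m.data * 2, mask=m.mask, valid=m.valid,
                            fps=m.fps) for m in movies[0]]
        est = CorrelationStateClustering(k=7, replicates=3, max_iter=200,
                                         stride=4, random_state=0).fit(doubled)
        assert np.array_equal(est.labels_, models[0].labels_)
        assert est.tdist_curve_ == models[0].tdist_curve_


class TestConsensus:
    def _models_from_maps(self, maps_list, mask):
        class _M:
            def __init__(self, maps):
                self.mean_maps_ = maps
        return [_M(m) for m in maps_list]

    def test_identical_maps_cluster_one_per_mouse(self, templates7, rng):
        tpl, mask = templates7
        noisy = [tpl + rng.normal(0, 1e-3, tpl.shape) * mask for _ in range(3)]
        models = self._models_from_maps(noisy, mask)
        cons = ConsensusStates(n_consensus=7, replicates=10,
                               random_state=0).fit(models, mask)
        lab = cons.map_labels_.reshape(3, 7)
        for c in range(7):
            counts = (lab == c).sum(axis=1)
            assert np.all(counts == 1)   # one state from every mouse

    def test_missing_template_leaves_group_of_two(self, templates7, rng):
        tpl, mask = templates7
        full = tpl + rng.normal(0, 1e-3, tpl.shape) * mask
        partial = tpl[:6] + rng.normal(0, 1e-3, tpl[:6].shape) * mask
        models = self._models_from_maps([full, full, partial], mask)
        cons = ConsensusStates(n_consensus=7, replicates=10,
                               random_state=0).fit(models, mask)
        sizes = sorted(np.bincount(cons.map_labels_, minlength=7))
        assert sizes == [2, 3, 3, 3, 3, 3, 3]

    def test_too_few_maps_rejected(self, templates7):
        tpl, mask = templates7
        models = self._models_from_maps([tpl[:3]], mask)
        with pytest.raises(ValueError, match="consensus"):
            ConsensusStates(n_consensus=7).fit(models, mask)

    def test_relabel_recovers_planted_labels_up_to_permutation(self, small_cohort):
        from mesostate.evaluation import preprocess_cohort

        movies = preprocess_cohort(small_cohort)
        models = [CorrelationStateClustering(k=7, replicates=3, max_iter=200,
                                             stride=4, random_state=0).fit(m)
                  for m in movies]
        cons = ConsensusStates(n_consensus=7, replicates=10,
                               random_state=0).fit(models, models[0].mask_)
        for mi, est in enumerate(models):
            lab = cons.relabel(mi, est.labels_)
            truth = np.concatenate(
                [t.truth.frame_labels for t in small_cohort.trials[mi]])
            assert adjusted_rand_score(truth, lab) >= 0.8
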