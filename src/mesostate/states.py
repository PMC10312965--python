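"""Cortical activation states by frame-correlation clustering.

Within one mouse, every z-scored DF/F frame is Pearson-correlated with
every other frame recorded across that mouse's trials; k-means on the
rows of this correlation matrix (each frame's correlation profile)
groups frames into recurring spatial activation patterns, and a
t-distance criterion — summed Welch t-statistics contrasting
within-cluster against across-cluster correlations — selects the number
of states. Averaging frames per state gives per-mouse mean activity
maps; correlating all mice's mean maps and k-means-clustering that
second matrix into a fixed number of consensus states yields a common
state space, through which every frame of every mouse is relabelled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import DffMovie

logger = logging.getLogger(__name__)

T_DISTANCE_CAP = 1e6     # sentinel for zero-variance (perfectly separated) clusters
# k-means *optimised* partitions of a structureless matrix reach t ~ 5 (vs
# |t| < 3 for random labels and hundreds for genuinely clustered data), so
# the low-separation flag trips below 10
LOW_SEPARATION_T = 10.0


@dataclass
class CorrelationMatrix:
    """All-frames Pearson correlation matrix with frame provenance."""

    values: np.ndarray                       # (N, N)
    frame_index: list[tuple[int, int]]       # row -> (trial, frame)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")


@dataclass
class StateModel:
    """Per-mouse decomposition: labels, mean maps, model-selection curve."""

    k: int
    labels: np.ndarray                       # per-frame state id (valid frames)
    frame_index: list[tuple[int, int]]
    mean_maps: np.ndarray                    # (k, H, W)
    tdist_curve: dict[int, float]
    low_separation: bool = False


@dataclass
class ConsensusModel:
    """Cross-mouse state space and the per-mouse-state -> consensus map."""

    n_consensus: int
    consensus_maps: np.ndarray               # (n_consensus, H, W)
    mouse_state_map: dict[tuple[int, int], int]
    map_labels: np.ndarray                   # consensus id of each input map


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Rows to zero mean, unit population sd (Pearson normalisation)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero-variance frame at row {int(bad[0])}")
    return (X - mu) / sd


def _stack_valid_frames(
    movies: list[DffMovie],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    mask = movies[0].mask
    for m in movies[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("all movies must share one cortex mask")
    X, index = [], []
    for t, m in enumerate(movies):
        vf = np.flatnonzero(m.valid)
        X.append(m.data[vf][:, mask])
        index.extend((t, int(f)) for f in vf)
    return np.concatenate(X, axis=0), index


def frame_correlation_matrix(
    movies: list[DffMovie] | DffMovie,
    block_rows: int | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of every valid frame with every other.

    Only in-mask pixels enter the correlation. ``block_rows`` computes the
    matrix in row blocks (identical result, bounded memory).
    """
    if isinstance(movies, DffMovie):
        movies = [movies]
    X, index = _stack_valid_frames(movies)
    Z = _standardize_rows(X.astype(float))
    P = Z.shape[1]
    N = Z.shape[0]
    if block_rows is None:
        C = (Z @ Z.T) / P
    else:
        C = np.empty((N, N), dtype=float)
        for s in range(0, N, block_rows):
            e = min(s + block_rows, N)
            C[s:e] = (Z[s:e] @ Z.T) / P
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return CorrelationMatrix(values=C, frame_index=index)


def cross_correlation_profiles(
    movies: list[DffMovie],
    reference: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Correlation of every valid frame against a reference frame set.

    ``reference`` is (n_ref, P) of already-extracted in-mask pixel vectors;
    returns (N, n_ref). Used to place unclustered frames into correlation-
    profile space.
    """
    X, _ = _stack_valid_frames(movies)
    Zx = _standardize_rows(X.astype(float))
    Zr = _standardize_rows(reference.astype(float))
    return (Zx @ Zr.T) / Zx.shape[1]


# ---------------------------------------------------------------------------
# clustering and model selection
# ---------------------------------------------------------------------------

def cluster_correlation(
    matrix: CorrelationMatrix | np.ndarray,
    k: int,
    seed: int | None = 0,
    replicates: int = 500,
    max_iter: int = 5000,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means on the rows (correlation profiles) of the matrix.

    ``replicates`` random restarts of at most ``max_iter`` Lloyd
    iterations each; the labelling with the best within-cluster sum of
    squares is kept. Returns (labels, cluster centers).
    """
    C = matrix.values if isinstance(matrix, CorrelationMatrix) else np.asarray(matrix)
    N = C.shape[0]
    if not 2 <= k <= N:
        raise ValueError(f"k={k} out of range for {N} frames")
    km = KMeans(n_clusters=k, n_init=replicates, max_iter=max_iter,
                random_state=seed, algorithm="lloyd").fit(C)
    counts = np.bincount(km.labels_, minlength=k)
    if np.any(counts == 0):
        raise RuntimeError("empty cluster after convergence")
    return km.labels_, km.cluster_centers_


def t_distance(
    matrix: CorrelationMatrix | np.ndarray,
    labels: np.ndarray,
    aggregate: str = "mean",
) -> float:
    """Cumulative t-distance of a partition of the correlation matrix.

    For each cluster, a Welch t-statistic compares the off-diagonal
    within-cluster correlations against the correlations between that
    cluster's frames and all other frames. The per-cluster statistics are
    combined into one separation score; the default normalises the sum by
    the number of clusters (the per-cluster mean), which penalises
    partitions that carve off small splinter clusters — an unnormalised
    raw sum (``aggregate="sum"``) grows almost monotonically with k and
    cannot select a cluster number. Higher means better separated.
    Degenerate (zero-variance) comparisons contribute a capped sentinel;
    clusters with fewer than 2 members contribute 0 with a warning.
    """
    C = matrix.values if isinstance(matrix, CorrelationMatrix) else np.asarray(matrix)
    labels = np.asarray(labels)
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    total = 0.0
    for c in np.unique(labels):
        inside = labels == c
        n_in = int(inside.sum())
        if n_in < 2:
            warnings.warn(f"cluster {c} has < 2 members; contributes 0",
                          stacklevel=2)
            continue
        sub = C[np.ix_(inside, inside)]
        within = sub[np.triu_indices(n_in, k=1)]
        across = C[np.ix_(inside, ~inside)].ravel()
        if across.size == 0:
            continue
        vw = within.var(ddof=1) if within.size > 1 else 0.0
        va = across.var(ddof=1) if across.size > 1 else 0.0
        denom = vw / within.size + va / across.size
        diff = within.mean() - across.mean()
        if denom == 0:
            t = np.sign(diff) * T_DISTANCE_CAP if diff != 0 else 0.0
        else:
            t = np.clip(diff / np.sqrt(denom), -T_DISTANCE_CAP, T_DISTANCE_CAP)
        total += float(t)
    if aggregate == "mean":
        total /= np.unique(labels).size
    return total


def select_k(
    matrix: CorrelationMatrix | np.ndarray,
    k_range: range | tuple[int, int] = (2, 15),
    seed: int | None = 0,
    replicates: int = 500,
    max_iter: int = 5000,
) -> tuple[int, np.ndarray, dict[int, float]]:
    """Number of states by maximum cumulative t-distance.

    Clusters the matrix at each candidate k and keeps the k with the
    largest cumulative t-distance (ties break towards the smaller,
    more parsimonious k). Returns (k*, labels at k*, t-distance curve).
    """
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    curve: dict[int, float] = {}
    all_labels: dict[int, np.ndarray] = {}
    for k in k_range:
        labels, _ = cluster_correlation(matrix, k, seed=seed,
                                        replicates=replicates, max_iter=max_iter)
        curve[k] = t_distance(matrix, labels)
        all_labels[k] = labels
    best = max(curve, key=lambda k: (curve[k], -k))
    return best, all_labels[best], curve


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class CorrelationStateClustering:
    """Per-mouse state decomposition (scikit-learn style estimator).

    Parameters
    ----------
    k : fixed number of states, or None to select by t-distance.
    k_range : candidate range for model selection.
    replicates, max_iter : k-means restarts and iteration cap (the
        production defaults follow the published protocol: 500/5000).
    stride : temporal subsampling for the correlation matrix and k-means;
        frames skipped by the stride are afterwards assigned to the
        nearest cluster centre in correlation-profile space, so
        ``stride=1`` reproduces the monolithic computation exactly.
    block_rows : compute the correlation matrix in row blocks.
    random_state : k-means seed.

    Fitted attributes: ``k_``, ``labels_`` (every valid frame),
    ``frame_index_``, ``mean_maps_``, ``tdist_curve_``, ``low_separation_``.
    """

    def __init__(self, k: int | None = None, k_range: tuple[int, int] = (2, 15),
                 replicates: int = 500, max_iter: int = 5000, stride: int = 1,
                 block_rows: int | None = None, random_state: int | None = 0) -> None:
        self.k = k
        self.k_range = k_range
        self.replicates = replicates
        self.max_iter = max_iter
        self.stride = stride
        self.block_rows = block_rows
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "k", "k_range", "replicates", "max_iter", "stride",
            "block_rows", "random_state")}

    def set_params(self, **params) -> "CorrelationStateClustering":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, movies: list[DffMovie] | DffMovie) -> "CorrelationStateClustering":
        if isinstance(movies, DffMovie):
            movies = [movies]
        X, index = _stack_valid_frames(movies)
        mask = movies[0].mask
        sub = np.arange(0, X.shape[0], self.stride)
        Xs = X[sub]
        Zs = _standardize_rows(Xs.astype(float))
        P = Zs.shape[1]
        if self.block_rows is None:
            C = Zs @ Zs.T / P
        else:
            C = np.empty((Zs.shape[0],) * 2)
            for s in range(0, Zs.shape[0], self.block_rows):
                e = min(s + self.block_rows, Zs.shape[0])
                C[s:e] = Zs[s:e] @ Zs.T / P
        np.fill_diagonal(C, 1.0)

        if self.k is None:
            k, sub_labels, curve = select_k(
                C, k_range=self.k_range, seed=self.random_state,
                replicates=self.replicates, max_iter=self.max_iter)
        else:
            k = self.k
            sub_labels, _ = cluster_correlation(
                C, k, seed=self.random_state,
                replicates=self.replicates, max_iter=self.max_iter)
            curve = {k: t_distance(C, sub_labels)}

        # place every frame in correlation-profile space and assign to the
        # nearest cluster centre (identity on the strided frames themselves)
        centers = np.stack([C[sub_labels == c].mean(axis=0) for c in range(k)])
        Z = _standardize_rows(X.astype(float))
        profiles = Z @ Zs.T / P
        d2 = ((profiles[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        labels[sub] = sub_labels  # clustered frames keep their k-means label

        maps = np.zeros((k,) + mask.shape)
        for c in range(k):
            maps[c][mask] = X[labels == c].mean(axis=0)

        self.k_ = int(k)
        self.labels_ = labels
        self.strided_indices_ = sub
        self.strided_labels_ = sub_labels
        self.tdist_curve_ = curve
        self.low_separation_ = max(curve.values()) < LOW_SEPARATION_T
        if self.low_separation_:
            logger.warning("low cluster separation (max cumulative t %.2f)",
                           max(curve.values()))
        self.mean_maps_ = maps
        self.mask_ = mask
        self.frame_index_ = index
        self.reference_ = Xs
        self.centers_ = centers
        return self

    def fit_predict(self, movies) -> np.ndarray:
        return self.fit(movies).labels_

    def predict(self, movies: list[DffMovie] | DffMovie) -> np.ndarray:
        """State labels for new movies sharing the fitted mask."""
        if isinstance(movies, DffMovie):
            movies = [movies]
        profiles = cross_correlation_profiles(movies, self.reference_, self.mask_)
        d2 = ((profiles[:, None, :] - self.centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def to_state_model(self) -> StateModel:
        return StateModel(k=self.k_, labels=self.labels_,
                          frame_index=self.frame_index_,
                          mean_maps=self.mean_maps_,
                          tdist_curve=self.tdist_curve_,
                          low_separation=self.low_separation_)


class ConsensusStates:
    """Cross-mouse consensus state space (scikit-learn style estimator).

    Correlates every mouse's per-state mean activity maps with every
    other's, k-means-clusters the rows of that matrix into
    ``n_consensus`` groups, and maps each (mouse, state) pair to its
    consensus id. Consensus ids are arbitrary integers; any naming
    (frontal, posterior, ...) is post-hoc annotation, never construction.
    """

    def __init__(self, n_consensus: int = 7, replicates: int = 500,
                 max_iter: int = 5000, random_state: int | None = 0) -> None:
        self.n_consensus = n_consensus
        self.replicates = replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_consensus", "replicates", "max_iter", "random_state")}

    def set_params(self, **params) -> "ConsensusStates":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, models: list[StateModel | CorrelationStateClustering],
            mask: np.ndarray) -> "ConsensusStates":
        mask = np.asarray(mask, dtype=bool)
        maps, owners = [], []
        for mi, model in enumerate(models):
            mm = model.mean_maps_ if hasattr(model, "mean_maps_") else model.mean_maps
            for si in range(mm.shape[0]):
                maps.append(mm[si][mask])
                owners.append((mi, si))
        M = len(maps)
        if M < self.n_consensus:
            raise ValueError(
                f"only {M} per-mouse states for {self.n_consensus} consensus states")
        V = np.stack(maps)
        Z = _standardize_rows(V)
        C = Z @ Z.T / Z.shape[1]
        np.fill_diagonal(C, 1.0)
        labels, _ = cluster_correlation(C, self.n_consensus,
                                        seed=self.random_state,
                                        replicates=self.replicates,
                                        max_iter=self.max_iter)
        cmaps = np.zeros((self.n_consensus,) + mask.shape)
        for c in range(self.n_consensus):
            cmaps[c][mask] = V[labels == c].mean(axis=0)
        self.mask_ = mask
        self.consensus_maps_ = cmaps
        self.map_labels_ = labels
        self.mouse_state_map_ = {ow: int(l) for ow, l in zip(owners, labels)}
        self.correlation_ = C
        return self

    def relabel(self, mouse: int, labels: np.ndarray) -> np.ndarray:
        """Per-mouse state labels -> consensus labels (invalid -1 passes through)."""
        labels = np.asarray(labels, dtype=int)
        out = np.full(labels.shape, -1, dtype=int)
        ok = labels >= 0
        lut = {s: c for (m, s), c in self.mouse_state_map_.items() if m == mouse}
        out[ok] = np.array([lut[int(s)] for s in labels[ok]], dtype=int)
        return out

    def to_model(self) -> ConsensusModel:
        return ConsensusModel(n_consensus=self.n_consensus,
                              consensus_maps=self.consensus_maps_,
                              mouse_state_map=self.mouse_state_map_,
                              map_labels=self.map_labels_)
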