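"""Raw dual-illumination stacks -> masked, filtered, z-scored DF/F movies.

The camera alternates blue (calcium-dependent) and green (calcium-
independent reference) illumination at 30 FPS total, giving 15 FPS per
channel. The pipeline, in fixed order:

    demultiplex -> (motion-correction hook) -> bilinear bin to 80%
    -> cortex mask -> global-illumination DF/F -> 0.1-5 Hz zero-phase
    Chebyshev band-pass -> 7-pixel nearest-neighbour spatial average
    -> per-pixel z-score

Every stage is mask-closed: pixels outside the cortex mask are exactly 0
at every point, and dropped-frame indices propagate so that behavioural
tables can drop the same frames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

CHANNEL_BLUE = "blue"
CHANNEL_GREEN = "green"
CHANNEL_UNKNOWN = "unknown"

# pixel + 4-neighbourhood + the first two diagonals in (row, col) order;
# "7-pixel nearest-neighbour average" is not a standard kernel, so the two
# diagonal picks are fixed deterministically (alternative: 3x3 minus corners)
SMOOTH_OFFSETS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1))


@dataclass
class FrameStack:
    """Raw (or demultiplexed) image stack with per-frame bookkeeping."""

    frames: np.ndarray                  # (T, H, W)
    timestamps: np.ndarray              # seconds, strictly increasing
    channel_labels: np.ndarray | None = None   # per-frame channel string
    dropped: np.ndarray | None = None          # per-frame bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.timestamps.shape[0] != self.frames.shape[0]:
            raise ValueError("timestamps must match frame count")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.dropped is None:
            self.dropped = np.zeros(self.frames.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class DffMovie:
    """Z-scored DF/F movie: the substrate of all state analysis."""

    data: np.ndarray                    # (T, H, W) float
    mask: np.ndarray                    # (H, W) bool
    valid: np.ndarray                   # (T,) bool
    fps: float = 15.0
    roi_labels: np.ndarray | None = None
    filtered: bool = True               # False when trial too short to filter

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def masked_frames(self, frames: np.ndarray | None = None) -> np.ndarray:
        """In-mask pixels as (T, P) vectors."""
        d = self.data if frames is None else self.data[frames]
        return d[:, self.mask]


class DegenerateClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# channel demultiplexing
# ---------------------------------------------------------------------------

def classify_channels(
    stack: FrameStack,
    bright_channel: str = CHANNEL_BLUE,
    outlier_sd: float = 4.0,
) -> FrameStack:
    """Label each frame blue or green from its mean intensity.

    Two-cluster k-means on the per-frame mean pixel intensities separates
    the illumination channels; the brighter cluster is labelled
    ``bright_channel``. Frames whose mean lies more than ``outlier_sd``
    cluster standard deviations from both centroids (motion artifacts, LED
    irregularities) are labelled unknown and marked dropped.
    """
    if stack.n_frames < 4:
        raise ValueError("need at least 4 frames to classify channels")
    means = stack.frames.reshape(stack.n_frames, -1).mean(axis=1).astype(float)
    if np.ptp(means) == 0:
        raise DegenerateClusteringError("all frame means identical")

    # gross artifacts would capture a k-means centroid on their own, so trim
    # them before clustering (robust MAD rule); they are re-examined by the
    # 4-sd rule below and end up unknown/dropped
    med = np.median(means)
    mad = 1.4826 * np.median(np.abs(means - med))
    spread = max(mad, 1e-9 * max(abs(med), 1.0))
    keep = np.abs(means - med) <= 8 * spread
    if keep.sum() < 4:
        raise DegenerateClusteringError("too few classifiable frames")
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(means[keep, None])
    centers = km.cluster_centers_.ravel()
    assign = np.full(stack.n_frames, -1, dtype=int)
    assign[keep] = km.labels_
    sds = np.array([
        means[assign == c].std() if np.sum(assign == c) > 1 else 0.0
        for c in range(2)
    ])
    # tolerance floor: a zero-variance cluster still accepts exact matches
    tol = np.maximum(outlier_sd * sds, 1e-9 + 1e-9 * np.abs(centers))
    dist = np.abs(means[:, None] - centers[None, :])
    outlier = np.all(dist > tol[None, :], axis=1)

    hi = int(np.argmax(centers))
    nearest = np.argmin(dist, axis=1)
    other = {CHANNEL_BLUE: CHANNEL_GREEN, CHANNEL_GREEN: CHANNEL_BLUE}[bright_channel]
    labels = np.where(nearest == hi, bright_channel, other).astype(object)
    labels[outlier] = CHANNEL_UNKNOWN
    dropped = stack.dropped | outlier
    if outlier.any():
        logger.info("flagged %d unclassifiable frame(s) for removal", outlier.sum())
    return FrameStack(frames=stack.frames, timestamps=stack.timestamps,
                      channel_labels=np.asarray(labels), dropped=dropped)


def demultiplex(stack: FrameStack) -> tuple[FrameStack, FrameStack]:
    """Split a labelled stack into blue and green sub-stacks (drops flagged frames)."""
    if stack.channel_labels is None:
        raise ValueError("classify_channels first")
    out = []
    for ch in (CHANNEL_BLUE, CHANNEL_GREEN):
        sel = (stack.channel_labels == ch) & ~stack.dropped
        out.append(FrameStack(frames=stack.frames[sel],
                              timestamps=stack.timestamps[sel]))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# spatial binning
# ---------------------------------------------------------------------------

def _bin_coords(n_in: int, n_out: int) -> np.ndarray:
    """Input coordinates of output pixel centres (pixel-centre convention)."""
    f = n_out / n_in
    return (np.arange(n_out) + 0.5) / f - 0.5


def bin_frames(frames: np.ndarray, factor: float = 0.8, order: int = 1) -> np.ndarray:
    """Bilinear resampling of each frame to ``round(dim * factor)`` pixels.

    Uses the pixel-centre convention (output centre i maps to input
    coordinate (i + 0.5)/f - 0.5, clamped at the borders), so constant
    images map to constant images of the same value.
    """
    if factor <= 0:
        raise ValueError("bin factor must be positive")
    frames = np.asarray(frames)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    T, H, W = frames.shape
    h, w = int(round(H * factor)), int(round(W * factor))
    if (h, w) == (H, W):
        out = frames.astype(float, copy=True)
        return out[0] if single else out
    rr = np.clip(_bin_coords(H, h), 0, H - 1)
    cc = np.clip(_bin_coords(W, w), 0, W - 1)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([R.ravel(), C.ravel()])
    out = np.empty((T, h, w), dtype=float)
    for t in range(T):
        out[t] = ndimage.map_coordinates(
            frames[t].astype(float), coords, order=order, mode="nearest"
        ).reshape(h, w)
    return out[0] if single else out


def bin_mask(mask: np.ndarray, factor: float = 0.8) -> np.ndarray:
    """Resample a boolean mask with the same transform (threshold at 0.5)."""
    return bin_frames(mask.astype(float), factor) > 0.5


def bin_labels(labels: np.ndarray, factor: float = 0.8) -> np.ndarray:
    """Resample an integer label image with nearest-neighbour sampling."""
    return np.rint(bin_frames(labels.astype(float), factor, order=0)).astype(labels.dtype)


# ---------------------------------------------------------------------------
# DF/F with global-illumination correction
# ---------------------------------------------------------------------------

def compute_dff(
    blue: FrameStack,
    green: FrameStack,
    mask: np.ndarray,
) -> np.ndarray:
    """Global-illumination-corrected DF/F.

    Each blue frame is paired with the nearest-in-time green frame; the
    green frame's in-mask spatial mean, normalised by its own trial mean,
    estimates the instantaneous global illumination g(t). The corrected
    fluorescence F = blue / g is converted per pixel to (F - F0)/F0 with
    F0 the pixel's trial mean. Divisive correction cancels any
    multiplicative drift the two channels share. Out-of-mask pixels are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if blue.frames.shape[1:] != mask.shape:
        raise ValueError("mask shape does not match frames")
    if green.n_frames == 0:
        raise ValueError("no green frames to correct with")
    pair = np.searchsorted(green.timestamps, blue.timestamps)
    pair = np.clip(pair, 0, green.n_frames - 1)
    left = np.clip(pair - 1, 0, green.n_frames - 1)
    use_left = (np.abs(green.timestamps[left] - blue.timestamps)
                < np.abs(green.timestamps[pair] - blue.timestamps))
    pair = np.where(use_left, left, pair)

    gmean = green.frames[:, mask].mean(axis=1).astype(float)
    g = gmean[pair]
    g = g / g.mean()

    F = blue.frames[:, mask].astype(float) / g[:, None]
    F0 = F.mean(axis=0)
    if np.any(F0 <= 0):
        bad = np.flatnonzero(F0 <= 0)[0]
        rr, cc = np.argwhere(mask)[bad]
        raise ValueError(f"non-positive baseline F0 at in-mask pixel ({rr}, {cc})")
    dff = (F - F0) / F0
    out = np.zeros((blue.n_frames,) + mask.shape, dtype=float)
    out[:, mask] = dff
    return out


# ---------------------------------------------------------------------------
# temporal band-pass
# ---------------------------------------------------------------------------

def design_bandpass(
    low_hz: float = 0.1,
    high_hz: float = 5.0,
    fps: float = 15.0,
    order: int = 3,
    ripple_db: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Chebyshev type-I band-pass coefficients (applied zero-phase)."""
    if fps <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    return signal.cheby1(order, ripple_db, [low_hz, high_hz], btype="band", fs=fps)


def bandpass(
    movie: np.ndarray,
    mask: np.ndarray,
    low_hz: float = 0.1,
    high_hz: float = 5.0,
    fps: float = 15.0,
    order: int = 3,
    ripple_db: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Zero-phase 0.1-5 Hz band-pass of every in-mask pixel trace.

    Forward-backward filtering with Gustafsson initial conditions, which
    makes the operator exactly time-reversal symmetric. Each trace is
    demeaned first: the mean is deep inside the stopband, so this changes
    nothing in the ideal response but suppresses edge transients. Trials
    shorter than three filter settle lengths are returned unfiltered with
    a warning (flag in the second return value).
    """
    b, a = design_bandpass(low_hz, high_hz, fps, order, ripple_db)
    settle = 3 * max(len(a), len(b))
    T = movie.shape[0]
    if T < 3 * settle:
        warnings.warn(
            f"trial of {T} frames is shorter than 3x filter settle length "
            f"({3 * settle}); skipping band-pass", stacklevel=2)
        return movie.copy(), False
    mask = np.asarray(mask, dtype=bool)
    x = movie[:, mask]
    x = x - x.mean(axis=0)
    y = signal.filtfilt(b, a, x, axis=0, method="gust")
    out = np.zeros_like(movie, dtype=float)
    out[:, mask] = y
    return out, True


# ---------------------------------------------------------------------------
# spatial smoothing and z-score
# ---------------------------------------------------------------------------

def spatial_smooth(movie: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """7-pixel nearest-neighbour average of every in-mask pixel.

    Each in-mask pixel is replaced by the mean over the 7-pixel kernel
    (itself, the 4-neighbourhood, and two fixed diagonals) restricted to
    in-bounds, in-mask members; near the mask edge the average simply runs
    over the available subset. Out-of-mask pixels stay exactly 0.
    """
    mask = np.asarray(mask, dtype=bool)
    single = movie.ndim == 2
    data = movie[None] if single else movie
    maskf = mask.astype(float)
    acc = np.zeros_like(data, dtype=float)
    cnt = np.zeros(mask.shape, dtype=float)
    H, W = mask.shape
    for dr, dc in SMOOTH_OFFSETS:
        rs = slice(max(dr, 0), H + min(dr, 0))
        rd = slice(max(-dr, 0), H + min(-dr, 0))
        cs = slice(max(dc, 0), W + min(dc, 0))
        cd = slice(max(-dc, 0), W + min(-dc, 0))
        acc[:, rd, cd] += data[:, rs, cs] * maskf[rs, cs]
        cnt[rd, cd] += maskf[rs, cs]
    out = np.zeros_like(data, dtype=float)
    inside = mask & (cnt > 0)
    out[:, inside] = acc[:, inside] / cnt[inside]
    return out[0] if single else out


def zscore_pixels(
    movie: np.ndarray,
    mask: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Z-score each in-mask pixel trace over valid frames (sample sd, n-1).

    Invalid frames are excluded from the moments but retained in place.
    """
    mask = np.asarray(mask, dtype=bool)
    T = movie.shape[0]
    valid = np.ones(T, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid frames to z-score")
    x = movie[:, mask]
    xv = x[valid]
    mu = xv.mean(axis=0)
    sd = xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)[0]
        rr, cc = np.argwhere(mask)[bad]
        raise ValueError(f"zero-variance in-mask pixel ({rr}, {cc})")
    out = np.zeros_like(movie, dtype=float)
    out[:, mask] = (x - mu) / sd
    return out


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

class DffPreprocessor:
    """Fixed-order preprocessing chain from raw stack to :class:`DffMovie`.

    Parameters mirror the acquisition/processing conventions: 80%
    bilinear binning, 0.1-5 Hz zero-phase Chebyshev band-pass, 7-pixel
    neighbour average, per-pixel z-score. A motion-correction callable can
    be hooked in after demultiplexing (the default is the identity; the
    synthetic data are motion-free).
    """

    def __init__(
        self,
        bin_factor: float = 0.8,
        low_hz: float = 0.1,
        high_hz: float = 5.0,
        fps: float = 15.0,
        filter_order: int = 3,
        ripple_db: float = 0.5,
        bright_channel: str = CHANNEL_BLUE,
        motion_corrector=None,
    ) -> None:
        self.bin_factor = bin_factor
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.fps = fps
        self.filter_order = filter_order
        self.ripple_db = ripple_db
        self.bright_channel = bright_channel
        self.motion_corrector = motion_corrector

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "bin_factor", "low_hz", "high_hz", "fps", "filter_order",
            "ripple_db", "bright_channel", "motion_corrector")}

    def set_params(self, **params) -> "DffPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def transform(
        self,
        stack: FrameStack,
        mask: np.ndarray,
        roi_labels: np.ndarray | None = None,
    ) -> DffMovie:
        """Run the full chain on one trial's interleaved stack.

        The output movie is aligned with the blue (calcium) frame
        timeline including dropped slots: a blue-parity frame flagged
        unclassifiable stays in the movie as an all-zero invalid frame, so
        downstream behaviour tables can drop the same indices. The audit
        table is stored on ``self.audit_``.
        """
        labelled = classify_channels(stack, bright_channel=self.bright_channel)
        self.audit_ = _frame_audit(labelled)
        blue, green = demultiplex(labelled)
        if self.motion_corrector is not None:
            blue = self.motion_corrector(blue)
            green = self.motion_corrector(green)
        blue_b = FrameStack(frames=bin_frames(blue.frames, self.bin_factor),
                            timestamps=blue.timestamps)
        green_b = FrameStack(frames=bin_frames(green.frames, self.bin_factor),
                             timestamps=green.timestamps)
        m = bin_mask(np.asarray(mask, dtype=bool), self.bin_factor)
        roi = None if roi_labels is None else bin_labels(roi_labels, self.bin_factor)
        dff = compute_dff(blue_b, green_b, m)
        dff, filtered = bandpass(dff, m, self.low_hz, self.high_hz, self.fps,
                                 self.filter_order, self.ripple_db)
        dff = spatial_smooth(dff, m)
        z = zscore_pixels(dff, m)

        # re-insert dropped blue-parity slots as invalid zero frames
        slots, slot_valid = _blue_slots(labelled)
        T = slots.size
        data = np.zeros((T,) + z.shape[1:], dtype=float)
        data[slot_valid] = z
        return DffMovie(data=data, mask=m, valid=slot_valid, fps=self.fps,
                        roi_labels=roi, filtered=filtered)


def _blue_slots(labelled: FrameStack) -> tuple[np.ndarray, np.ndarray]:
    """Indices of blue-timeline slots in the interleaved stack.

    Unclassifiable frames are attributed to the parity the blue frames
    occupy (majority vote), so a dropped calcium frame still owns a slot.
    Returns (original frame indices, per-slot validity).
    """
    lab = labelled.channel_labels
    is_blue = lab == CHANNEL_BLUE
    blue_idx = np.flatnonzero(is_blue)
    parity = int(np.round(np.mean(blue_idx % 2))) if blue_idx.size else 0
    unknown = lab == CHANNEL_UNKNOWN
    slot = is_blue | (unknown & (np.arange(lab.size) % 2 == parity))
    slots = np.flatnonzero(slot)
    valid = is_blue[slots] & ~labelled.dropped[slots]
    return slots, valid


def _frame_audit(labelled: FrameStack):
    import pandas as pd

    return pd.DataFrame({
        "index": np.arange(labelled.n_frames),
        "channel": labelled.channel_labels,
        "dropped": labelled.dropped,
        "reason": np.where(labelled.dropped, "unclassifiable", ""),
    })
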