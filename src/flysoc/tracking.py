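"""Constant-count multi-fly tracking.

The tracker's defining assumption is that the number of flies N is
constant throughout the video (a closed arena fully inside the field of
view). Per frame it therefore emits exactly N fly states, whatever the
number of connected components:

1. a bipartite graph connects the N flies of the previous frame to the
   current blobs, where merged candidate blobs are duplicated until the
   right side also holds N nodes (node duplication keeps the assignment
   square and the count constant);
2. the minimum-cost perfect matching (Hungarian algorithm, Euclidean
   center distances) decides how many flies each blob hosts;
3. blobs hosting k > 1 flies are split into k Gaussian-mixture components
   (EM over pixel coordinates, means initialized at the predicted fly
   positions) and identities are re-assigned among the split centers by a
   second Hungarian matching;
4. head and tail are the endpoints of each body's principal axis, with
   the head chosen in the direction of smoothed motion (a walking fly
   leads with its head); stationary flies keep their previous orientation.

Videos that start mid-occlusion are anchored at the first frame with all
flies separated and tracked backwards to the start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .detection import (
    DEFAULT_MERGE_FACTOR,
    DEFAULT_MIN_AREA,
    Blob,
    BlobSet,
    build_background,
    estimate_fly_area,
    flag_merged,
    principal_axis,
    segment_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FlyState",
    "TrackSet",
    "TrackConfig",
    "AssignmentGraph",
    "build_assignment_graph",
    "solve_assignment",
    "split_merged_blob",
    "assign_identities",
    "update_orientation",
    "track_video",
    "total_walking_distance",
]


@dataclass(frozen=True)
class FlyState:
    fly_id: int                 # 1-based
    frame: int                  # 0-based
    center: np.ndarray
    head: np.ndarray
    tail: np.ndarray
    speed: float                # px/frame


@dataclass
class TrackSet:
    """Exactly one state per (fly, frame): arrays of shape (T, N, 2)."""

    centers: np.ndarray
    heads: np.ndarray
    tails: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_flies(self) -> int:
        return self.centers.shape[1]

    @property
    def speeds(self) -> np.ndarray:
        """Per-frame center displacement, (T, N); frame 0 is 0."""
        s = np.zeros(self.centers.shape[:2])
        s[1:] = np.linalg.norm(np.diff(self.centers, axis=0), axis=2)
        return s

    @property
    def body_length(self) -> float:
        """Median head-to-tail length across all states."""
        return float(np.median(np.linalg.norm(self.heads - self.tails, axis=2)))

    def state(self, fly_id: int, frame: int) -> FlyState:
        f = fly_id - 1
        speed = 0.0 if frame == 0 else float(
            np.linalg.norm(self.centers[frame, f] - self.centers[frame - 1, f])
        )
        return FlyState(fly_id, frame, self.centers[frame, f],
                        self.heads[frame, f], self.tails[frame, f], speed)

    def to_table(self):
        import pandas as pd

        t, n, _ = self.centers.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(t), n),
                "fly_id": np.tile(np.arange(1, n + 1), t),
                "cx": self.centers[:, :, 0].ravel(),
                "cy": self.centers[:, :, 1].ravel(),
                "hx": self.heads[:, :, 0].ravel(),
                "hy": self.heads[:, :, 1].ravel(),
                "tx": self.tails[:, :, 0].ravel(),
                "ty": self.tails[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_table(cls, df) -> "TrackSet":
        df = df.sort_values(["frame", "fly_id"])
        frames = df["frame"].to_numpy()
        n = df["fly_id"].nunique()
        t = frames.max() + 1
        if len(df) != t * n:
            raise ValueError("incomplete trajectory table")
        shape = (t, n, 2)
        return cls(
            centers=df[["cx", "cy"]].to_numpy().reshape(shape),
            heads=df[["hx", "hy"]].to_numpy().reshape(shape),
            tails=df[["tx", "ty"]].to_numpy().reshape(shape),
        )


@dataclass(frozen=True)
class TrackConfig:
    n_flies: int
    threshold: float | None = None          # None -> Otsu
    min_area: int = DEFAULT_MIN_AREA
    merge_factor: float = DEFAULT_MERGE_FACTOR
    background_stride: int = 20
    typical_area: float | None = None       # None -> estimated from the video
    orient_window: int = 5
    speed_floor: float = 0.2                # px/frame
    em_seed: int = 0
    em_covariance: str = "full"             # GaussianMixture covariance_type


@dataclass
class AssignmentGraph:
    """Square bipartite cost structure: previous flies vs blob copies."""

    cost: np.ndarray            # (N, N) Euclidean distances
    col_blob: np.ndarray        # column -> blob index in the BlobSet
    multiplicities: np.ndarray  # per-blob provisional fly counts
    blobs: list[Blob] = field(default_factory=list)


def build_assignment_graph(
    prev_centers: np.ndarray,
    bs: BlobSet,
    n_flies: int,
    typical_area: float,
    merge_factor: float = DEFAULT_MERGE_FACTOR,
) -> AssignmentGraph:
    """Duplicate merged candidates until the right side has N nodes.

    The n_flies - blob_count duplicates are distributed over candidate
    merged blobs in proportion to excess area (largest first); blob b then
    appears 1 + duplicates(b) times as assignment columns, and the column
    multiset always has exactly N members (count conservation).
    """
    prev_centers = np.asarray(prev_centers, dtype=float)
    if prev_centers.shape != (n_flies, 2):
        raise ValueError("need exactly n_flies previous centers")
    if len(bs) == 0:
        raise ValueError(f"frame {bs.frame_index}: no blobs to assign")
    mult = flag_merged(bs, n_flies, typical_area, merge_factor)
    col_blob = np.repeat(np.arange(len(bs)), mult)
    centroids = bs.centroids[col_blob]
    diff = prev_centers[:, None, :] - centroids[None, :, :]
    cost = np.linalg.norm(diff, axis=2)
    return AssignmentGraph(cost=cost, col_blob=col_blob,
                           multiplicities=mult, blobs=bs.blobs)


def solve_assignment(g: AssignmentGraph) -> np.ndarray:
    """Minimum-cost perfect matching; returns the column of each left node.

    The number of left nodes matched into copies of a blob is that blob's
    final fly count for the frame.
    """
    if not np.all(np.isfinite(g.cost)):
        raise ValueError("assignment costs must be finite")
    rows, cols = linear_sum_assignment(g.cost)
    out = np.empty(g.cost.shape[0], dtype=int)
    out[rows] = cols
    return out


def split_merged_blob(
    pixels: np.ndarray,
    k: int,
    init_centers: np.ndarray | None = None,
    seed: int = 0,
    covariance_type: str = "full",
) -> tuple[np.ndarray, np.ndarray]:
    """Split a merged blob into k flies by EM on pixel coordinates.

    A k-component Gaussian mixture (full covariances, floored to avoid
    pixel-lattice degeneracy) is fitted to the blob's pixels with means
    initialized at the predicted positions of the k assigned flies.
    Returns (k component means, hard partition labels per pixel). An EM
    run leaving a component empty is retried once from k-means++.
    """
    pixels = np.asarray(pixels, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pixels) < k:
        raise ValueError("fewer pixels than components")
    if k == 1:
        return pixels.mean(axis=0, keepdims=True), np.zeros(len(pixels), dtype=int)

    def _fit(means_init):
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            means_init=means_init,
            max_iter=100,
            tol=1e-4,
            reg_covar=0.25,
            random_state=seed,
            init_params="k-means++",
        )
        labels = gm.fit_predict(pixels)
        return np.asarray(gm.means_)[:, :2], labels

    init = None if init_centers is None else np.asarray(init_centers, dtype=float)
    means, labels = _fit(init)
    if len(np.unique(labels)) < k and init is not None:
        means, labels = _fit(None)  # k-means++ restart
    if len(np.unique(labels)) < k:
        raise RuntimeError("EM split degenerate: empty component after restart")
    return means, labels


def assign_identities(prev_centers: np.ndarray, split_centers: np.ndarray) -> np.ndarray:
    """Identity inheritance: minimum-cost matching of previous fly centers
    to current (split) centers; returns, per previous fly, the index of
    the current center it owns."""
    prev_centers = np.asarray(prev_centers, dtype=float)
    split_centers = np.asarray(split_centers, dtype=float)
    if prev_centers.shape != split_centers.shape:
        raise ValueError("need equally many previous and current centers")
    cost = np.linalg.norm(
        prev_centers[:, None, :] - split_centers[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    out = np.empty(len(prev_centers), dtype=int)
    out[rows] = cols
    return out


def update_orientation(
    centers: np.ndarray,
    axes: np.ndarray,
    semi_lengths: np.ndarray,
    orient_window: int = 5,
    speed_floor: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the head/tail ambiguity of the principal axis by motion.

    For one fly: ``centers`` (T, 2), ``axes`` (T, 2) unit principal axes,
    ``semi_lengths`` (T,). The head is the axis endpoint whose direction
    agrees with the velocity averaged over the trailing ``orient_window``
    frames; below ``speed_floor`` px/frame the previous head choice is
    kept. Frame 0 is provisional (positive axis direction).
    Returns (heads, tails), each (T, 2).
    """
    t_max = len(centers)
    heads = np.empty_like(centers)
    tails = np.empty_like(centers)
    prev_dir = axes[0].copy()
    for t in range(t_max):
        w = min(orient_window, t)
        if w > 0:
            vel = (centers[t] - centers[t - w]) / w
            speed = np.linalg.norm(vel)
        else:
            vel, speed = np.zeros(2), 0.0
        axis = axes[t]
        if speed >= speed_floor:
            sign = 1.0 if float(axis @ vel) >= 0 else -1.0
        else:
            sign = 1.0 if float(axis @ prev_dir) >= 0 else -1.0
        d = sign * axis
        heads[t] = centers[t] + semi_lengths[t] * d
        tails[t] = centers[t] - semi_lengths[t] * d
        prev_dir = d
    return heads, tails


def _step(
    prev_centers: np.ndarray,
    bs: BlobSet,
    cfg: TrackConfig,
    typical_area: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance one frame: returns (centers, axes, semi_lengths) per fly."""
    n = cfg.n_flies
    g = build_assignment_graph(prev_centers, bs, n, typical_area, cfg.merge_factor)
    match = solve_assignment(g)
    blob_of_fly = g.col_blob[match]
    centers = np.empty((n, 2))
    axes = np.empty((n, 2))
    semis = np.empty(n)
    for b_idx in np.unique(blob_of_fly):
        fly_rows = np.nonzero(blob_of_fly == b_idx)[0]
        blob = g.blobs[b_idx]
        if len(fly_rows) == 1:
            f = fly_rows[0]
            centers[f] = blob.centroid
            axes[f] = blob.major_axis
            semis[f] = blob.semi_major
        else:
            means, labels = split_merged_blob(
                blob.pixels, len(fly_rows),
                init_centers=prev_centers[fly_rows], seed=cfg.em_seed,
                covariance_type=cfg.em_covariance,
            )
            owner = assign_identities(prev_centers[fly_rows], means)
            for local, f in enumerate(fly_rows):
                comp = owner[local]
                part = blob.pixels[labels == comp]
                if len(part) >= 2:
                    axis, semi = principal_axis(part)
                    centers[f] = part.mean(axis=0)
                else:
                    axis, semi = blob.major_axis, blob.semi_major / len(fly_rows)
                    centers[f] = means[comp]
                axes[f] = axis
                semis[f] = semi
    return centers, axes, semis


def track_video(frames, cfg: TrackConfig) -> TrackSet:
    """Track a frame sequence into exactly ``cfg.n_flies`` continuous tracks.

    ``frames`` is any indexable sequence of 2-D uint8 arrays (for example
    the simulator's lazy renderer or a loaded video). The anchor is the
    first frame whose blob count equals N; earlier frames are tracked
    backwards from it.
    """
    n_frames = len(frames)
    if n_frames < 1:
        raise ValueError("empty video")
    background = build_background(
        frames, min(cfg.background_stride, max(n_frames - 1, 1))
    )
    blobsets = [
        segment_frame(frames[t], background, cfg.threshold, cfg.min_area, t)
        for t in range(n_frames)
    ]
    typical_area = (
        cfg.typical_area
        if cfg.typical_area is not None
        else estimate_fly_area(blobsets, cfg.n_flies)
    )
    anchor = next(
        (t for t, bs in enumerate(blobsets) if len(bs) == cfg.n_flies), None
    )
    if anchor is None:
        raise ValueError("no frame with all flies separated; cannot anchor tracks")
    if anchor > 0:
        logger.info("anchoring at frame %d; tracking earlier frames backwards", anchor)

    t_max, n = n_frames, cfg.n_flies
    centers = np.empty((t_max, n, 2))
    axes = np.empty((t_max, n, 2))
    semis = np.empty((t_max, n))

    bs0 = blobsets[anchor]
    order = np.lexsort((bs0.centroids[:, 0], bs0.centroids[:, 1]))
    for f, b_idx in enumerate(order):
        blob = bs0.blobs[b_idx]
        centers[anchor, f] = blob.centroid
        axes[anchor, f] = blob.major_axis
        semis[anchor, f] = blob.semi_major

    for t in range(anchor + 1, t_max):
        centers[t], axes[t], semis[t] = _step(
            centers[t - 1], blobsets[t], cfg, typical_area
        )
    for t in range(anchor - 1, -1, -1):
        centers[t], axes[t], semis[t] = _step(
            centers[t + 1], blobsets[t], cfg, typical_area
        )

    heads = np.empty_like(centers)
    tails = np.empty_like(centers)
    for f in range(n):
        heads[:, f], tails[:, f] = update_orientation(
            centers[:, f], axes[:, f], semis[:, f],
            cfg.orient_window, cfg.speed_floor,
        )
    return TrackSet(centers=centers, heads=heads, tails=tails)


def total_walking_distance(ts: TrackSet) -> tuple[np.ndarray, float]:
    """Per-fly summed center displacement and the group total, in pixels."""
    steps = np.linalg.norm(np.diff(ts.centers, axis=0), axis=2)
    per_fly = steps.sum(axis=0)
    return per_fly, float(per_fly.sum())
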