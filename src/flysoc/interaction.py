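"""Touch-interaction detection from trajectories.

A *touch* is a single-frame head-to-tail contact of an ordered fly pair
(interactor's head at the interacted fly's tail). Single-frame touches
are recognized by a supervised classifier (RBF-kernel support vector
machine) over 22 temporal features per (interactor, interacted, frame)
triple: the 11 head-to-tail Euclidean distances over the 11-frame window
centered on the frame, and the 11 magnitudes of the interactor's
displacement from its window-center position expressed relative to the
interacted fly's concurrent position (the window-center entry is 0 by
construction).

A *touch interaction* is a run of touch frames lasting at least
``MIN_RUN`` (15) consecutive frames (~0.5 s at 30 fps); gaps shorter
than ``MIN_GAP`` (15) frames between runs are merged first, so a
flickering classifier output counts as one sustained touch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .tracking import TrackSet

__all__ = [
    "WINDOW_HALF",
    "N_FEATURES",
    "MIN_RUN",
    "MIN_GAP",
    "TouchInteraction",
    "extract_features",
    "feature_matrix",
    "build_training_set",
    "train_classifier",
    "classify_frames",
    "extract_interactions",
]

WINDOW_HALF = 5           # 11-frame window: frame-5 .. frame+5
N_FEATURES = 22
MIN_RUN = 15              # frames; ~0.5 s at 30 fps
MIN_GAP = 15              # frames between distinct interactions
DEFAULT_CANDIDATE_RADIUS_BL = 3.0   # gating radius in body lengths


@dataclass(frozen=True)
class TouchInteraction:
    """Directed interaction event; frames inclusive, ids 1-based."""

    interactor_id: int
    interacted_id: int
    start_frame: int
    end_frame: int

    @property
    def duration(self) -> int:
        return self.end_frame - self.start_frame + 1


def extract_features(ts: TrackSet, i: int, j: int, t: int) -> np.ndarray:
    """The 22-vector for interactor ``i`` toward interacted ``j`` at frame
    ``t`` (1-based fly ids). Raises if the 11-frame window leaves the video."""
    if not WINDOW_HALF <= t < ts.n_frames - WINDOW_HALF:
        raise ValueError(
            f"frame {t}: the {2 * WINDOW_HALF + 1}-frame window leaves the video"
        )
    return feature_matrix(
        ts, np.array([t]), np.array([i - 1]), np.array([j - 1])
    )[0]


def feature_matrix(
    ts: TrackSet, t_idx: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray
) -> np.ndarray:
    """Vectorized feature extraction for M (frame, interactor, interacted)
    triples given as 0-based index arrays; returns an (M, 22) matrix.

    Entries 0-10: Euclidean distance from i's head to j's tail at
    t+tau, tau = -5..5. Entries 11-21: |r(tau) - r(0)| where
    r(tau) = center_i(t+tau) - center_j(t+tau) — the interactor's
    displacement from its window-center position in a coordinate frame
    translated to the interacted fly's concurrent position.
    """
    taus = np.arange(-WINDOW_HALF, WINDOW_HALF + 1)
    tw = t_idx[:, None] + taus[None, :]                       # (M, 11)
    hi = ts.heads[tw, i_idx[:, None]]                         # (M, 11, 2)
    tj = ts.tails[tw, j_idx[:, None]]
    dists = np.linalg.norm(hi - tj, axis=2)
    rel = ts.centers[tw, i_idx[:, None]] - ts.centers[tw, j_idx[:, None]]
    disp = np.linalg.norm(rel - rel[:, WINDOW_HALF : WINDOW_HALF + 1], axis=2)
    return np.concatenate([dists, disp], axis=1)


def _candidate_triples(
    ts: TrackSet, candidate_radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (t, i, j) with i != j, full window inside the video, and i's
    head within ``candidate_radius`` of j's tail at t (0-based indices)."""
    t0, t1 = WINDOW_HALF, ts.n_frames - WINDOW_HALF
    d = np.linalg.norm(
        ts.heads[t0:t1, :, None, :] - ts.tails[t0:t1, None, :, :], axis=3
    )
    n = ts.n_flies
    d[:, np.arange(n), np.arange(n)] = np.inf
    t_idx, i_idx, j_idx = np.nonzero(d <= candidate_radius)
    return t_idx + t0, i_idx, j_idx


def build_training_set(
    ts: TrackSet,
    touch_labels: np.ndarray,
    n_per_class: int = 1000,
    candidate_radius: float | None = None,
    margin: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced training matrix from a labelled trajectory set.

    ``touch_labels`` is the (T, N, N) ordered-pair boolean array (for
    example the simulator's ground truth). Positives are sampled from
    labelled touch frames; negatives from candidate-gated pairs at least
    ``margin`` frames away from any touch of that pair, topped up with
    random far pairs when the arena yields too few near-miss frames.
    """
    rng = np.random.default_rng(rng)
    if candidate_radius is None:
        candidate_radius = DEFAULT_CANDIDATE_RADIUS_BL * ts.body_length
    t0, t1 = WINDOW_HALF, ts.n_frames - WINDOW_HALF

    pt, pi, pj = np.nonzero(touch_labels[t0:t1])
    pt = pt + t0
    if len(pt) == 0:
        raise ValueError("no labelled touch frames in the valid window")
    take = rng.choice(len(pt), size=min(n_per_class, len(pt)), replace=False)
    pos = (pt[take], pi[take], pj[take])

    # dilate labels in time to keep negatives clear of touch boundaries
    dil = touch_labels.copy()
    for s in range(1, margin + 1):
        dil[s:] |= touch_labels[:-s]
        dil[:-s] |= touch_labels[s:]
    ct, ci, cj = _candidate_triples(ts, candidate_radius)
    keep = ~dil[ct, ci, cj]
    ct, ci, cj = ct[keep], ci[keep], cj[keep]
    n_neg = min(len(ct), n_per_class)
    take = rng.choice(len(ct), size=n_neg, replace=False)
    neg = [ct[take], ci[take], cj[take]]
    short = n_per_class - n_neg
    if short > 0:  # random far pairs
        rt = rng.integers(t0, t1, size=short)
        ri = rng.integers(0, ts.n_flies, size=short)
        rj = (ri + rng.integers(1, ts.n_flies, size=short)) % ts.n_flies
        neg = [np.concatenate([a, b]) for a, b in zip(neg, (rt, ri, rj))]

    x_pos = feature_matrix(ts, *pos)
    x_neg = feature_matrix(ts, *neg)
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(len(x_pos), dtype=int), np.zeros(len(x_neg), dtype=int)])
    perm = rng.permutation(len(y))
    return x[perm], y[perm]


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    cv_folds: int = 5,
) -> Pipeline:
    """Fit the touch/no-touch classifier.

    Features are z-scored with constants learned on the training set, and
    an RBF-kernel SVM is fitted on top; C and the kernel width are chosen
    by stratified cross-validation. Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    grid = GridSearchCV(
        pipe,
        param_grid={"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.05]},
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    grid.fit(np.asarray(features, dtype=float), labels)
    return grid.best_estimator_


def classify_frames(
    model: Pipeline,
    ts: TrackSet,
    candidate_radius: float | None = None,
    batch: int = 20000,
) -> np.ndarray:
    """Per-frame ordered-pair touch booleans, shape (T, N, N).

    Only pairs whose head-tail distance is within ``candidate_radius``
    (default 3 body lengths) are scored; all others are false, as are
    frames whose feature window leaves the video. The gate is an
    efficiency device: at the default radius it leaves every plausible
    contact in play while skipping the vast majority of the N(N-1)
    ordered pairs per frame.
    """
    if candidate_radius is None:
        candidate_radius = DEFAULT_CANDIDATE_RADIUS_BL * ts.body_length
    out = np.zeros((ts.n_frames, ts.n_flies, ts.n_flies), dtype=bool)
    t_idx, i_idx, j_idx = _candidate_triples(ts, candidate_radius)
    for s in range(0, len(t_idx), batch):
        sl = slice(s, s + batch)
        x = feature_matrix(ts, t_idx[sl], i_idx[sl], j_idx[sl])
        pred = model.predict(x).astype(bool)
        out[t_idx[sl], i_idx[sl], j_idx[sl]] = pred
    return out


def _bool_runs(series: np.ndarray) -> list[tuple[int, int]]:
    """Maximal true-runs of a boolean series as (start, end) inclusive."""
    padded = np.concatenate([[False], series, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts, ends))


def extract_interactions(
    frame_labels: np.ndarray,
    min_run: int = MIN_RUN,
    min_gap: int = MIN_GAP,
) -> list[TouchInteraction]:
    """Apply the run/gap rules to per-frame touch labels.

    ``frame_labels`` is either a (T, N, N) ordered-pair boolean array or a
    1-D boolean series for one ordered pair (then reported as pair 1->2).
    Gaps shorter than ``min_gap`` are merged first; merged runs shorter
    than ``min_run`` frames are dropped.
    """
    frame_labels = np.asarray(frame_labels, dtype=bool)
    if frame_labels.ndim == 1:
        return [
            TouchInteraction(1, 2, s, e)
            for s, e in _pair_interactions(frame_labels, min_run, min_gap)
        ]
    if frame_labels.ndim != 3:
        raise ValueError("frame_labels must be 1-D or (T, N, N)")
    events: list[TouchInteraction] = []
    n = frame_labels.shape[1]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            series = frame_labels[:, i, j]
            if not series.any():
                continue
            events.extend(
                TouchInteraction(i + 1, j + 1, s, e)
                for s, e in _pair_interactions(series, min_run, min_gap)
            )
    events.sort(key=lambda ev: (ev.start_frame, ev.interactor_id, ev.interacted_id))
    return events


def _pair_interactions(
    series: np.ndarray, min_run: int, min_gap: int
) -> list[tuple[int, int]]:
    runs = _bool_runs(series)
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < min_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s + 1 >= min_run]
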