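"""Synthetic walking-arena simulator.

Emulates the recording conditions of a dark-background infrared arena:
bright fly-sized ellipses on a dark field, smooth random-walk locomotion
with heading persistence, scripted pairwise crossings (occlusions) and
scripted head-to-tail touch episodes with frame-exact ground-truth labels.

Every downstream stage (segmentation, tracking, interaction detection,
network construction) is testable against the ground truth produced here.

Conventions: pixel coordinates with origin at the top-left corner, x to
the right, y down; frames are 0-based; fly ids are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TouchSpec",
    "CrossingSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_trajectories",
    "render_frames",
    "RenderedVideo",
    "random_touch_specs",
    "random_crossing_specs",
    "random_episode_specs",
]


@dataclass(frozen=True)
class TouchSpec:
    """A scripted head-to-tail touch: ``interactor``'s head is held within
    the touch radius of ``interacted``'s tail for ``duration`` frames
    starting at ``start``. Fly ids are 1-based."""

    interactor: int
    interacted: int
    start: int
    duration: int


@dataclass(frozen=True)
class CrossingSpec:
    """A scripted crossing: ``fly_b`` approaches ``fly_a`` and their body
    centers stay within one body length for ``duration`` frames, with the
    offset direction sweeping so the two bodies overlap mid-episode."""

    fly_a: int
    fly_b: int
    start: int
    duration: int


# Frames of steered approach granted to a scripted fly before its episode.
_LEAD_IN = 150


@dataclass(frozen=True)
class SimConfig:
    arena_width_px: int = 640
    arena_height_px: int = 480
    n_flies: int = 16
    n_frames: int = 600
    fps: float = 30.0
    fly_area_px: float = 20.0
    aspect_ratio: float = 2.5
    speed_mean: float = 1.0
    speed_sd: float = 0.3
    heading_persistence: float = 0.9
    touch_radius_bl: float = 0.5   # touch radius in body lengths
    noise_sd: float = 0.0          # optional Gaussian pixel noise
    background_level: int = 10
    fly_level: int = 255
    seed: int = 0
    crossing_specs: tuple[CrossingSpec, ...] = field(default_factory=tuple)
    touch_specs: tuple[TouchSpec, ...] = field(default_factory=tuple)

    # --- derived geometry -------------------------------------------------
    @property
    def semi_major(self) -> float:
        """Ellipse semi-major axis a with pi*a*b = fly_area_px, b = a/aspect."""
        return math.sqrt(self.fly_area_px * self.aspect_ratio / math.pi)

    @property
    def semi_minor(self) -> float:
        return self.semi_major / self.aspect_ratio

    @property
    def body_length(self) -> float:
        return 2.0 * self.semi_major

    @property
    def touch_radius(self) -> float:
        return self.touch_radius_bl * self.body_length

    def validate(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fly_area_px <= 0:
            raise ValueError("fly_area_px must be > 0")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValueError("heading_persistence must be in [0, 1]")
        for ep in self.touch_specs:
            self._check_episode(ep.interactor, ep.interacted, ep.start, ep.duration)
        for ep in self.crossing_specs:
            self._check_episode(ep.fly_a, ep.fly_b, ep.start, ep.duration)

    def _check_episode(self, f1: int, f2: int, start: int, duration: int) -> None:
        for f in (f1, f2):
            if not 1 <= f <= self.n_flies:
                raise ValueError(f"episode references fly id {f} outside 1..{self.n_flies}")
        if f1 == f2:
            raise ValueError("episode flies must be distinct")
        if start < 1 or duration < 1:
            # frame 0 is the random initial placement; scripted geometry is
            # only guaranteed from frame 1 onward
            raise ValueError("episode start must be >= 1 and duration >= 1")
        if start + duration > self.n_frames:
            raise ValueError("episode extends beyond n_frames")


@dataclass
class GroundTruth:
    """Frame-exact simulated truth.

    centers/heads/tails have shape (n_frames, n_flies, 2) in (x, y) pixels;
    touch_labels has shape (n_frames, n_flies, n_flies) with
    touch_labels[t, i-1, j-1] true when fly i touches fly j (ordered) at t.
    """

    cfg: SimConfig
    centers: np.ndarray
    heads: np.ndarray
    tails: np.ndarray
    touch_labels: np.ndarray
    crossing_frames: list[tuple[int, tuple[int, int]]]

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_flies(self) -> int:
        return self.centers.shape[1]

    def to_trajectory_table(self):
        """Long-format trajectory table (frame, fly_id, cx, cy, hx, hy, tx, ty)."""
        import pandas as pd

        t, n, _ = self.centers.shape
        frames = np.repeat(np.arange(t), n)
        ids = np.tile(np.arange(1, n + 1), t)
        return pd.DataFrame(
            {
                "frame": frames,
                "fly_id": ids,
                "cx": self.centers[:, :, 0].ravel(),
                "cy": self.centers[:, :, 1].ravel(),
                "hx": self.heads[:, :, 0].ravel(),
                "hy": self.heads[:, :, 1].ravel(),
                "tx": self.tails[:, :, 0].ravel(),
                "ty": self.tails[:, :, 1].ravel(),
            }
        )

    def touch_label_table(self):
        """Long-format labels (frame, interactor_id, interacted_id) of true frames."""
        import pandas as pd

        t_idx, i_idx, j_idx = np.nonzero(self.touch_labels)
        return pd.DataFrame(
            {"frame": t_idx, "interactor_id": i_idx + 1, "interacted_id": j_idx + 1}
        )


def _unit(theta: float | np.ndarray) -> np.ndarray:
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def simulate_trajectories(cfg: SimConfig) -> GroundTruth:
    """Simulate smooth bounded random walks with scripted episodes.

    The motion model is an Ornstein-Uhlenbeck-like heading walk: per frame
    the heading receives Gaussian turning noise scaled by
    ``(1 - heading_persistence)`` and the speed is drawn around
    ``speed_mean``; walls reflect the heading. Scripted flies are steered
    toward their episode geometry during a lead-in window and follow the
    exact scripted geometry during the episode, so planted labels are
    frame-exact. Deterministic for a given config (seed included).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, t_max = cfg.n_flies, cfg.n_frames
    a = cfg.semi_major
    bl = cfg.body_length
    margin = a + 2.0
    lo = np.array([margin, margin])
    hi = np.array([cfg.arena_width_px - 1 - margin, cfg.arena_height_px - 1 - margin])
    if np.any(hi <= lo):
        raise ValueError("arena too small for the fly size")

    # per-frame role tables: follower -> (target, spec, kind)
    touch_by_frame: dict[int, list[TouchSpec]] = {}
    cross_by_frame: dict[int, list[CrossingSpec]] = {}
    for ep in cfg.touch_specs:
        for t in range(max(0, ep.start - _LEAD_IN), ep.start + ep.duration):
            touch_by_frame.setdefault(t, []).append(ep)
    for ep in cfg.crossing_specs:
        for t in range(max(0, ep.start - _LEAD_IN), ep.start + ep.duration):
            cross_by_frame.setdefault(t, []).append(ep)

    centers = np.empty((t_max, n, 2))
    thetas = np.empty((t_max, n))

    # initial placement: rejection-sample centers at pairwise distance > 2.5 BL
    pos = np.empty((n, 2))
    placed = 0
    while placed < n:
        cand = lo + rng.random(2) * (hi - lo)
        if placed == 0 or np.min(np.linalg.norm(pos[:placed] - cand, axis=1)) > 2.5 * bl:
            pos[placed] = cand
            placed += 1
    theta = rng.uniform(0, 2 * math.pi, size=n)
    turn_sd = (1.0 - cfg.heading_persistence) * 2.0  # radians per frame

    delta_touch = 0.6 * cfg.touch_radius  # planted head-tail separation

    centers[0] = pos
    thetas[0] = theta

    for t in range(1, t_max):
        prev = centers[t - 1]
        cur = prev.copy()
        th = thetas[t - 1].copy()

        scripted = np.zeros(n, dtype=bool)
        followers: list[tuple[int, int, str, object]] = []  # (follower, target, phase, spec)
        for ep in touch_by_frame.get(t, []):
            phase = "hold" if t >= ep.start else "approach"
            followers.append((ep.interactor - 1, ep.interacted - 1, phase, ep))
            scripted[ep.interactor - 1] = True
        for ep in cross_by_frame.get(t, []):
            phase = "hold" if t >= ep.start else "approach"
            followers.append((ep.fly_b - 1, ep.fly_a - 1, phase, ep))
            scripted[ep.fly_b - 1] = True

        # -- free flies: heading walk with wall reflection ----------------
        free = ~scripted
        n_free = int(free.sum())
        if n_free:
            th[free] += rng.normal(0.0, turn_sd, size=n_free)
            speeds = np.clip(
                rng.normal(cfg.speed_mean, cfg.speed_sd, size=n_free), 0.0, None
            )
            step = speeds[:, None] * _unit(th[free])
            nxt = prev[free] + step
            # reflect at walls
            for axis in range(2):
                low = nxt[:, axis] < lo[axis]
                high = nxt[:, axis] > hi[axis]
                nxt[low, axis] = 2 * lo[axis] - nxt[low, axis]
                nxt[high, axis] = 2 * hi[axis] - nxt[high, axis]
                if low.any() or high.any():
                    ang = th[free]
                    flip = low | high
                    if axis == 0:
                        ang[flip] = math.pi - ang[flip]
                    else:
                        ang[flip] = -ang[flip]
                    th[free] = ang
            cur[free] = np.clip(nxt, lo, hi)

        # -- soft repulsion: free flies keep clear of every other fly ------
        # (scripted flies are not displaced; only the free member moves)
        if n_free >= 1 and n > 1:
            idx = np.nonzero(free)[0]
            # scripted flies still sit at their previous position here; they
            # are placed after the free flies below
            for ii in idx:
                d = cur[ii] - cur
                dist = np.linalg.norm(d, axis=1)
                dist[ii] = np.inf
                for jj in np.nonzero(dist < 1.6 * bl)[0]:
                    nrm = dist[jj]
                    u = d[jj] / nrm if nrm > 1e-9 else _unit(rng.uniform(0, 2 * math.pi))
                    factor = 0.5 if free[jj] else 1.0
                    push = min(0.4 * factor * (1.6 * bl - nrm), 1.5)
                    cur[ii] = cur[ii] + u * push
            cur[idx] = np.clip(cur[idx], lo, hi)

        # -- scripted flies: approach then hold exact geometry ------------
        for f, tgt, phase, ep in followers:
            frames_left = ep.start - t
            # keep a standoff until the last 15 lead-in frames, then close
            # in smoothly; prevents long close-range following (id-swap bait)
            extra = 0.0 if phase == "hold" else 1.5 * bl * min(frames_left, 15) / 15
            if isinstance(ep, TouchSpec):
                tail_t = cur[tgt] - a * _unit(th[tgt])
                u_vec = tail_t - prev[f]
                nrm = np.linalg.norm(u_vec)
                u_vec = u_vec / nrm if nrm > 1e-9 else _unit(th[f])
                goal = tail_t - (a + delta_touch + extra) * u_vec
            else:
                ep_c: CrossingSpec = ep
                # offset sweeps across the target's flank, staying within
                # 60 deg of the perpendicular so the occlusion is a partial
                # side-by-side overlap rather than a full along-axis merge
                side = 1.0 if (ep_c.fly_a + ep_c.fly_b + ep_c.start) % 2 else -1.0
                if phase == "hold":
                    frac = (t - ep_c.start) / max(ep_c.duration - 1, 1)
                    mag = bl * (0.9 - 0.45 * math.sin(math.pi * frac))
                else:
                    frac, mag = 0.0, 0.9 * bl + extra
                psi = side * (math.pi / 2) + (frac - 0.5) * (2 * math.pi / 3)
                phi = math.atan2(*_unit(th[tgt])[::-1]) + psi
                goal = cur[tgt] + mag * np.array([math.cos(phi), math.sin(phi)])

            move = goal - prev[f]
            dist_goal = np.linalg.norm(move)
            if phase == "hold":
                step_len = dist_goal  # exact placement
            else:
                # guaranteed arrival: never slower than remaining dist / frames
                need = dist_goal / max(frames_left, 1)
                step_len = min(dist_goal, max(2.5 * cfg.speed_mean, 1.25 * need))
            if dist_goal > 1e-9:
                cur[f] = prev[f] + move * (step_len / dist_goal)
                th[f] = math.atan2(move[1], move[0])
            else:
                cur[f] = prev[f]
            if phase == "approach":
                # steer around uninvolved flies while closing in; keep a
                # smaller clearance from the target too (the goal is always
                # at least 0.9 body lengths from it, so this never blocks)
                d = cur[f] - cur
                dist = np.linalg.norm(d, axis=1)
                dist[f] = np.inf
                for jj in np.nonzero(dist < 1.4 * bl)[0]:
                    clear = 0.8 * bl if jj == tgt else 1.4 * bl
                    nrm = dist[jj]
                    if nrm >= clear:
                        continue
                    u = d[jj] / nrm if nrm > 1e-9 else _unit(rng.uniform(0, 2 * math.pi))
                    cur[f] = cur[f] + u * min(0.5 * (clear - nrm), 1.5)
            cur[f] = np.clip(cur[f], lo, hi)

        # touch followers: heading must point at the target tail for the
        # head-to-tail geometry to be exact during the hold phase
        for f, tgt, phase, ep in followers:
            if isinstance(ep, TouchSpec) and phase == "hold":
                tail_t = cur[tgt] - a * _unit(th[tgt])
                v = tail_t - cur[f]
                nrm = np.linalg.norm(v)
                if nrm > 1e-9:
                    th[f] = math.atan2(v[1], v[0])
                    cur[f] = tail_t - (a + delta_touch) * (v / nrm)

        centers[t] = cur
        thetas[t] = th

    heads = centers + a * _unit(thetas)
    tails = centers - a * _unit(thetas)

    touch_labels = np.zeros((t_max, n, n), dtype=bool)
    for ep in cfg.touch_specs:
        sl = slice(ep.start, ep.start + ep.duration)
        touch_labels[sl, ep.interactor - 1, ep.interacted - 1] = True
    crossing_frames = [
        (t, (ep.fly_a, ep.fly_b))
        for ep in cfg.crossing_specs
        for t in range(ep.start, ep.start + ep.duration)
    ]

    gt = GroundTruth(cfg, centers, heads, tails, touch_labels, crossing_frames)
    _check_touch_geometry(gt)
    return gt



def _check_touch_geometry(gt: GroundTruth) -> None:
    r = gt.cfg.touch_radius
    for ep in gt.cfg.touch_specs:
        # the first scripted frame may still carry approach residue when the
        # episode starts at frame 0 (no lead-in exists before the video)
        t0 = max(ep.start, 1)
        d = np.linalg.norm(
            gt.heads[t0 : ep.start + ep.duration, ep.interactor - 1]
            - gt.tails[t0 : ep.start + ep.duration, ep.interacted - 1],
            axis=1,
        )
        if np.any(d > r + 1e-6):
            raise RuntimeError(
                f"planted touch episode {ep} violates the touch radius "
                f"(max head-tail distance {d.max():.2f} > {r:.2f})"
            )


class RenderedVideo:
    """Lazy frame sequence rendered from a :class:`GroundTruth`.

    Behaves like an indexable sequence of uint8 2-D arrays; frames are
    rasterized on demand so long videos never reside in memory at once.
    """

    def __init__(self, gt: GroundTruth, cfg: SimConfig | None = None):
        self.gt = gt
        self.cfg = cfg or gt.cfg
        self._h = self.cfg.arena_height_px
        self._w = self.cfg.arena_width_px

    def __len__(self) -> int:
        return self.gt.n_frames

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self), self._h, self._w)

    def empty_frame(self) -> np.ndarray:
        """The arena with no flies — the renderer's true background."""
        return np.full((self._h, self._w), self.cfg.background_level, dtype=np.uint8)

    def __getitem__(self, t):
        if isinstance(t, slice):
            return [self[i] for i in range(*t.indices(len(self)))]
        if t < 0:
            t += len(self)
        if not 0 <= t < len(self):
            raise IndexError(t)
        frame = self.empty_frame()
        cfg = self.cfg
        a, b = cfg.semi_major, cfg.semi_minor
        for f in range(self.gt.n_flies):
            cx, cy = self.gt.centers[t, f]
            hx, hy = self.gt.heads[t, f]
            ux, uy = (hx - cx), (hy - cy)
            nrm = math.hypot(ux, uy)
            if nrm < 1e-9:
                ux, uy = 1.0, 0.0
            else:
                ux, uy = ux / nrm, uy / nrm
            _fill_ellipse(frame, cx, cy, a, b, ux, uy, cfg.fly_level)
        if cfg.noise_sd > 0:
            rng = np.random.default_rng((cfg.seed, 0xF0F0, t))
            noisy = frame.astype(np.float64) + rng.normal(0, cfg.noise_sd, frame.shape)
            frame = np.clip(noisy, 0, 255).astype(np.uint8)
        return frame

    def __iter__(self):
        for t in range(len(self)):
            yield self[t]


def _fill_ellipse(img, cx, cy, a, b, ux, uy, value):
    """Rasterize a filled rotated ellipse by testing pixel centers in a
    local bounding patch (axis-aligned extent of the rotated ellipse)."""
    h, w = img.shape
    ext = max(a, b) + 1.0
    x0, x1 = max(0, int(cx - ext)), min(w - 1, int(cx + ext) + 1)
    y0, y1 = max(0, int(cy - ext)), min(h - 1, int(cy + ext) + 1)
    if x1 < x0 or y1 < y0:
        return
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - cx
    dy = ys - cy
    along = dx * ux + dy * uy
    across = -dx * uy + dy * ux
    mask = (along / a) ** 2 + (across / b) ** 2 <= 1.0
    img[ys[mask], xs[mask]] = value


def render_frames(gt: GroundTruth, cfg: SimConfig | None = None) -> RenderedVideo:
    """Render the ground truth as a lazy dark-background frame sequence."""
    return RenderedVideo(gt, cfg)


# ---------------------------------------------------------------------------
# episode scripting helpers
# ---------------------------------------------------------------------------

def random_episode_specs(
    n_flies: int,
    n_touch: int,
    n_crossings: int,
    n_frames: int,
    touch_duration: int = 20,
    crossing_duration: int = 12,
    min_gap: int = 60,
    rng: np.random.Generator | int | None = None,
) -> tuple[tuple[TouchSpec, ...], tuple[CrossingSpec, ...]]:
    """Script non-conflicting touch and crossing episodes together.

    A single occupancy ledger guarantees that no fly participates in two
    time-overlapping episodes of either kind (lead-in windows included),
    and repeat touches of the same ordered pair are separated by at least
    ``min_gap`` frames so each planted interaction stays a distinct
    maximal run.
    """
    rng = np.random.default_rng(rng)
    touches: list[TouchSpec] = []
    crossings: list[CrossingSpec] = []
    busy: list[tuple[int, int, int]] = []  # (fly, t_start, t_end) occupancy

    def place(duration: int, pad_after: int):
        for _ in range(4000):
            i, j = rng.choice(n_flies, size=2, replace=False) + 1
            start = int(rng.integers(_LEAD_IN + 10, n_frames - duration - 10))
            t0, t1 = start - _LEAD_IN, start + duration + pad_after
            if any(f in (i, j) and not (t1 < b0 or t0 > b1) for f, b0, b1 in busy):
                continue
            return int(i), int(j), start, t0, t1
        raise RuntimeError("could not place the requested episodes")

    for _ in range(n_touch):
        while True:
            i, j, start, t0, t1 = place(touch_duration, min_gap // 2)
            if not any(
                s.interactor == i and s.interacted == j
                and abs(s.start - start) < s.duration + touch_duration + min_gap
                for s in touches
            ):
                break
        touches.append(TouchSpec(i, j, start, touch_duration))
        busy += [(i, t0, t1), (j, t0, t1)]
    for _ in range(n_crossings):
        a, b, start, t0, t1 = place(crossing_duration, 20)
        crossings.append(CrossingSpec(a, b, start, crossing_duration))
        busy += [(a, t0, t1), (b, t0, t1)]
    return tuple(touches), tuple(crossings)


def random_touch_specs(
    n_flies: int,
    n_episodes: int,
    n_frames: int,
    duration: int = 20,
    min_gap: int = 60,
    rng: np.random.Generator | int | None = None,
) -> tuple[TouchSpec, ...]:
    """Script non-conflicting touch episodes (no crossings)."""
    touches, _ = random_episode_specs(
        n_flies, n_episodes, 0, n_frames,
        touch_duration=duration, min_gap=min_gap, rng=rng,
    )
    return touches


def random_crossing_specs(
    n_flies: int,
    n_episodes: int,
    n_frames: int,
    duration: int = 12,
    rng: np.random.Generator | int | None = None,
) -> tuple[CrossingSpec, ...]:
    """Script non-conflicting crossing (occlusion) episodes (no touches)."""
    _, crossings = random_episode_specs(
        n_flies, 0, n_episodes, n_frames,
        crossing_duration=duration, rng=rng,
    )
    return crossings
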