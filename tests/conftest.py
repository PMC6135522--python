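"""Shared fixtures: synthetic videos and a trained touch classifier.

Everything is generated programmatically and seeded; session scope keeps
the expensive pieces (tracked videos, classifier training) to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from flysoc.interaction import build_training_set, train_classifier
from flysoc.simulate import (
    SimConfig,
    random_episode_specs,
    render_frames,
    simulate_trajectories,
)
from flysoc.tracking import TrackConfig, TrackSet, track_video


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """8 flies, 600 frames, 3 touches + 2 crossings in a 400x300 arena."""
    touches, crossings = random_episode_specs(8, 3, 2, 600, rng=100)
    return SimConfig(
        n_flies=8, n_frames=600, seed=0,
        arena_width_px=400, arena_height_px=300,
        touch_specs=touches, crossing_specs=crossings,
    )


@pytest.fixture(scope="session")
def small_gt(small_cfg):
    return simulate_trajectories(small_cfg)


@pytest.fixture(scope="session")
def small_video(small_gt):
    return render_frames(small_gt)


@pytest.fixture(scope="session")
def small_tracks(small_video, small_cfg) -> TrackSet:
    return track_video(small_video, TrackConfig(n_flies=small_cfg.n_flies))


@pytest.fixture(scope="session")
def plain_cfg() -> SimConfig:
    """6 flies, 300 frames, no scripted episodes."""
    return SimConfig(
        n_flies=6, n_frames=300, seed=5,
        arena_width_px=400, arena_height_px=300,
    )


@pytest.fixture(scope="session")
def plain_gt(plain_cfg):
    return simulate_trajectories(plain_cfg)


@pytest.fixture(scope="session")
def plain_video(plain_gt):
    return render_frames(plain_gt)


@pytest.fixture(scope="session")
def training_sim():
    """Labelled trajectory set rich in planted touches, for training."""
    touches, _ = random_episode_specs(16, 40, 0, 1800, rng=999)
    cfg = SimConfig(
        n_flies=16, n_frames=1800, seed=555,
        arena_width_px=480, arena_height_px=360, touch_specs=touches,
    )
    gt = simulate_trajectories(cfg)
    ts = TrackSet(centers=gt.centers, heads=gt.heads, tails=gt.tails)
    return gt, ts


@pytest.fixture(scope="session")
def touch_model(training_sim):
    gt, ts = training_sim
    x, y = build_training_set(ts, gt.touch_labels, n_per_class=700, rng=1)
    return train_classifier(x, y, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
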