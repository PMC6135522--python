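"""File formats, run configuration and format validators.

Interchange dialect: UTF-8 comma-separated CSV with a header row and
"." decimals; frames are 0-based, fly ids 1-based, coordinates in pixels
with origin top-left, x right / y down. Every artifact written here
embeds the hash of the configuration that produced it as a leading
``#`` comment line; readers skip comment lines, so round trips are
bit-exact on the data.

Video containers: multi-page TIFF stacks (read/written via tifffile)
are the native container; other containers are attempted through
imageio when a suitable plugin is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["frame", "fly_id", "cx", "cy", "hx", "hy", "tx", "ty"]
EVENT_COLUMNS = ["interactor_id", "interacted_id", "start_frame", "end_frame"]
LABEL_COLUMNS = ["frame", "interactor_id", "interacted_id", "label"]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULTS: dict = {
    "simulate.arena_width_px": 640,
    "simulate.arena_height_px": 480,
    "simulate.n_flies": 16,
    "simulate.n_frames": 600,
    "simulate.fps": 30.0,
    "simulate.fly_area_px": 20.0,
    "simulate.speed_mean": 1.0,
    "simulate.speed_sd": 0.3,
    "simulate.heading_persistence": 0.9,
    "simulate.touch_radius_bl": 0.5,
    "simulate.noise_sd": 0.0,
    "simulate.seed": 0,
    "detection.threshold": None,
    "detection.min_area": 4,
    "detection.merge_factor": 1.5,
    "detection.background_stride": 20,
    "tracking.orient_window": 5,
    "tracking.speed_floor": 0.2,
    "tracking.em_seed": 0,
    "interaction.min_run": 15,
    "interaction.min_gap": 15,
    "interaction.candidate_radius_bl": 3.0,
    "interaction.train_seed": 0,
    "avgnet.beta0": 0.5,
    "avgnet.rate": 1.075,
    "avgnet.beta_max": 10.0,
    "avgnet.sinkhorn_iters": 30,
    "stats.correlation_method": "pearson",
    "stats.alpha": 0.01,
}


@dataclass
class RunConfig:
    """Flat namespaced key-value configuration shared by all stages."""

    values: dict = field(default_factory=lambda: dict(DEFAULTS))

    def __post_init__(self):
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a key-value mapping")
        return cls(values=data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header_comment(config: RunConfig | None) -> str:
    h = (config or RunConfig()).config_hash
    return f"# flysoc config_hash={h}\n"


def _write_csv(df: pd.DataFrame, path, config: RunConfig | None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectories(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    validate_trajectories(df)
    _write_csv(df[TRAJECTORY_COLUMNS], path, config)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_trajectories(df)
    return df


def validate_trajectories(df: pd.DataFrame) -> None:
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    dup = df.duplicated(["frame", "fly_id"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"duplicate (frame, fly_id) rows: {rows}")
    per_frame = df.groupby("frame")["fly_id"].count()
    if per_frame.nunique() > 1:
        raise ValueError("incomplete table: unequal fly counts across frames")


# ---------------------------------------------------------------------------
# interaction events and labels
# ---------------------------------------------------------------------------

def events_to_table(events) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "interactor_id": ev.interactor_id,
                "interacted_id": ev.interacted_id,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    )


def table_to_events(df: pd.DataFrame):
    from .interaction import TouchInteraction

    return [
        TouchInteraction(
            int(r.interactor_id), int(r.interacted_id),
            int(r.start_frame), int(r.end_frame),
        )
        for r in df.itertuples()
    ]


def write_events(events, path, config: RunConfig | None = None) -> None:
    df = events_to_table(events)
    validate_events(df)
    _write_csv(df, path, config)


def read_events(path):
    df = pd.read_csv(path, comment="#")
    validate_events(df)
    return table_to_events(df)


def validate_events(df: pd.DataFrame) -> None:
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if (df["end_frame"] < df["start_frame"]).any():
        raise ValueError("events with end_frame < start_frame")
    if (df["interactor_id"] == df["interacted_id"]).any():
        raise ValueError("self-interaction events are invalid")
    for (_, _), grp in df.groupby(["interactor_id", "interacted_id"]):
        g = grp.sort_values("start_frame")
        overlap = g["start_frame"].iloc[1:].to_numpy() <= g["end_frame"].iloc[:-1].to_numpy()
        if overlap.any():
            raise ValueError(
                "overlapping intervals for the same ordered pair: "
                f"{g.iloc[:5].to_dict('records')}"
            )


def write_labels(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    _write_csv(df[LABEL_COLUMNS], path, config)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# adjacency matrices and network export
# ---------------------------------------------------------------------------

def write_adjacency(net, path, config: RunConfig | None = None) -> None:
    """N x N integer count matrix with a header row of fly ids."""
    df = pd.DataFrame(net.counts, columns=[str(i) for i in net.fly_ids])
    _write_csv(df, path, config)


def read_adjacency(path):
    from .network import SocialNetwork

    df = pd.read_csv(path, comment="#")
    fly_ids = np.array([int(c) for c in df.columns])
    return SocialNetwork(df.to_numpy(dtype=int), fly_ids=fly_ids)


def write_graphml(net, path) -> None:
    import networkx as nx

    g = net.to_digraph()
    relabel = {i: int(net.fly_ids[i]) for i in range(net.n)}
    nx.write_graphml(nx.relabel_nodes(g, relabel), path)


# ---------------------------------------------------------------------------
# video containers
# ---------------------------------------------------------------------------

def write_video(frames, path) -> None:
    """Write a grayscale frame sequence; ``.tif``/``.tiff`` natively,
    other containers through imageio when a plugin supports them."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffWriter(path) as tw:
            for frame in frames:
                tw.write(np.asarray(frame, dtype=np.uint8), contiguous=True)
        return
    import imageio.v3 as iio

    iio.imwrite(path, np.stack([np.asarray(f, dtype=np.uint8) for f in frames]))


def read_video(path):
    """Load a video as a (T, H, W) uint8 array of grayscale frames."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise IOError(f"unreadable or corrupt video {path}: {exc}") from exc
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise IOError(f"unreadable video {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1).astype(np.uint8)
    return arr
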