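"""Frame segmentation into fly-candidate blobs.

Flies appear as bright connected components on a dark background. The
background is modelled as the per-pixel temporal median of sampled frames;
foreground pixels are those whose absolute difference from the background
exceeds a threshold (Otsu on the difference histogram by default).
Components use 8-connectivity — 4-connectivity breaks thin fly bodies at
the ~20 px scale — and components smaller than ``min_area`` pixels are
discarded as sensor noise.

A frame holding fewer blobs than flies contains merged (multi-fly)
components; these are flagged by the area rule and finally resolved by the
tracking assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)

DEFAULT_MIN_AREA = 4
DEFAULT_MERGE_FACTOR = 1.5


@dataclass
class Blob:
    """One connected component of a segmented frame."""

    centroid: np.ndarray          # (x, y) pixel coordinates
    area: int                     # pixel count
    pixels: np.ndarray            # (area, 2) int array of (x, y)
    major_axis: np.ndarray        # unit vector of the principal axis
    semi_major: float             # half-length estimate along the axis

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "Blob":
        pixels = np.asarray(pixels)
        centroid = pixels.mean(axis=0)
        axis, semi = principal_axis(pixels)
        return cls(centroid=centroid, area=len(pixels), pixels=pixels,
                   major_axis=axis, semi_major=semi)


@dataclass
class BlobSet:
    frame_index: int
    blobs: list[Blob] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blobs)

    @property
    def centroids(self) -> np.ndarray:
        if not self.blobs:
            return np.empty((0, 2))
        return np.array([b.centroid for b in self.blobs])

    @property
    def areas(self) -> np.ndarray:
        return np.array([b.area for b in self.blobs], dtype=int)


def principal_axis(pixels: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal axis of a pixel set and its semi-length.

    For a solid ellipse of semi-major a, the leading eigenvalue of the
    pixel covariance is a^2/4, so the semi-length estimate is 2*sqrt(l1).
    Degenerate (single-pixel) blobs return the x unit vector and length 0.
    """
    pts = np.asarray(pixels, dtype=float)
    if len(pts) < 2:
        return np.array([1.0, 0.0]), 0.0
    cov = np.cov(pts.T, bias=True)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    semi = 2.0 * np.sqrt(max(vals[-1], 0.0))
    return axis / np.linalg.norm(axis), float(semi)


def build_background(frames, sample_stride: int = 20) -> np.ndarray:
    """Per-pixel temporal median over frames sampled every ``sample_stride``.

    With a single available frame the frame itself is returned with a
    warning (segmentation then degenerates to a global threshold on it).
    """
    n = len(frames)
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    if sample_stride >= n and n > 1:
        raise ValueError(
            f"sample_stride {sample_stride} leaves < 2 of {n} frames to sample"
        )
    idx = range(0, n, sample_stride)
    sample = np.stack([np.asarray(frames[i], dtype=np.uint8) for i in idx])
    if sample.shape[0] < 2:
        warnings.warn("single-frame background: falling back to the frame itself")
        return sample[0]
    return np.median(sample, axis=0).astype(np.uint8)


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    frame_index: int = 0,
) -> BlobSet:
    """Background-subtract, threshold and extract 8-connected components.

    ``threshold=None`` selects Otsu's threshold on the difference image.
    Components below ``min_area`` pixels are dropped as noise.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = np.abs(frame.astype(np.int16) - background.astype(np.int16))
    if threshold is None:
        if diff.max() == 0:
            return BlobSet(frame_index=frame_index)
        threshold = threshold_otsu(diff)
    fg = diff > threshold
    labels, n_labels = ndi.label(fg, structure=_EIGHT_CONN)
    blobs = []
    for sl_idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = np.nonzero(labels[sl] == sl_idx)
        if len(ys) < min_area:
            continue
        pix = np.column_stack([xs + sl[1].start, ys + sl[0].start])
        blobs.append(Blob.from_pixels(pix))
    return BlobSet(frame_index=frame_index, blobs=blobs)


def estimate_fly_area(blobsets: list[BlobSet], n_flies: int) -> float:
    """Median blob area over frames whose blob count equals ``n_flies``.

    Merged frames are excluded by construction; raises if no frame shows
    all flies separated (a typical-area config value must then be given).
    """
    areas: list[int] = []
    for bs in blobsets:
        if len(bs) == n_flies:
            areas.extend(int(b.area) for b in bs.blobs)
    if not areas:
        raise ValueError(
            "no frame with exactly n_flies blobs; supply typical_area manually"
        )
    return float(np.median(areas))


def flag_merged(
    bs: BlobSet,
    n_flies: int,
    typical_area: float,
    merge_factor: float = DEFAULT_MERGE_FACTOR,
) -> np.ndarray:
    """Provisional per-blob fly multiplicities.

    With a full complement of blobs every multiplicity is 1. Otherwise
    blobs with area > merge_factor * typical_area are candidates to host
    the missing flies; the final counts come from the tracking assignment.
    Extra blobs (count > n_flies) are resolved by keeping the n largest.
    """
    if typical_area <= 0:
        raise ValueError("typical_area must be > 0")
    count = len(bs)
    if count > n_flies:
        logger.warning(
            "frame %d: %d blobs for %d flies; keeping the %d largest",
            bs.frame_index, count, n_flies, n_flies,
        )
        order = np.argsort(-bs.areas, kind="stable")[:n_flies]
        bs.blobs = [bs.blobs[i] for i in sorted(order)]
        count = n_flies
    mult = np.ones(count, dtype=int)
    missing = n_flies - count
    if missing <= 0:
        return mult
    areas = bs.areas.astype(float)
    candidates = np.nonzero(areas > merge_factor * typical_area)[0]
    if candidates.size == 0:
        logger.warning(
            "frame %d: %d missing blobs but no merged candidate by area; "
            "duplicating the largest blobs", bs.frame_index, missing,
        )
        candidates = np.arange(count)
    # distribute duplicates over candidates in proportion to excess area:
    # repeatedly grant to the candidate with the largest per-slot excess,
    # ties by larger area then lower index
    excess = np.maximum(areas[candidates] - typical_area, 1e-9)
    for _ in range(missing):
        score = excess / mult[candidates]
        best = np.lexsort((candidates, -areas[candidates], -score))[0]
        mult[candidates[best]] += 1
    return mult
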