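"""Nearest-neighbour centroid tracking and per-track motility metrics.

Frame-to-frame linking is greedy and distance-sorted: all candidate pairs
within ``max_dist`` are sorted by distance (ties broken by lower previous,
then lower next, label index) and accepted while both endpoints are free.
Detections left unmatched start new tracks; tracks with no match
terminate — there is no gap closing, so a missed detection splits a
trajectory.

"Total displacement" is the cumulative path length; the net start-to-end
displacement is reported separately.  Mean velocity is path length divided
by elapsed time, in px/s, or um/s when the recording is calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .detection import MaskStack, label_regions
from .stack_io import ChannelConfig

__all__ = [
    "TrackingParams",
    "Track",
    "link_frames",
    "build_tracks",
    "motility_metrics",
    "tracks_table",
    "motility_table",
    "per_frame_speed_table",
]


@dataclass(frozen=True)
class TrackingParams:
    """max_dist: largest allowed frame-to-frame jump, in pixels."""

    max_dist: float = 10.0

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")


@dataclass
class Track:
    """One organelle's linked centroid sequence.

    points are (frame, x, y) with frames strictly consecutive.
    """

    track_id: int
    organelle_class: str
    points: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def step_lengths(self) -> np.ndarray:
        pts = np.asarray([(x, y) for _, x, y in self.points], dtype=float)
        if len(pts) < 2:
            return np.empty(0)
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    @property
    def total_displacement(self) -> float:
        return float(self.step_lengths().sum())

    @property
    def net_displacement(self) -> float:
        if len(self.points) < 2:
            return 0.0
        _, x0, y0 = self.points[0]
        _, x1, y1 = self.points[-1]
        return math.hypot(x1 - x0, y1 - y0)


def link_frames(
    prev: list[tuple[float, float]],
    next: list[tuple[float, float]],
    params: TrackingParams,
) -> list[int]:
    """Greedy nearest-neighbour assignment of *next* centroids to *prev*.

    Returns, for each next-centroid index, the matched prev index or -1
    (start of a new track).  Candidate pairs within ``max_dist`` are taken
    in increasing distance order; exact ties fall to the lower label index.
    """
    assign = [-1] * len(next)
    if not prev or not next:
        return assign
    d = cdist(np.asarray(prev, dtype=float), np.asarray(next, dtype=float))
    pairs = [
        (d[i, j], i, j)
        for i in range(len(prev))
        for j in range(len(next))
        if d[i, j] <= params.max_dist
    ]
    pairs.sort()
    prev_used = set()
    for dist, i, j in pairs:
        if i in prev_used or assign[j] != -1:
            continue
        assign[j] = i
        prev_used.add(i)
    return assign


def build_tracks(masks: MaskStack, params: TrackingParams) -> list[Track]:
    """Link per-frame component centroids into tracks across the stack.

    Every detection belongs to exactly one track; track ids are assigned in
    order of creation (frame, then label).
    """
    tracks: list[Track] = []
    active: list[Track] = []  # active[i] corresponds to prev centroid i
    prev_centroids: list[tuple[float, float]] = []
    for t in range(masks.n_frames):
        centroids = [r.centroid_xy for r in label_regions(masks.masks[t])]
        assign = link_frames(prev_centroids, centroids, params)
        new_active: list[Track] = []
        for j, (cx, cy) in enumerate(centroids):
            if assign[j] >= 0:
                tr = active[assign[j]]
            else:
                tr = Track(track_id=len(tracks), organelle_class=masks.organelle_class)
                tracks.append(tr)
            tr.points.append((t, cx, cy))
            new_active.append(tr)
        active = new_active
        prev_centroids = centroids
    return tracks


def motility_metrics(track: Track, config: ChannelConfig) -> dict:
    """Motility summary row for one track.

    Lengths are converted to micrometres when ``pixel_size_um`` is set
    (using the post-upscaling pixel size); otherwise pixels.  Mean velocity
    is path length over elapsed time; single-point tracks report zeros.
    """
    if track.n_points == 0:
        raise ValueError("empty track")
    scale = config.effective_pixel_size_um
    unit = "um" if scale is not None else "px"
    s = scale if scale is not None else 1.0
    total = track.total_displacement * s
    net = track.net_displacement * s
    elapsed = (track.n_points - 1) * config.frame_interval_s
    velocity = total / elapsed if elapsed > 0 else 0.0
    return {
        "track_id": track.track_id,
        "organelle": track.organelle_class,
        "n_points": track.n_points,
        "total_displacement": total,
        "net_displacement": net,
        "mean_velocity": velocity,
        "unit": unit,
    }


def tracks_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format coordinates: ``track_id,frame,x,y``."""
    rows = [
        {"track_id": tr.track_id, "frame": f, "x": x, "y": y}
        for tr in tracks
        for f, x, y in tr.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])


def motility_table(tracks: list[Track], config: ChannelConfig) -> pd.DataFrame:
    cols = ["track_id", "organelle", "n_points", "total_displacement",
            "net_displacement", "mean_velocity", "unit"]
    return pd.DataFrame([motility_metrics(tr, config) for tr in tracks], columns=cols)


def per_frame_speed_table(tracks: list[Track], config: ChannelConfig, n_frames: int) -> pd.DataFrame:
    """Mean instantaneous speed per frame (step assigned to its later frame).

    Frames with no step (including frame 0) report NaN, not a missing row,
    so frame coverage is preserved for downstream joins.
    """
    scale = config.effective_pixel_size_um or 1.0
    sums = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    for tr in tracks:
        steps = tr.step_lengths()
        for (frame, _, _), step in zip(tr.points[1:], steps):
            sums[frame] += step
            counts[frame] += 1
    with np.errstate(invalid="ignore"):
        speed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    speed = speed * scale / config.frame_interval_s
    return pd.DataFrame({"frame": np.arange(n_frames), "mean_speed": speed})
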