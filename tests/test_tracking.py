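import math

import numpy as np
import pytest

from organelletrack.detection import MaskStack, label_regions
from organelletrack.stack_io import ChannelConfig
from organelletrack.synthetic import generate_stack, get_preset
from organelletrack.tracking import (
    Track,
    TrackingParams,
    build_tracks,
    link_frames,
    motility_metrics,
    tracks_table,
)

from conftest import greedy_assignment_oracle, raster_disc

P5 = TrackingParams(max_dist=5.0)


def test_link_within_gate():
    assert link_frames([(10, 10)], [(13, 10)], P5) == [0]


def test_link_outside_gate_starts_new_track():
    assert link_frames([(10, 10)], [(17, 10)], P5) == [-1]


def test_conflict_smaller_distance_wins():
    # next-centroids at distances 2 and 4 from the same prev-centroid
    assign = link_frames([(10.0, 10.0)], [(12.0, 10.0), (14.0, 10.0)], P5)
    assert assign == [0, -1]


def test_exact_tie_broken_by_lower_label_index():
    assign = link_frames([(10.0, 10.0)], [(13.0, 10.0), (7.0, 10.0)], P5)
    assert assign == [0, -1]  # equal 3-px distances: next index 0 wins


def test_empty_lists_terminate_or_start_all():
    assert link_frames([], [(1, 1), (2, 2)], P5) == [-1, -1]
    assert link_frames([(1, 1)], [], P5) == []


def test_link_matches_greedy_assignment_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n_prev, n_next = rng.integers(0, 7, size=2)
        prev = [tuple(p) for p in rng.uniform(0, 30, size=(n_prev, 2))]
        nxt = [tuple(p) for p in rng.uniform(0, 30, size=(n_next, 2))]
        params = TrackingParams(max_dist=float(rng.uniform(2, 15)))
        assert link_frames(prev, nxt, params) == greedy_assignment_oracle(
            prev, nxt, params.max_dist
        )


def _mask_stack(frames_of_centers, shape=(128, 128), radius=4):
    frames = []
    for centers in frames_of_centers:
        frame = np.zeros(shape, dtype=bool)
        for c in centers:
            frame |= raster_disc(shape, c, radius)
        frames.append(frame)
    return MaskStack(masks=np.stack(frames), organelle_class="mito")


def test_stationary_objects_one_track_each():
    centers = [(20, 20), (60, 20), (100, 20), (20, 80), (60, 80)]
    masks = _mask_stack([centers] * 10)
    tracks = build_tracks(masks, TrackingParams(max_dist=10))
    assert len(tracks) == 5
    assert all(tr.n_points == 10 for tr in tracks)


def test_object_in_single_frame_gives_single_point_track():
    masks = _mask_stack([[(30, 30)], [], []])
    tracks = build_tracks(masks, P5)
    assert len(tracks) == 1
    assert tracks[0].n_points == 1
    assert motility_metrics(tracks[0], ChannelConfig())["mean_velocity"] == 0.0


def test_linear_motion_recovered_exactly():
    """Planted 2 px/frame linear trajectories come back point-for-point."""
    starts = [(20.0, 20.0), (20.0, 60.0), (20.0, 100.0)]
    frames = [[(x0 + 2.0 * t, y0) for x0, y0 in starts] for t in range(10)]
    masks = _mask_stack(frames)
    tracks = build_tracks(masks, P5)
    assert len(tracks) == 3
    by_y = sorted(tracks, key=lambda tr: tr.points[0][2])
    for tr, (x0, y0) in zip(by_y, starts):
        for t, x, y in tr.points:
            assert math.isclose(x, x0 + 2.0 * t, abs_tol=1e-9)
            assert math.isclose(y, y0, abs_tol=1e-9)


def test_detection_conservation_across_tracks():
    stack, _ = generate_stack(get_preset("tracking"))
    from organelletrack.detection import SegmentationParams, segment_stack
    from organelletrack.stack_io import preprocess

    pp = preprocess(stack, ChannelConfig())
    masks = segment_stack(pp, 0, SegmentationParams(), "mito")
    tracks = build_tracks(masks, TrackingParams(max_dist=10))
    n_detections = sum(len(label_regions(masks.masks[t])) for t in range(masks.n_frames))
    assert sum(tr.n_points for tr in tracks) == n_detections
    for tr in tracks:
        frames = [f for f, _, _ in tr.points]
        assert frames == list(range(frames[0], frames[0] + len(frames)))
        assert (tr.step_lengths() <= 10 + 1e-9).all()


def _track(points):
    return Track(track_id=0, organelle_class="mito", points=points)


def test_motility_arithmetic_constant_speed():
    # 2 px/frame over 10 frames (9 steps) at 5 s/frame
    tr = _track([(t, 2.0 * t, 0.0) for t in range(10)])
    row = motility_metrics(tr, ChannelConfig(frame_interval_s=5.0))
    assert row["total_displacement"] == pytest.approx(18.0)
    assert row["mean_velocity"] == pytest.approx(0.4)
    assert row["unit"] == "px"


def test_motility_stationary_track_zeros():
    tr = _track([(t, 7.0, 7.0) for t in range(10)])
    row = motility_metrics(tr, ChannelConfig())
    assert row["total_displacement"] == 0.0
    assert row["mean_velocity"] == 0.0


def test_square_loop_net_zero_total_perimeter():
    pts = [(0, 0.0, 0.0), (1, 4.0, 0.0), (2, 4.0, 4.0), (3, 0.0, 4.0), (4, 0.0, 0.0)]
    tr = _track(pts)
    row = motility_metrics(tr, ChannelConfig(frame_interval_s=1.0))
    assert row["net_displacement"] == 0.0
    assert row["total_displacement"] == pytest.approx(16.0)


def test_micrometre_units_when_calibrated():
    tr = _track([(t, 2.0 * t, 0.0) for t in range(10)])
    cfg = ChannelConfig(frame_interval_s=5.0, pixel_size_um=0.1)
    row = motility_metrics(tr, cfg)
    assert row["unit"] == "um"
    assert row["total_displacement"] == pytest.approx(1.8)
    assert row["mean_velocity"] == pytest.approx(0.04)


def test_mean_speed_recovered_under_centroid_jitter():
    """Constant-velocity tracks with sigma=0.3 px centroid jitter: the
    estimated mean speed stays within 5% of the planted speed."""
    rng = np.random.default_rng(99)
    speed, n_frames, interval = 3.0, 20, 5.0
    cfg = ChannelConfig(frame_interval_s=interval)
    ratios = []
    for _ in range(50):
        prev = None
        pts = []
        for t in range(n_frames):
            x = 10.0 + speed * t + rng.normal(0, 0.3)
            y = 50.0 + rng.normal(0, 0.3)
            pts.append((t, x, y))
        tr = _track(pts)
        row = motility_metrics(tr, cfg)
        ratios.append(row["mean_velocity"] / (speed / interval))
    assert abs(np.mean(ratios) - 1.0) < 0.05


def test_tracks_table_columns(counting_run):
    import pandas as pd

    df = pd.read_csv(counting_run["out"] / "Mito_Tracks.csv")
    assert list(df.columns) == ["track_id", "frame", "x", "y"]
    assert df.groupby("track_id").size().min() >= 1
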