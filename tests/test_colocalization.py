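import math

import numpy as np
import pytest

from organelletrack.colocalization import (
    coloc_table,
    coloc_timeseries,
    manders_from_masks,
    pearson_from_masks,
    percent_overlap,
)
from organelletrack.detection import MaskStack
from organelletrack.synthetic import generate_stack, get_preset

from conftest import coloc_by_counting, raster_disc


def _stack(frames, cls):
    return MaskStack(masks=np.stack(frames), organelle_class=cls)


def test_identical_masks_full_colocalization():
    m = raster_disc((32, 32), (16, 16), 6)
    assert manders_from_masks(m, m) == (1.0, 1.0)
    assert pearson_from_masks(m, m) == pytest.approx(1.0)
    assert percent_overlap(m, m) == pytest.approx(100.0)


def test_disjoint_masks_zero_colocalization():
    a = raster_disc((32, 32), (8, 8), 4)
    b = raster_disc((32, 32), (24, 24), 4)
    assert manders_from_masks(a, b) == (0.0, 0.0)
    assert percent_overlap(a, b) == 0.0


def test_subset_mask_manders_asymmetry():
    a = np.zeros((16, 16), dtype=bool)
    b = np.zeros((16, 16), dtype=bool)
    a.ravel()[:10] = True
    b.ravel()[:40] = True
    m1, m2 = manders_from_masks(a, b)
    assert m1 == pytest.approx(1.0)
    assert m2 == pytest.approx(0.25)


def test_phi_of_complement_masks_is_minus_one():
    a = np.zeros((8, 8), dtype=bool)
    a[:4] = True
    assert pearson_from_masks(a, ~a) == pytest.approx(-1.0)


def test_phi_balanced_two_by_two_table_is_zero():
    # 4 pixels, A = {p1,p2}, B = {p2,p3}: contingency (1,1,1,1) -> phi 0
    a = np.array([[True, True], [False, False]])
    b = np.array([[False, True], [True, False]])
    assert pearson_from_masks(a, b) == pytest.approx(0.0)


def test_phi_undefined_for_constant_mask():
    a = np.ones((4, 4), dtype=bool)
    b = raster_disc((4, 4), (2, 2), 1)
    assert math.isnan(pearson_from_masks(a, b))
    assert math.isnan(pearson_from_masks(b, np.zeros((4, 4), bool)))


def test_percent_overlap_jaccard_value():
    a = np.zeros((10, 10), dtype=bool)
    b = np.zeros((10, 10), dtype=bool)
    a.ravel()[:30] = True
    b.ravel()[10:40] = True  # |A|=|B|=30, inter 20, union 40
    assert percent_overlap(a, b) == pytest.approx(50.0)


def test_shape_mismatch_raises():
    a = np.zeros((8, 8), dtype=bool)
    b = np.zeros((8, 9), dtype=bool)
    for fn in (manders_from_masks, pearson_from_masks, percent_overlap):
        with pytest.raises(ValueError, match="shape mismatch"):
            fn(a, b)


def test_all_metrics_match_counting_oracle():
    rng = np.random.default_rng(21)
    for _ in range(200):
        a = rng.random((16, 16)) < rng.uniform(0.05, 0.9)
        b = rng.random((16, 16)) < rng.uniform(0.05, 0.9)
        m1, m2 = manders_from_masks(a, b)
        phi = pearson_from_masks(a, b)
        pct = percent_overlap(a, b)
        om1, om2, ophi, opct = coloc_by_counting(a, b)
        assert m1 == pytest.approx(om1, abs=1e-12)
        assert m2 == pytest.approx(om2, abs=1e-12)
        assert pct == pytest.approx(opct, abs=1e-12)
        if math.isnan(ophi):
            assert math.isnan(phi)
        else:
            assert phi == pytest.approx(ophi, abs=1e-12)


def test_swap_symmetry():
    rng = np.random.default_rng(22)
    a = rng.random((20, 20)) < 0.3
    b = rng.random((20, 20)) < 0.4
    m1, m2 = manders_from_masks(a, b)
    m1s, m2s = manders_from_masks(b, a)
    assert (m1, m2) == (m2s, m1s)
    assert pearson_from_masks(a, b) == pytest.approx(pearson_from_masks(b, a))
    assert percent_overlap(a, b) == pytest.approx(percent_overlap(b, a))


def test_translation_drives_overlap_to_zero():
    a = raster_disc((64, 64), (20, 32), 6)
    b_on = raster_disc((64, 64), (20, 32), 6)
    b_off = raster_disc((64, 64), (50, 32), 6)
    assert manders_from_masks(a, b_on)[0] == 1.0
    assert manders_from_masks(a, b_off) == (0.0, 0.0)
    assert percent_overlap(a, b_off) == 0.0


def test_timeseries_identical_masks_all_frames():
    m = raster_disc((32, 32), (16, 16), 6)
    records = coloc_timeseries(_stack([m] * 10, "mito"), _stack([m] * 10, "lyso"))
    assert len(records) == 10
    for t, r in enumerate(records):
        assert r.frame == t
        assert (r.m1, r.m2) == (1.0, 1.0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.percent_overlap == pytest.approx(100.0)


def test_timeseries_frame_count_mismatch():
    m = raster_disc((16, 16), (8, 8), 3)
    with pytest.raises(ValueError, match="frame-count mismatch"):
        coloc_timeseries(_stack([m] * 3, "mito"), _stack([m] * 4, "lyso"))


def test_empty_lyso_channel_reports_zero_m1():
    a = raster_disc((16, 16), (8, 8), 3)
    empty = np.zeros((16, 16), dtype=bool)
    records = coloc_timeseries(_stack([a] * 3, "mito"), _stack([empty] * 3, "lyso"))
    assert all(r.m1 == 0.0 and r.m2 == 0.0 for r in records)


def test_planted_overlap_schedule_measured_exactly():
    """The overlap fixture plants |A∩B|/|A| in {1,.75,.5,.25,0}; the
    measured M1 from the ground-truth masks equals it exactly."""
    spec = get_preset("coloc-schedule")
    _, gt = generate_stack(spec)
    schedule = spec.overlap_schedule
    m1_series = []
    for t in range(spec.n_frames):
        m1, m2 = manders_from_masks(gt.channel_masks[t][0], gt.channel_masks[t][1])
        m1_series.append(m1)
        assert m1 == pytest.approx(schedule[t], abs=0.0)
        if schedule[t] > 0:
            assert m2 == 1.0  # schedule pixels are a subset of the mito mask
    assert all(a > b for a, b in zip(m1_series, m1_series[1:]))  # monotone ramp


def test_coloc_table_columns():
    m = raster_disc((16, 16), (8, 8), 3)
    df = coloc_table(coloc_timeseries(_stack([m] * 2, "mito"), _stack([m] * 2, "lyso")))
    assert list(df.columns) == [
        "frame", "m1", "m2", "pearson_r", "percent_overlap",
        "n_mito_px", "n_lyso_px", "n_overlap_px",
    ]
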