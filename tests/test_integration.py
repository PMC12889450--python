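import numpy as np
import pandas as pd
import pytest

from organelletrack.integration import correlation_matrix, matrix_difference, merge_metrics


def _inputs(n_frames=10, drop_coloc_frame=None):
    frames = list(range(n_frames))
    counts = pd.DataFrame({"frame": frames, "count": [5] * n_frames})
    morphology = pd.DataFrame(
        {
            "frame": np.repeat(frames, 2),
            "label": [1, 2] * n_frames,
            "area": [120, 40] * n_frames,
            "eccentricity": [0.95, 0.2] * n_frames,
            "category": ["elongated", "punctate"] * n_frames,
        }
    )
    shape_cols = ["area", "perimeter", "eccentricity", "circularity", "solidity", "aspect_ratio"]
    shapes = pd.DataFrame(
        {"frame": np.repeat(frames, 2), "label": [1, 2] * n_frames}
        | {c: np.linspace(1, 2, 2 * n_frames) for c in shape_cols}
    )
    speeds = pd.DataFrame({"frame": frames, "mean_speed": [np.nan] + [0.4] * (n_frames - 1)})
    coloc_frames = [f for f in frames if f != drop_coloc_frame]
    coloc = pd.DataFrame(
        {
            "frame": coloc_frames,
            "m1": np.linspace(1, 0, len(coloc_frames)),
            "m2": 0.5,
            "pearson_r": 0.3,
            "percent_overlap": 20.0,
        }
    )
    return counts, morphology, shapes, shapes.copy(), speeds, speeds.copy(), coloc


def test_inner_join_full_coverage_keeps_all_frames():
    table = merge_metrics(*_inputs(10), merge_mode="inner")
    assert len(table) == 10
    assert table["lyso_count"].tolist() == [5] * 10
    assert table["frac_elongated"].tolist() == [0.5] * 10
    assert table["n_mito"].tolist() == [2] * 10


def test_inner_join_drops_missing_coloc_frame():
    table = merge_metrics(*_inputs(10, drop_coloc_frame=9), merge_mode="inner")
    assert len(table) == 9
    assert 9 not in table["frame"].tolist()


def test_outer_join_keeps_frame_with_empty_cell():
    table = merge_metrics(*_inputs(10, drop_coloc_frame=9), merge_mode="outer")
    assert len(table) == 10
    assert np.isnan(table.loc[table["frame"] == 9, "m1"]).all()


def test_no_shared_frames_raises():
    inputs = list(_inputs(4))
    inputs[6] = inputs[6].assign(frame=[100, 101, 102, 103])
    with pytest.raises(ValueError, match="no shared frames"):
        merge_metrics(*inputs, merge_mode="inner")


def test_correlation_matches_textbook_pearson():
    """5-row two-column table against the closed-form Pearson formula."""
    x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
    expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    table = pd.DataFrame({"frame": range(5), "a": x, "b": y})
    corr = correlation_matrix(table)
    assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
    assert corr.loc["a", "a"] == pytest.approx(1.0)


def test_affine_columns_correlate_perfectly():
    x = np.arange(6, dtype=float)
    table = pd.DataFrame({"frame": range(6), "x": x, "y": 2 * x + 3})
    corr = correlation_matrix(table)
    assert corr.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)


def test_constant_column_is_nan_not_zero():
    table = pd.DataFrame({"frame": range(5), "x": np.arange(5.0), "c": 7.0})
    corr = correlation_matrix(table)
    assert np.isnan(corr.loc["x", "c"])
    assert np.isnan(corr.loc["c", "c"])


def test_correlation_requires_three_rows():
    with pytest.raises(ValueError, match="at least 3"):
        correlation_matrix(pd.DataFrame({"frame": [0, 1], "x": [1.0, 2.0]}))


def test_matrix_symmetric_unit_diagonal_bounded():
    table = merge_metrics(*_inputs(10))
    corr = correlation_matrix(table)
    vals = corr.to_numpy()
    np.testing.assert_allclose(vals, vals.T, equal_nan=True)
    finite = vals[np.isfinite(vals)]
    assert (finite >= -1 - 1e-12).all() and (finite <= 1 + 1e-12).all()
    for c in corr.columns:
        assert np.isnan(corr.loc[c, c]) or corr.loc[c, c] == pytest.approx(1.0)


def test_difference_with_itself_is_zero():
    corr = correlation_matrix(merge_metrics(*_inputs(10)))
    diff = matrix_difference(corr, corr)
    finite = diff.to_numpy()[np.isfinite(diff.to_numpy())]
    assert np.allclose(finite, 0.0)


def test_difference_antisymmetry_and_nan_propagation():
    a = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["p", "q"], columns=["p", "q"])
    b = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["p", "q"], columns=["p", "q"])
    d_ab = matrix_difference(a, b)
    d_ba = matrix_difference(b, a)
    np.testing.assert_allclose(d_ab.to_numpy(), -d_ba.to_numpy(), equal_nan=True)
    assert np.isnan(d_ab.loc["p", "q"])


def test_difference_empty_label_intersection_raises():
    a = pd.DataFrame([[1.0]], index=["p"], columns=["p"])
    b = pd.DataFrame([[1.0]], index=["q"], columns=["q"])
    with pytest.raises(ValueError, match="no labels"):
        matrix_difference(a, b)


def test_planted_colinear_metrics_correlate_at_one():
    """In the 'integration' preset the lysosome count and the Manders M1
    fraction are both linear in the frame index by construction, so their
    correlation entry is 1 to within numerical precision."""
    from organelletrack.detection import SegmentationParams, segment_stack
    from organelletrack.colocalization import coloc_table, coloc_timeseries
    from organelletrack.morphometrics import count_lysosomes
    from organelletrack.stack_io import ChannelConfig, preprocess
    from organelletrack.synthetic import generate_stack, get_preset

    stack, _ = generate_stack(get_preset("integration"))
    pp = preprocess(stack, ChannelConfig())
    mito = segment_stack(pp, 0, SegmentationParams(), "mito")
    lyso = segment_stack(pp, 1, SegmentationParams(), "lyso")
    counts = count_lysosomes(lyso)
    coloc = coloc_table(coloc_timeseries(mito, lyso))
    assert counts["count"].tolist() == list(range(1, 11))
    table = pd.DataFrame(
        {"frame": counts["frame"], "lyso_count": counts["count"], "m1": coloc["m1"]}
    )
    corr = correlation_matrix(table)
    assert corr.loc["lyso_count", "m1"] == pytest.approx(1.0, abs=1e-9)
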