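"""Merge per-frame metrics from all stages and correlate them.

The integrated table has one row per frame and a documented, stable column
set: lysosome count, mitochondrion count, elongated fraction, per-frame
mean shape descriptors for each organelle, per-frame mean step speed per
organelle, and the four colocalization metrics.  Per-object values are
aggregated to per-frame means by default (medians via ``agg``).

Correlations are pairwise-complete Pearson (or Spearman) over frames.
Constant columns produce NaN entries, which are surfaced as undefined —
never imputed as 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["merge_metrics", "correlation_matrix", "matrix_difference", "INTEGRATED_COLUMNS"]

_SHAPE_DESCRIPTORS = ["area", "perimeter", "eccentricity", "circularity", "solidity", "aspect_ratio"]

INTEGRATED_COLUMNS = (
    ["frame", "lyso_count", "n_mito", "frac_elongated"]
    + [f"mito_mean_{d}" for d in _SHAPE_DESCRIPTORS]
    + [f"lyso_mean_{d}" for d in _SHAPE_DESCRIPTORS]
    + ["mito_mean_speed", "lyso_mean_speed", "m1", "m2", "pearson_r", "percent_overlap"]
)


def _aggregate_shapes(shape_df: pd.DataFrame, prefix: str, agg: str) -> pd.DataFrame:
    if shape_df.empty:
        return pd.DataFrame(columns=["frame"] + [f"{prefix}_mean_{d}" for d in _SHAPE_DESCRIPTORS])
    g = shape_df.groupby("frame")[_SHAPE_DESCRIPTORS].agg(agg).reset_index()
    g.columns = ["frame"] + [f"{prefix}_mean_{d}" for d in _SHAPE_DESCRIPTORS]
    return g


def merge_metrics(
    counts: pd.DataFrame,
    morphology: pd.DataFrame,
    mito_shapes: pd.DataFrame,
    lyso_shapes: pd.DataFrame,
    mito_speeds: pd.DataFrame,
    lyso_speeds: pd.DataFrame,
    coloc: pd.DataFrame,
    merge_mode: str = "inner",
    agg: str = "mean",
) -> pd.DataFrame:
    """Join all per-frame tables on the frame index.

    ``merge_mode`` is ``"inner"`` (default: only frames present in every
    stage) or ``"outer"`` (union of frames, missing cells empty).  Raises
    if an inner join leaves no rows.
    """
    if merge_mode not in ("inner", "outer"):
        raise ValueError("merge_mode must be 'inner' or 'outer'")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")

    counts = counts.rename(columns={"count": "lyso_count"})[["frame", "lyso_count"]]

    if morphology.empty:
        morph = pd.DataFrame(columns=["frame", "n_mito", "frac_elongated"])
    else:
        morph = (
            morphology.groupby("frame")
            .agg(
                n_mito=("label", "size"),
                frac_elongated=("category", lambda c: float(np.mean(c == "elongated"))),
            )
            .reset_index()
        )

    pieces = [
        counts,
        morph,
        _aggregate_shapes(mito_shapes, "mito", agg),
        _aggregate_shapes(lyso_shapes, "lyso", agg),
        mito_speeds.rename(columns={"mean_speed": "mito_mean_speed"}),
        lyso_speeds.rename(columns={"mean_speed": "lyso_mean_speed"}),
        coloc[["frame", "m1", "m2", "pearson_r", "percent_overlap"]],
    ]
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.merge(piece, on="frame", how=merge_mode)
    if merge_mode == "inner" and out.empty:
        raise ValueError("no shared frames across stages under inner join")
    out = out.sort_values("frame").reset_index(drop=True)
    return out.reindex(columns=INTEGRATED_COLUMNS)


def correlation_matrix(table: pd.DataFrame, corr_method: str = "pearson") -> pd.DataFrame:
    """Metric-metric correlation over frames (pairwise-complete rows).

    Entries involving a constant column are NaN; the diagonal is 1 wherever
    defined.  Requires at least 3 rows.
    """
    if corr_method not in ("pearson", "spearman"):
        raise ValueError("corr_method must be 'pearson' or 'spearman'")
    if len(table) < 3:
        raise ValueError("correlation requires at least 3 frames")
    numeric = table.drop(columns=["frame"], errors="ignore").select_dtypes(include=[np.number])
    corr = numeric.corr(method=corr_method)
    n_undef = int(corr.isna().sum().sum())
    if n_undef:
        logger.warning("%d undefined correlation entries (constant columns)", n_undef)
    return corr


def matrix_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Elementwise a - b on the shared label set; NaN entries propagate."""
    common = [lab for lab in a.columns if lab in set(b.columns)]
    if not common:
        raise ValueError("correlation matrices share no labels")
    if len(common) < len(a.columns) or len(common) < len(b.columns):
        logger.warning("label sets differ; using %d shared labels", len(common))
    return a.loc[common, common] - b.loc[common, common]
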