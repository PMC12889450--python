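"""Adaptive two-sample comparison of exported metrics between two runs.

Test selection is data-driven: Shapiro-Wilk normality on each group (if
either p < alpha, Mann-Whitney U), then median-centered Levene variance
equality (p < alpha, Welch's t; otherwise Student's t).  The effect size
follows the test: Cohen's d (pooled SD) for Student, Hedges' g (small-
sample corrected d) for Welch, and rank-biserial r = 1 - 2U/(n1*n2) for
Mann-Whitney, with U the statistic of the first sample.  All tests are
two-sided.

By default per-object rows are pooled across frames within a run; this
treats objects as the sampling unit and ignores within-frame dependence,
so a frame-level aggregation mode (``unit="frame"``) is offered to
mitigate pseudo-replication.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "select_test",
    "effect_size",
    "compare_samples",
    "compare_runs",
    "METRIC_SOURCES",
]

# metric name -> (CSV filename, column, optional filter column/value)
METRIC_SOURCES: dict[str, tuple[str, str, tuple[str, str] | None]] = {
    "lyso_count": ("Lysosome_Counts.csv", "count", None),
    "m1": ("Colocalization.csv", "m1", None),
    "m2": ("Colocalization.csv", "m2", None),
    "pearson_r": ("Colocalization.csv", "pearson_r", None),
    "percent_overlap": ("Colocalization.csv", "percent_overlap", None),
    "mean_velocity": ("Motility_Summary.csv", "mean_velocity", None),
    "total_displacement": ("Motility_Summary.csv", "total_displacement", None),
    "net_displacement": ("Motility_Summary.csv", "net_displacement", None),
    "frac_elongated": ("Integrated_Merged_Data.csv", "frac_elongated", None),
}
for _desc in ("area", "perimeter", "eccentricity", "circularity", "solidity", "aspect_ratio"):
    METRIC_SOURCES[f"mito_{_desc}"] = ("Mito_ShapeMetrics.csv", _desc, None)
    METRIC_SOURCES[f"lyso_{_desc}"] = ("Lyso_ShapeMetrics.csv", _desc, None)
for _mot in ("mean_velocity", "total_displacement", "net_displacement"):
    METRIC_SOURCES[f"mito_{_mot}"] = ("Motility_Summary.csv", _mot, ("organelle", "mito"))
    METRIC_SOURCES[f"lyso_{_mot}"] = ("Motility_Summary.csv", _mot, ("organelle", "lyso"))


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    median1: float
    median2: float
    shapiro_p1: float
    shapiro_p2: float
    levene_p: float | None
    test_used: str  # student_t | welch_t | mann_whitney_u
    statistic: float
    p_value: float
    effect_size_name: str  # cohens_d | hedges_g | rank_biserial_r
    effect_size_value: float


def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    return x[np.isfinite(x)]


def select_test(x, y, alpha: float = 0.05) -> tuple[str, float, float, float | None]:
    """Choose the two-sample test; returns (test, shapiro_p1, shapiro_p2, levene_p)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("insufficient sample: both groups need n >= 3")
    p1 = stats.shapiro(x).pvalue if np.ptp(x) > 0 else 0.0
    p2 = stats.shapiro(y).pvalue if np.ptp(y) > 0 else 0.0
    if p1 < alpha or p2 < alpha:
        return "mann_whitney_u", p1, p2, None
    p_lev = stats.levene(x, y, center="median").pvalue
    if p_lev < alpha:
        return "welch_t", p1, p2, p_lev
    return "student_t", p1, p2, p_lev


def effect_size(test_used: str, x, y) -> tuple[str, float]:
    """Effect size matched to the selected test; see module docstring."""
    x, y = _clean(x), _clean(y)
    n1, n2 = len(x), len(y)
    if test_used == "mann_whitney_u":
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        return "rank_biserial_r", 1.0 - 2.0 * u / (n1 * n2)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        d = diff / math.sqrt(sp2)
    if test_used == "student_t":
        return "cohens_d", d
    if test_used == "welch_t":
        return "hedges_g", d * (1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0))
    raise ValueError(f"unknown test {test_used!r}")


def compare_samples(x, y, metric: str = "metric", alpha: float = 0.05) -> ComparisonResult:
    """Full adaptive comparison of two samples: select, test, effect size."""
    x, y = _clean(x), _clean(y)
    test, p1, p2, p_lev = select_test(x, y, alpha=alpha)
    if test == "mann_whitney_u":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    elif test == "welch_t":
        res = stats.ttest_ind(x, y, equal_var=False)
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
    es_name, es_value = effect_size(test, x, y)
    return ComparisonResult(
        metric=metric,
        n1=len(x),
        n2=len(y),
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        shapiro_p1=p1,
        shapiro_p2=p2,
        levene_p=p_lev,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_name=es_name,
        effect_size_value=float(es_value),
    )


def load_metric(run_dir: str | Path, metric: str, unit: str = "object") -> np.ndarray:
    """Load one metric's sample from a run's exported CSV directory.

    ``unit="object"`` pools per-object/per-track rows; ``unit="frame"``
    averages within frames first (for tables that carry a frame column).
    """
    if metric not in METRIC_SOURCES:
        raise KeyError(
            f"unknown metric {metric!r}; known: {', '.join(sorted(METRIC_SOURCES))}"
        )
    filename, column, flt = METRIC_SOURCES[metric]
    path = Path(run_dir) / filename
    if not path.exists():
        raise FileNotFoundError(f"expected {filename} in {run_dir} for metric {metric!r}")
    df = pd.read_csv(path)
    if flt is not None:
        df = df[df[flt[0]] == flt[1]]
    if column not in df.columns:
        raise KeyError(f"column {column!r} missing from {path}")
    if unit == "frame" and "frame" in df.columns:
        df = df.groupby("frame", as_index=False)[column].mean()
    return _clean(df[column].to_numpy())


def compare_runs(
    dir_a: str | Path,
    dir_b: str | Path,
    metrics: list[str],
    alpha: float = 0.05,
    unit: str = "object",
    out_dir: str | Path | None = None,
    holm: bool = False,
) -> list[ComparisonResult]:
    """Compare each named metric between two pipeline output directories.

    Writes ``<Metric>_Comparison.png`` violins and a summary
    ``Metrics_Comparison.csv`` when *out_dir* is given.  ``holm=True``
    applies a Holm step-down correction across the requested metrics.
    """
    results = []
    samples = {}
    for metric in metrics:
        x = load_metric(dir_a, metric, unit=unit)
        y = load_metric(dir_b, metric, unit=unit)
        samples[metric] = (x, y)
        results.append(compare_samples(x, y, metric=metric, alpha=alpha))
    if holm and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adjusted = {}
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * results[idx].p_value)
            adjusted[idx] = min(running, 1.0)
        results = [
            ComparisonResult(**{**r.__dict__, "p_value": adjusted[i]})
            for i, r in enumerate(results)
        ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from . import render

        for r in results:
            x, y = samples[r.metric]
            render.comparison_violin(x, y, r, out_dir / f"{r.metric.title()}_Comparison.png")
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            out_dir / "Metrics_Comparison.csv", index=False
        )
    return results
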