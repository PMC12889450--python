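"""Figure and overlay rendering for every pipeline stage.

Conventions: mitochondria are drawn red, lysosomes green, overlap pixels
bright blue.  Correlation heatmaps use a fixed symmetric colour scale of
[-1, 1] (differences: [-2, 2]) so figures from different runs are directly
comparable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from skimage.segmentation import find_boundaries

MITO_COLOR = (255, 60, 60)
LYSO_COLOR = (60, 220, 60)
OVERLAP_COLOR = (80, 140, 255)


def _to_rgb(frame: np.ndarray) -> np.ndarray:
    return np.stack([frame] * 3, axis=-1).astype(np.uint8)


def detection_overlay(frame: np.ndarray, mask: np.ndarray, color: tuple[int, int, int]) -> np.ndarray:
    """Grayscale frame with the mask contour painted in *color*."""
    rgb = _to_rgb(frame)
    rgb[find_boundaries(mask, mode="thick")] = color
    return rgb


def save_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)
    return path


def labeled_count_image(frame: np.ndarray, regions, path: str | Path) -> Path:
    """Frame with each labelled lysosome annotated by its label id."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(frame, cmap="gray")
    for region in regions:
        x, y = region.centroid_xy
        ax.text(x, y, str(region.label), color="yellow", fontsize=8,
                ha="center", va="center")
    ax.set_title(f"{len(regions)} lysosomes")
    ax.axis("off")
    return _save_fig(fig, path)


def morphology_overlay(frame: np.ndarray, calls, path: str | Path) -> Path:
    """Elongated objects outlined orange, punctate cyan."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(frame, cmap="gray")
    for call in calls:
        r = call.region
        color = "orange" if call.category == "elongated" else "cyan"
        ax.plot(r.centroid_x, r.centroid_y, "o", ms=4, color=color)
    ax.set_title("orange = elongated, cyan = punctate")
    ax.axis("off")
    return _save_fig(fig, path)


def coloc_overlay(mito_mask: np.ndarray, lyso_mask: np.ndarray, path: str | Path) -> Path:
    rgb = np.zeros((*mito_mask.shape, 3), dtype=np.uint8)
    rgb[mito_mask] = MITO_COLOR
    rgb[lyso_mask] = LYSO_COLOR
    rgb[mito_mask & lyso_mask] = OVERLAP_COLOR
    return save_png(rgb, path)


def _save_fig(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def count_plot(counts: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(counts["frame"], counts["count"], marker="o")
    ax.set_xlabel("frame")
    ax.set_ylabel("lysosome count")
    return _save_fig(fig, path)


def shape_violins(mito_shapes: pd.DataFrame, lyso_shapes: pd.DataFrame, path: str | Path) -> Path:
    descriptors = ["area", "circularity", "solidity", "eccentricity", "aspect_ratio"]
    fig, axes = plt.subplots(1, len(descriptors), figsize=(3 * len(descriptors), 3.5))
    for ax, d in zip(axes, descriptors):
        frames_ = []
        for name, df in (("mito", mito_shapes), ("lyso", lyso_shapes)):
            if not df.empty:
                frames_.append(pd.DataFrame({"organelle": name, d: df[d]}))
        if frames_:
            data = pd.concat(frames_, ignore_index=True).dropna()
            if not data.empty:
                sns.violinplot(data=data, x="organelle", y=d, ax=ax, cut=0)
        ax.set_title(d)
    fig.tight_layout()
    return _save_fig(fig, path)


def cumulative_tracks(tracks, shape: tuple[int, int], path: str | Path, title: str) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    for tr in tracks:
        pts = np.asarray([(x, y) for _, x, y in tr.points])
        ax.plot(pts[:, 0], pts[:, 1], lw=1)
    ax.set_xlim(0, shape[1])
    ax.set_ylim(shape[0], 0)
    ax.set_aspect("equal")
    ax.set_title(title)
    return _save_fig(fig, path)


def motility_scatter(motility: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    unit = motility["unit"].iloc[0] if len(motility) else "px"
    for name, grp in motility.groupby("organelle"):
        ax.scatter(grp["total_displacement"], grp["mean_velocity"], label=name, s=18)
    ax.set_xlabel(f"total displacement ({unit})")
    ax.set_ylabel(f"mean velocity ({unit}/s)")
    ax.legend()
    return _save_fig(fig, path)


def motility_distributions(motility: pd.DataFrame, path: str | Path) -> Path:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col in zip(axes, ("mean_velocity", "total_displacement")):
        if len(motility):
            sns.histplot(data=motility, x=col, hue="organelle", ax=ax, element="step")
        ax.set_title(col)
    fig.tight_layout()
    return _save_fig(fig, path)


def coloc_metrics_plot(coloc: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6.5, 3.5))
    for col in ("m1", "m2", "pearson_r"):
        ax.plot(coloc["frame"], coloc[col], marker=".", label=col)
    ax2 = ax.twinx()
    ax2.plot(coloc["frame"], coloc["percent_overlap"], color="gray", ls="--",
             label="percent_overlap")
    ax2.set_ylabel("percent overlap")
    ax.set_xlabel("frame")
    ax.set_ylabel("coefficient")
    ax.legend(loc="upper right")
    return _save_fig(fig, path)


def correlation_heatmap(matrix: pd.DataFrame, path: str | Path, difference: bool = False) -> Path:
    lim = 2.0 if difference else 1.0
    fig, ax = plt.subplots(figsize=(0.45 * len(matrix) + 3, 0.45 * len(matrix) + 2.5))
    sns.heatmap(matrix, vmin=-lim, vmax=lim, cmap="RdBu_r", ax=ax, square=True,
                cbar_kws={"shrink": 0.8})
    fig.tight_layout()
    return _save_fig(fig, path)


def comparison_violin(x: np.ndarray, y: np.ndarray, result, path: str | Path) -> Path:
    data = pd.DataFrame(
        {
            "group": ["A"] * len(x) + ["B"] * len(y),
            result.metric: np.concatenate([x, y]),
        }
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    sns.violinplot(data=data, x="group", y=result.metric, ax=ax, cut=0)
    ax.set_title(
        f"{result.test_used}: p={result.p_value:.3g}\n"
        f"{result.effect_size_name}={result.effect_size_value:.3g}"
    )
    fig.tight_layout()
    return _save_fig(fig, path)
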