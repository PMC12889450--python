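"""End-to-end orchestration: run all stages and emit the standard outputs.

The pipeline executes, in order: segmentation of both channels (1),
lysosome counting (2), mitochondrial morphology classification (3), shape
feature extraction (4), tracking and motility (5), colocalization (6) and
the integrated correlation summary (7).  Every run writes a fixed set of
output filenames (CSV + PNG, optionally videos) into one directory,
together with a copy of the configuration and a manifest mapping each
file to the stage that produced it.  Runs are deterministic for a fixed
input stack and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import render
from .colocalization import coloc_table, coloc_timeseries
from .detection import SegmentationParams, label_regions, segment_stack
from .integration import correlation_matrix, merge_metrics
from .morphometrics import (
    MorphologyParams,
    classify_morphology,
    count_lysosomes,
    morphology_table,
    shape_features,
    shape_table,
)
from .stack_io import ChannelConfig, preprocess, read_stack
from .tracking import (
    TrackingParams,
    build_tracks,
    motility_table,
    per_frame_speed_table,
    tracks_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_video"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, step: int, stage: str, message: str):
        super().__init__(f"Step {step} ({stage}): {message}")
        self.step = step
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to key=value text."""

    input_path: str = ""
    output_dir: str = "."
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    mito_seg: SegmentationParams = field(default_factory=SegmentationParams)
    lyso_seg: SegmentationParams = field(default_factory=SegmentationParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    merge_mode: str = "inner"
    corr_method: str = "pearson"
    make_videos: bool = False
    make_plots: bool = True
    preview_frame: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "channels": ChannelConfig,
        "mito_seg": SegmentationParams,
        "lyso_seg": SegmentationParams,
        "morphology": MorphologyParams,
        "tracking": TrackingParams,
    }

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            name = f.name
            value = getattr(self, name)
            if name in self._SECTIONS:
                for sub in fields(value):
                    v = getattr(value, sub.name)
                    lines.append(f"{name}.{sub.name} = {'' if v is None else v}")
            else:
                lines.append(f"{name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        flat: dict[str, str] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key = value): {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            flat[key] = value
        kwargs: dict = {}
        sections: dict[str, dict] = {name: {} for name in cls._SECTIONS}
        type_map = {f.name: f for f in fields(cls)}
        for key, value in flat.items():
            if "." in key:
                section, sub = key.split(".", 1)
                if section not in sections:
                    raise ValueError(f"unknown config section {section!r}")
                sections[section][sub] = value
            elif key in type_map:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        for name, klass in cls._SECTIONS.items():
            if sections[name]:
                typed = {}
                for f in fields(klass):
                    if f.name in sections[name]:
                        typed[f.name] = _coerce(sections[name][f.name])
                kwargs[name] = klass(**typed)
        for key in ("make_videos", "make_plots"):
            if key in kwargs:
                kwargs[key] = str(kwargs[key]).lower() in ("1", "true", "yes")
        if "preview_frame" in kwargs:
            kwargs["preview_frame"] = int(kwargs["preview_frame"])
        return cls(**kwargs)


def _coerce(value: str):
    if value == "":
        return None
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def write_video(frames: list[np.ndarray], path: str | Path, fps: float) -> tuple[list[Path], str | None]:
    """Write an MP4, or fall back to a numbered PNG sequence.

    Returns (paths written, downgrade note or None).  The fallback
    directory carries the video's stem so outputs remain discoverable.
    """
    if not frames:
        raise ValueError("write_video needs at least one frame")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        import imageio

        with imageio.get_writer(path, fps=fps) as writer:
            for frame in frames:
                writer.append_data(frame)
        return [path], None
    except Exception as exc:  # no encoder available
        note = f"no MP4 encoder ({exc.__class__.__name__}); wrote PNG sequence instead"
        logger.warning("%s", note)
        seq_dir = path.with_suffix("")
        seq_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for i, frame in enumerate(frames):
            p = seq_dir / f"frame{i:04d}.png"
            iio.imwrite(p, frame)
            written.append(p)
        return written, note


def run_pipeline(config: RunConfig) -> dict:
    """Execute Steps 1-7 and return the output manifest.

    The manifest maps each written filename (relative to the output
    directory) to its step number, plus any notes (e.g. video downgrade).
    On failure a ``FAILED`` marker naming the stage is left in the output
    directory and a :class:`PipelineError` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict[str, int] = {}
    notes: list[str] = []
    step, stage = 0, "stack_io"

    def emit(path: Path, step_no: int) -> None:
        manifest[str(path.relative_to(out))] = step_no

    try:
        # Step 0: read + preprocess
        stack = read_stack(config.input_path, config.channels)
        stack = preprocess(stack, config.channels)
        (out / "run_config.txt").write_text(config.to_text())
        manifest["run_config.txt"] = 0

        cc = config.channels
        pf = config.preview_frame

        # Step 1: detection
        step, stage = 1, "detection"
        mito_masks = segment_stack(stack, cc.mito_channel, config.mito_seg, "mito")
        lyso_masks = segment_stack(stack, cc.lyso_channel, config.lyso_seg, "lyso")
        mito_frames = stack.channel(cc.mito_channel)
        lyso_frames = stack.channel(cc.lyso_channel)
        emit(render.save_png(
            render.detection_overlay(mito_frames[pf], mito_masks.masks[pf], render.MITO_COLOR),
            out / "Mito_Frame0.png"), 1)
        emit(render.save_png(
            render.detection_overlay(lyso_frames[pf], lyso_masks.masks[pf], render.LYSO_COLOR),
            out / "Lyso_Frame0.png"), 1)
        if config.make_videos:
            for name, frames_, masks_, color in (
                ("Mito_Detection.mp4", mito_frames, mito_masks, render.MITO_COLOR),
                ("Lyso_Detection.mp4", lyso_frames, lyso_masks, render.LYSO_COLOR),
            ):
                rendered = [
                    render.detection_overlay(frames_[t], masks_.masks[t], color)
                    for t in range(stack.n_frames)
                ]
                paths, note = write_video(rendered, out / name, fps=1.0 / cc.frame_interval_s)
                for p in paths:
                    emit(p, 1)
                if note:
                    notes.append(f"{name}: {note}")

        # Step 2: lysosome counting
        step, stage = 2, "lyso_count"
        counts = count_lysosomes(lyso_masks)
        counts.to_csv(out / "Lysosome_Counts.csv", index=False)
        manifest["Lysosome_Counts.csv"] = 2
        emit(render.labeled_count_image(
            lyso_frames[pf], label_regions(lyso_masks.masks[pf]),
            out / "Lyso_Frame0_Count.png"), 2)
        if config.make_plots:
            emit(render.count_plot(counts, out / "Lyso_Count_Plot.png"), 2)

        # Step 3: morphology classification
        step, stage = 3, "morphology"
        morph = morphology_table(mito_masks, config.morphology)
        morph.to_csv(out / "Morphology_Summary.csv", index=False)
        manifest["Morphology_Summary.csv"] = 3
        calls = [
            classify_morphology(shape_features(r, frame=pf), config.morphology)
            for r in label_regions(mito_masks.masks[pf])
        ]
        emit(render.morphology_overlay(mito_frames[pf], calls,
                                       out / "Morphology_Frame0_Labeled.png"), 3)

        # Step 4: shape features
        step, stage = 4, "shape_features"
        mito_shapes = shape_table(mito_masks)
        lyso_shapes = shape_table(lyso_masks)
        mito_shapes.to_csv(out / "Mito_ShapeMetrics.csv", index=False)
        lyso_shapes.to_csv(out / "Lyso_ShapeMetrics.csv", index=False)
        manifest["Mito_ShapeMetrics.csv"] = 4
        manifest["Lyso_ShapeMetrics.csv"] = 4
        if config.make_plots:
            emit(render.shape_violins(mito_shapes, lyso_shapes,
                                      out / "Shape_ViolinPlots.png"), 4)

        # Step 5: tracking + motility
        step, stage = 5, "tracking"
        mito_tracks = build_tracks(mito_masks, config.tracking)
        lyso_tracks = build_tracks(lyso_masks, config.tracking)
        tracks_table(mito_tracks).to_csv(out / "Mito_Tracks.csv", index=False)
        tracks_table(lyso_tracks).to_csv(out / "Lyso_Tracks.csv", index=False)
        manifest["Mito_Tracks.csv"] = 5
        manifest["Lyso_Tracks.csv"] = 5
        motility = pd.concat(
            [motility_table(mito_tracks, cc), motility_table(lyso_tracks, cc)],
            ignore_index=True,
        )
        motility.to_csv(out / "Motility_Summary.csv", index=False)
        manifest["Motility_Summary.csv"] = 5
        if config.make_plots:
            emit(render.cumulative_tracks(mito_tracks, stack.frame_shape,
                                          out / "Cumulative_Mito.png", "mitochondria"), 5)
            emit(render.cumulative_tracks(lyso_tracks, stack.frame_shape,
                                          out / "Cumulative_Lyso.png", "lysosomes"), 5)
            emit(render.motility_scatter(motility, out / "Motility_Scatter.png"), 5)
            emit(render.motility_distributions(motility, out / "Motility_Distributions.png"), 5)

        # Step 6: colocalization
        step, stage = 6, "colocalization"
        records = coloc_timeseries(mito_masks, lyso_masks)
        coloc = coloc_table(records)
        coloc.to_csv(out / "Colocalization.csv", index=False)
        manifest["Colocalization.csv"] = 6
        emit(render.coloc_overlay(mito_masks.masks[pf], lyso_masks.masks[pf],
                                  out / "Colocalization_Frame0.png"), 6)
        if config.make_plots:
            emit(render.coloc_metrics_plot(coloc, out / "Colocalization_MetricsPlot.png"), 6)

        # Step 7: integration
        step, stage = 7, "integration"
        merged = merge_metrics(
            counts,
            morph,
            mito_shapes,
            lyso_shapes,
            per_frame_speed_table(mito_tracks, cc, stack.n_frames),
            per_frame_speed_table(lyso_tracks, cc, stack.n_frames),
            coloc,
            merge_mode=config.merge_mode,
        )
        merged.to_csv(out / "Integrated_Merged_Data.csv", index=False)
        manifest["Integrated_Merged_Data.csv"] = 7
        corr = correlation_matrix(merged, corr_method=config.corr_method)
        if config.make_plots:
            emit(render.correlation_heatmap(corr, out / "Integrated_CorrelationMatrix.png"), 7)
        corr.to_csv(out / "Integrated_CorrelationMatrix.csv")
        manifest["Integrated_CorrelationMatrix.csv"] = 7

    except Exception as exc:
        (out / "FAILED").write_text(f"Step {step} ({stage}): {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(step, stage, str(exc)) from exc

    payload = {"files": manifest, "notes": notes}
    manifest["manifest.json"] = 0
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
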