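"""Adaptive Otsu segmentation of organelle channels into binary masks.

Each frame is thresholded independently ("adaptive" in the temporal sense:
the global Otsu threshold is re-estimated per frame and scaled by a
user-set stringency factor), then cleaned by morphological opening,
small-object removal and optional border clearing, in that fixed order.
Connected components use 8-connectivity throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import clear_border as sk_clear_border

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "MaskStack",
    "LabeledRegion",
    "segment_frame",
    "segment_stack",
    "label_regions",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the per-frame segmentation.

    thr_factor scales the Otsu threshold (>1 = more stringent); min_size
    discards components below an area in pixels (camera noise, debris);
    opening_radius is the disc radius of the morphological opening;
    clear_border drops components touching the image edge.
    """

    thr_factor: float = 1.0
    min_size: int = 10
    opening_radius: int = 1
    clear_border: bool = True

    def __post_init__(self) -> None:
        if self.thr_factor <= 0:
            raise ValueError("thr_factor must be > 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")


@dataclass
class MaskStack:
    """Per-frame binary masks for one organelle class."""

    masks: np.ndarray  # (T, H, W) bool
    organelle_class: str  # "mito" | "lyso"
    params_used: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.masks.ndim != 3:
            raise ValueError("MaskStack.masks must be 3-D (T, H, W)")
        if self.organelle_class not in ("mito", "lyso"):
            raise ValueError("organelle_class must be 'mito' or 'lyso'")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


@dataclass(frozen=True)
class LabeledRegion:
    """One 8-connected component: label id and its pixel coordinates."""

    label: int
    coords: np.ndarray  # (N, 2) array of (row, col)

    @property
    def area(self) -> int:
        return len(self.coords)

    @property
    def centroid_xy(self) -> tuple[float, float]:
        """Centroid as (x, y) = (col, row)."""
        r, c = self.coords.mean(axis=0)
        return float(c), float(r)


def segment_frame(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment one 2-D 8-bit frame into a boolean foreground mask.

    Pipeline order is fixed: Otsu x thr_factor -> ``>=`` threshold ->
    opening -> small-object removal -> border clearing.  A zero-variance
    frame (Otsu undefined) yields an empty mask with a warning rather than
    aborting the stack.
    """
    if frame.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2-D frame")
    if frame.max() == frame.min():
        logger.warning("zero-variance frame: Otsu undefined, returning empty mask")
        return np.zeros(frame.shape, dtype=bool)
    # skimage's Otsu value is exclusive (foreground = pixel > t); convert to
    # the equivalent inclusive integer threshold so that ">= t" selects the
    # identical pixel set, then scale by the stringency factor
    t_otsu = math.floor(threshold_otsu(frame)) + 1
    t = t_otsu * params.thr_factor
    mask = frame >= t
    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    mask = _remove_small(mask, params.min_size)
    if params.clear_border:
        mask = sk_clear_border(mask)
    return mask


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected components with area strictly below min_size."""
    if min_size <= 1 or not mask.any():
        return mask
    lab = sk_label(mask, connectivity=2)
    areas = np.bincount(lab.ravel())
    keep = areas >= min_size
    keep[0] = False
    return keep[lab]


def segment_stack(stack, channel: int, params: SegmentationParams, organelle_class: str = "mito") -> MaskStack:
    """Apply :func:`segment_frame` to every frame of one channel."""
    if not stack.preprocessed:
        raise ValueError("stack must be preprocessed before segmentation")
    if channel >= stack.n_channels:
        raise ValueError(f"channel count mismatch: channel {channel} of {stack.n_channels}")
    frames = stack.channel(channel)
    masks = np.stack([segment_frame(frames[t], params) for t in range(stack.n_frames)])
    return MaskStack(masks=masks, organelle_class=organelle_class, params_used=params)


def label_regions(mask: np.ndarray) -> list[LabeledRegion]:
    """8-connected components of a boolean mask, labelled 1..N in raster order.

    Raster order means labels are assigned by the first pixel of each
    component encountered scanning rows top-to-bottom, columns
    left-to-right.  An empty mask yields an empty list.
    """
    if mask.ndim != 2:
        raise ValueError("label_regions expects a 2-D boolean mask")
    lab = sk_label(mask, connectivity=2)
    return [LabeledRegion(label=rp.label, coords=rp.coords) for rp in regionprops(lab)]
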