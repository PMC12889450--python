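"""Binary-mask colocalization: Manders M1/M2, Pearson phi, percent overlap.

All metrics are computed from the two segmented masks, pixel-for-pixel:

* M1 = |A∩B| / |A|, M2 = |A∩B| / |B|  (A = mito mask, B = lyso mask);
  an empty denominator yields 0 with a flag rather than an error, so
  whole-stack runs survive blank frames.
* Pearson r is the correlation of the two masks as 0/1 pixel vectors over
  the full frame — the phi coefficient of the 2x2 pixel contingency table.
  It is NaN (undefined) when either mask is constant.
* Percent overlap is the Jaccard index x 100, i.e. 100·|A∩B| / |A∪B|.
  This symmetric definition is a package convention; note that
  per-channel (|A∩B|/|A|) variants exist in the literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import MaskStack

logger = logging.getLogger(__name__)

__all__ = [
    "ColocRecord",
    "manders_from_masks",
    "pearson_from_masks",
    "percent_overlap",
    "coloc_timeseries",
    "coloc_table",
]

COLOC_COLUMNS = [
    "frame", "m1", "m2", "pearson_r", "percent_overlap",
    "n_mito_px", "n_lyso_px", "n_overlap_px",
]


@dataclass(frozen=True)
class ColocRecord:
    frame: int
    m1: float
    m2: float
    pearson_r: float  # NaN when undefined (constant mask)
    percent_overlap: float
    n_mito_px: int
    n_lyso_px: int
    n_overlap_px: int


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def manders_from_masks(mito_mask: np.ndarray, lyso_mask: np.ndarray) -> tuple[float, float]:
    """(M1, M2) pixel-count ratios; empty-denominator channels report 0."""
    _check_shapes(mito_mask, lyso_mask)
    a = np.asarray(mito_mask, dtype=bool)
    b = np.asarray(lyso_mask, dtype=bool)
    n_a, n_b = int(a.sum()), int(b.sum())
    n_ab = int((a & b).sum())
    if n_a == 0:
        logger.warning("empty mitochondrial mask: M1 reported as 0")
    if n_b == 0:
        logger.warning("empty lysosomal mask: M2 reported as 0")
    m1 = n_ab / n_a if n_a else 0.0
    m2 = n_ab / n_b if n_b else 0.0
    return m1, m2


def pearson_from_masks(mito_mask: np.ndarray, lyso_mask: np.ndarray) -> float:
    """Phi coefficient of the two masks over all pixels (NaN if either is constant)."""
    _check_shapes(mito_mask, lyso_mask)
    a = np.asarray(mito_mask, dtype=bool)
    b = np.asarray(lyso_mask, dtype=bool)
    n = a.size
    n_a, n_b = int(a.sum()), int(b.sum())
    if n_a in (0, n) or n_b in (0, n):
        return float("nan")
    n11 = int((a & b).sum())
    # phi from the 2x2 contingency table
    num = n * n11 - n_a * n_b
    den = math.sqrt(n_a * (n - n_a)) * math.sqrt(n_b * (n - n_b))
    return num / den


def percent_overlap(mito_mask: np.ndarray, lyso_mask: np.ndarray) -> float:
    """Jaccard overlap as a percentage; two empty masks report 0."""
    _check_shapes(mito_mask, lyso_mask)
    a = np.asarray(mito_mask, dtype=bool)
    b = np.asarray(lyso_mask, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        logger.warning("both masks empty: percent_overlap reported as 0")
        return 0.0
    return 100.0 * int((a & b).sum()) / union


def coloc_timeseries(mito_masks: MaskStack, lyso_masks: MaskStack) -> list[ColocRecord]:
    """One :class:`ColocRecord` per frame, in frame order."""
    if mito_masks.n_frames != lyso_masks.n_frames:
        raise ValueError(
            f"frame-count mismatch: {mito_masks.n_frames} vs {lyso_masks.n_frames}"
        )
    _check_shapes(mito_masks.masks[0], lyso_masks.masks[0])
    records = []
    for t in range(mito_masks.n_frames):
        a = mito_masks.masks[t]
        b = lyso_masks.masks[t]
        m1, m2 = manders_from_masks(a, b)
        records.append(
            ColocRecord(
                frame=t,
                m1=m1,
                m2=m2,
                pearson_r=pearson_from_masks(a, b),
                percent_overlap=percent_overlap(a, b),
                n_mito_px=int(a.sum()),
                n_lyso_px=int(b.sum()),
                n_overlap_px=int((a & b).sum()),
            )
        )
    return records


def coloc_table(records: list[ColocRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=COLOC_COLUMNS)
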