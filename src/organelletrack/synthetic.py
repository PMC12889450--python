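"""Synthetic two-channel time-lapse stacks with exact ground truth.

Objects are filled ellipses rasterised without anti-aliasing (a pixel is
foreground iff its centre satisfies the ellipse inequality), so the
ground-truth pixel sets match the noise-free image exactly.  Motion is
linear (per-frame velocity vector) or a seeded Gaussian random walk, and
objects may appear/vanish at scheduled frames.  Gaussian read noise is
added after rasterisation and the result clipped to 8 bits.

An overlap schedule overrides the lysosome channel: for each frame the
lysosome mask is built as the first ``round(f_t * |A_t|)`` pixels of the
mitochondrial mask in raster order, so the planted Manders M1 fraction is
exact whenever ``f_t * |A_t|`` is an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .stack_io import ImageStack, write_stack

__all__ = ["EllipseObject", "SyntheticSpec", "GroundTruth", "generate_stack", "preset_fixtures", "get_preset"]


@dataclass(frozen=True)
class EllipseObject:
    """One planted organelle: geometry, brightness and motion.

    ``a``/``b`` are ellipse semi-axes in pixels, ``orientation`` the major
    axis angle vs x (radians, counter-clockwise).  Exactly one of
    ``velocity`` (px/frame) or ``rw_sigma`` (random-walk step SD, px)
    describes motion; both absent means stationary.  ``appear``/``vanish``
    bound the frames in which the object exists (vanish exclusive).
    """

    channel: int  # 0 = mito, 1 = lyso (package default layout)
    a: float
    b: float
    center: tuple[float, float]  # (x, y) at appearance
    orientation: float = 0.0
    intensity: int = 200
    velocity: tuple[float, float] | None = None
    rw_sigma: float | None = None
    appear: int = 0
    vanish: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be > 0")
        if self.velocity is not None and self.rw_sigma is not None:
            raise ValueError("give either velocity or rw_sigma, not both")
        if not (0 < self.intensity <= 255):
            raise ValueError("intensity must be in (0, 255]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic recording (seed-deterministic)."""

    shape: tuple[int, int] = (128, 128)  # (H, W)
    n_frames: int = 10
    objects: tuple[EllipseObject, ...] = ()
    n_channels: int = 2
    background: int = 10
    noise_sigma: float = 0.0
    seed: int = 0
    overlap_schedule: tuple[float, ...] | None = None  # target |A∩B|/|A| per frame
    lyso_intensity: int = 200  # brightness of schedule-generated lyso pixels
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.overlap_schedule is not None and len(self.overlap_schedule) != self.n_frames:
            raise ValueError("overlap_schedule length must equal n_frames")
        for obj in self.objects:
            if obj.channel >= self.n_channels:
                raise ValueError("object channel index out of range")


@dataclass
class GroundTruth:
    """Planted truth, pixel-exact with the pre-noise stack.

    centroids[t][i] -> (x, y) of object i in frame t (only objects present);
    pixel_sets[t][i] -> (N, 2) array of (row, col);
    channel_masks[t][c] -> boolean mask of channel c before noise;
    overlap[t] -> (n_mito_px, n_lyso_px, n_overlap_px).
    """

    centroids: list[dict[int, tuple[float, float]]]
    pixel_sets: list[dict[int, np.ndarray]]
    channel_masks: list[list[np.ndarray]]
    overlap: list[tuple[int, int, int]]
    object_channels: list[int] = field(default_factory=list)

    def count(self, frame: int, channel: int) -> int:
        return sum(1 for i in self.centroids[frame] if self.object_channels[i] == channel)


def rasterize_ellipse(shape: tuple[int, int], center: tuple[float, float],
                      a: float, b: float, orientation: float = 0.0) -> np.ndarray:
    """Boolean mask of a filled ellipse (no anti-aliasing)."""
    H, W = shape
    cx, cy = center
    yy, xx = np.mgrid[0:H, 0:W]
    dx = xx - cx
    dy = yy - cy
    c, s = math.cos(orientation), math.sin(orientation)
    # y grows downwards; use the y-up angle convention of morphometrics
    u = dx * c - dy * s
    v = dx * s + dy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _positions(obj: EllipseObject, spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[float, float] | None]:
    """Per-frame centre of one object (None when absent)."""
    H, W = spec.shape
    margin = max(obj.a, obj.b)
    vanish = obj.vanish if obj.vanish is not None else spec.n_frames
    pos: list[tuple[float, float] | None] = []
    x, y = obj.center
    # random-walk steps are drawn for every frame slot (present or not) so
    # that adding/removing other objects does not shift this object's path
    for t in range(spec.n_frames):
        if obj.rw_sigma is not None and t > obj.appear:
            step = rng.normal(0.0, obj.rw_sigma, size=2)
        else:
            step = None
        if t < obj.appear or t >= vanish:
            pos.append(None)
            continue
        if t > obj.appear:
            if obj.velocity is not None:
                x, y = x + obj.velocity[0], y + obj.velocity[1]
            elif step is not None:
                x, y = x + step[0], y + step[1]
        cx, cy = x, y
        if not (margin <= cx <= W - 1 - margin and margin <= cy <= H - 1 - margin):
            if not spec.clamp:
                raise ValueError(f"object leaves the field at frame {t} with clamp disabled")
            cx = min(max(cx, margin), W - 1 - margin)
            cy = min(max(cy, margin), H - 1 - margin)
            x, y = cx, cy
        pos.append((cx, cy))
    return pos


def generate_stack(spec: SyntheticSpec, path: str | Path | None = None) -> tuple[ImageStack, GroundTruth]:
    """Render the spec into an (un-preprocessed, 8-bit) stack plus ground truth.

    The same spec (same seed) always yields bit-identical pixels.  When
    *path* is given, the stack is also written as a multipage TIFF readable
    by :func:`organelletrack.stack_io.read_stack`.
    """
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    trajectories = [_positions(obj, spec, rng) for obj in spec.objects]

    pixels = np.full((spec.n_frames, spec.n_channels, H, W), spec.background, dtype=np.float64)
    gt = GroundTruth(
        centroids=[{} for _ in range(spec.n_frames)],
        pixel_sets=[{} for _ in range(spec.n_frames)],
        channel_masks=[[np.zeros((H, W), bool) for _ in range(spec.n_channels)]
                       for _ in range(spec.n_frames)],
        overlap=[],
        object_channels=[obj.channel for obj in spec.objects],
    )

    for t in range(spec.n_frames):
        for i, obj in enumerate(spec.objects):
            center = trajectories[i][t]
            if center is None:
                continue
            if spec.overlap_schedule is not None and obj.channel == 1:
                continue  # lyso channel is derived from the schedule
            mask = rasterize_ellipse((H, W), center, obj.a, obj.b, obj.orientation)
            pixels[t, obj.channel][mask] = np.maximum(pixels[t, obj.channel][mask], obj.intensity)
            gt.channel_masks[t][obj.channel] |= mask
            coords = np.argwhere(mask)
            gt.pixel_sets[t][i] = coords
            gt.centroids[t][i] = (float(coords[:, 1].mean()), float(coords[:, 0].mean()))

        if spec.overlap_schedule is not None:
            a_mask = gt.channel_masks[t][0]
            n_a = int(a_mask.sum())
            k = int(round(spec.overlap_schedule[t] * n_a))
            b_mask = np.zeros((H, W), bool)
            if k > 0:
                rows, cols = np.nonzero(a_mask)  # raster order
                b_mask[rows[:k], cols[:k]] = True
            pixels[t, 1][b_mask] = spec.lyso_intensity
            gt.channel_masks[t][1] = b_mask

        n_mito = int(gt.channel_masks[t][0].sum())
        n_lyso = int(gt.channel_masks[t][1].sum())
        n_both = int((gt.channel_masks[t][0] & gt.channel_masks[t][1]).sum())
        gt.overlap.append((n_mito, n_lyso, n_both))

    if spec.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, size=pixels.shape)
    pixels = np.rint(np.clip(pixels, 0, 255)).astype(np.uint8)

    stack = ImageStack(pixels=pixels, bit_depth_note="uint8 (synthetic)", preprocessed=False)
    if path is not None:
        write_stack(stack, path)
    return stack, gt


def _spread_centers(n: int, shape: tuple[int, int], margin: float, min_gap: float,
                    seed: int) -> list[tuple[float, float]]:
    """Deterministic well-separated centres on a jittered grid."""
    H, W = shape
    rng = np.random.default_rng(seed)
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    xs = np.linspace(margin, W - 1 - margin, cols)
    ys = np.linspace(margin, H - 1 - margin, rows)
    centers = []
    for j in range(rows):
        for i in range(cols):
            if len(centers) == n:
                break
            jitter = rng.uniform(-min_gap / 4, min_gap / 4, size=2)
            centers.append((float(xs[i] + jitter[0]), float(ys[j] + jitter[1])))
    return centers


def preset_fixtures() -> dict[str, SyntheticSpec]:
    """Catalogue of named specs used throughout the test suite and examples."""
    presets: dict[str, SyntheticSpec] = {}

    # "counting": 5 mito ellipses + 7 lyso discs, static, noise-free
    mito = [
        EllipseObject(channel=0, a=8, b=4, center=c, orientation=0.4 * i, intensity=200)
        for i, c in enumerate(_spread_centers(5, (128, 128), 14, 20, seed=11))
    ]
    lyso = [
        EllipseObject(channel=1, a=3.2, b=3.2, center=c, intensity=220)
        for c in _spread_centers(7, (128, 128), 10, 18, seed=12)
    ]
    presets["counting"] = SyntheticSpec(
        shape=(128, 128), n_frames=12, objects=tuple(mito + lyso), background=10, seed=1
    )

    # "morphology": elongated 50x10 ellipses + punctate discs on both sides
    # of the default (area_thresh=50, ecc_thresh=0.8) decision boundary
    elong = [
        EllipseObject(channel=0, a=25, b=5, center=(40.5, 30.5 + 40 * i), intensity=210)
        for i in range(2)
    ]
    punct = [
        EllipseObject(channel=0, a=3.5, b=3.5, center=(100.5, 20.5 + 28 * i), intensity=210)
        for i in range(4)
    ]
    lyso_m = [
        EllipseObject(channel=1, a=3.0, b=3.0, center=c, intensity=220)
        for c in _spread_centers(5, (140, 140), 10, 18, seed=13)
    ]
    presets["morphology"] = SyntheticSpec(
        shape=(140, 140), n_frames=6, objects=tuple(elong + punct + lyso_m), seed=2
    )

    # "tracking": linear movers + random walkers, steps < default max_dist
    movers = [
        EllipseObject(channel=0, a=4, b=4, center=(20.0, 20.0 + 28 * i),
                      velocity=(2.0, 0.0), intensity=200)
        for i in range(3)
    ] + [
        EllipseObject(channel=0, a=4, b=4, center=(100.0, 30.0 + 40 * i),
                      rw_sigma=1.0, intensity=200)
        for i in range(2)
    ]
    lyso_t = [
        EllipseObject(channel=1, a=3.0, b=3.0, center=(30.0 + 22 * i, 105.0),
                      velocity=(1.5, 0.0), intensity=220)
        for i in range(3)
    ]
    presets["tracking"] = SyntheticSpec(
        shape=(160, 160), n_frames=20, objects=tuple(movers + lyso_t), seed=3
    )

    # "coloc-schedule": 4 discs of r=8 -> |A| = 788 px, divisible by 4, so
    # the planted fractions {1, .75, .5, .25, 0} give exact pixel counts
    coloc_mito = [
        EllipseObject(channel=0, a=8, b=8, center=c, intensity=200)
        for c in [(30.0, 30.0), (90.0, 30.0), (30.0, 90.0), (90.0, 90.0)]
    ]
    presets["coloc-schedule"] = SyntheticSpec(
        shape=(128, 128), n_frames=5, objects=tuple(coloc_mito),
        overlap_schedule=(1.0, 0.75, 0.5, 0.25, 0.0), seed=4
    )

    # "integration": static mito field; one extra lysosome appears per frame,
    # each fully inside a mito disc, so lyso_count and M1 are both linear in t
    int_mito = [
        EllipseObject(channel=0, a=9, b=9, center=(18.0 + 22 * i, 64.0), intensity=200)
        for i in range(5)
    ]
    int_lyso = [
        EllipseObject(channel=1, a=2.5, b=2.5, center=(18.0 + 22 * (i % 5), 58.0 + 12 * (i // 5)),
                      intensity=220, appear=i)
        for i in range(10)
    ]
    presets["integration"] = SyntheticSpec(
        shape=(128, 128), n_frames=10, objects=tuple(int_mito + int_lyso), seed=5
    )

    # "two-conditions": same layout, planted speeds 1 vs 3 px/frame
    def _condition(speed: float, seed: int) -> SyntheticSpec:
        mito_c = [
            EllipseObject(channel=0, a=4, b=4, center=(25.0, 18.0 + 26 * i),
                          velocity=(speed, 0.0), intensity=200)
            for i in range(5)
        ]
        lyso_c = [
            EllipseObject(channel=1, a=3.0, b=3.0, center=(25.0, 30.0 + 26 * i),
                          velocity=(speed, 0.2), intensity=220)
            for i in range(5)
        ]
        return SyntheticSpec(shape=(160, 160), n_frames=20,
                             objects=tuple(mito_c + lyso_c),
                             noise_sigma=4.0, seed=seed)

    presets["two-conditions-slow"] = _condition(1.0, seed=6)
    presets["two-conditions-fast"] = _condition(3.0, seed=7)
    return presets


def get_preset(name: str, seed: int | None = None) -> SyntheticSpec:
    """Look up a preset by name; optionally override its seed."""
    presets = preset_fixtures()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(sorted(presets))}")
    spec = presets[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec
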