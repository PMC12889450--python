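"""Reading, validation and standardisation of multichannel time-lapse TIFF stacks.

Stacks are normalised to a ``frames x channels x height x width`` (TCYX)
uint array regardless of the axis order on disk.  Preprocessing converts
each channel to 8-bit by a per-channel min--max rescale computed over the
*whole* stack (not per frame), so that temporal intensity trends survive the
conversion, and optionally upscales the spatial axes by an integer factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = ["ChannelConfig", "ImageStack", "read_stack", "write_stack", "preprocess"]


@dataclass(frozen=True)
class ChannelConfig:
    """Channel assignment and physical calibration of a two-channel recording.

    Parameters
    ----------
    mito_channel, lyso_channel
        Zero-based channel indices of the mitochondrial and lysosomal
        channels.  The conventional layout is mitochondria in channel 0 and
        lysosomes in channel 1.
    frame_interval_s
        Seconds between consecutive frames (default 5 s).
    upscale_factor
        Integer spatial upscaling applied during preprocessing; 2x is a
        common choice for dim or low-resolution recordings.
    pixel_size_um
        Micrometres per pixel (of the *original* image, before upscaling).
        When absent, all lengths downstream are reported in pixels.
    interpolation
        ``"nearest"`` (default, preserves crisp object edges) or
        ``"bilinear"``.
    """

    mito_channel: int = 0
    lyso_channel: int = 1
    frame_interval_s: float = 5.0
    upscale_factor: int = 1
    pixel_size_um: float | None = None
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        if self.mito_channel == self.lyso_channel:
            raise ValueError("mito_channel and lyso_channel must differ")
        if self.mito_channel < 0 or self.lyso_channel < 0:
            raise ValueError("channel indices must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if int(self.upscale_factor) != self.upscale_factor or self.upscale_factor < 1:
            raise ValueError("upscale_factor must be an integer >= 1")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0 when given")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")

    @property
    def effective_pixel_size_um(self) -> float | None:
        """Pixel size after upscaling (None when uncalibrated)."""
        if self.pixel_size_um is None:
            return None
        return self.pixel_size_um / self.upscale_factor


@dataclass
class ImageStack:
    """A frames x channels x height x width intensity grid.

    ``pixels`` is always TCYX.  ``preprocessed`` records whether the 8-bit
    conversion / upscaling pass has run; downstream stages require it.
    """

    pixels: np.ndarray
    bit_depth_note: str = "uint8"
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("ImageStack pixels must be 4-D (TCYX)")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, index: int) -> np.ndarray:
        """All frames of one channel, shape (T, H, W)."""
        return self.pixels[:, index]


_FRAME_AXES = "TIZQ"  # axis labels tifffile uses for a plain image sequence


def _normalize_axes(arr: np.ndarray, axes: str | None) -> np.ndarray:
    """Return the array as TCYX, inferring axis meaning when needed.

    Accepts frames-first (TCYX), channel-first (CTYX) and interleaved
    (TYXC) layouts.  When no usable metadata is present the smallest
    non-spatial axis of size <= 4 is assumed to be channels, and the
    assumption is logged.
    """
    if axes is not None and len(axes) == arr.ndim:
        keep = [i for i, n in enumerate(arr.shape) if n > 1]
        axes = "".join(axes[i] for i in keep)
    arr = np.squeeze(arr)
    if arr.ndim == 3:
        # single frame (CYX or YXC) -- a 2-channel stack needs a channel axis
        if axes and set(axes) <= set("CYX" + _FRAME_AXES) and "C" in axes:
            order = [axes.index("C"), axes.index("Y"), axes.index("X")]
            return arr.transpose(order)[np.newaxis]
        if arr.shape[0] <= 4:
            return arr[np.newaxis]  # CYX
        if arr.shape[-1] <= 4:
            logger.info("assuming interleaved YXC layout for 3-D array")
            return arr.transpose(2, 0, 1)[np.newaxis]
        raise ValueError(
            "channel count mismatch: cannot locate a channel axis in a "
            f"3-D array of shape {arr.shape}"
        )
    if arr.ndim != 4:
        raise ValueError(f"dimensional inconsistency: expected 3-D or 4-D data, got shape {arr.shape}")

    if axes and len(axes) == 4 and "C" in axes and "Y" in axes and "X" in axes:
        frame_axis = next((i for i, a in enumerate(axes) if a in _FRAME_AXES), None)
        if frame_axis is not None:
            order = [frame_axis, axes.index("C"), axes.index("Y"), axes.index("X")]
            return arr.transpose(order)
    # heuristic: YX are the trailing spatial axes unless the last axis is tiny
    if arr.shape[-1] <= 4 < arr.shape[-2]:
        logger.info("assuming interleaved TYXC layout (last axis size %d)", arr.shape[-1])
        return arr.transpose(0, 3, 1, 2)
    # remaining two leading axes are frames and channels; smaller one (<=4) is channels
    a0, a1 = arr.shape[0], arr.shape[1]
    if a1 <= 4 or a1 <= a0:
        return arr
    logger.info("assuming channel-first CTYX layout (axis sizes %d, %d)", a0, a1)
    return arr.transpose(1, 0, 2, 3)


def read_stack(path: str | Path, config: ChannelConfig) -> ImageStack:
    """Read a multichannel TIFF and return an un-preprocessed :class:`ImageStack`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        ``"channel count mismatch"`` when the file has fewer channels than
        the configured indices require, ``"dimensional inconsistency"`` when
        pages disagree in shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes
        try:
            arr = series.asarray()
        except (ValueError, IndexError) as exc:  # ragged pages
            raise ValueError(f"dimensional inconsistency in {path.name}: {exc}") from exc
        if len(tif.series) > 1 or (
            len(tif.pages) > 1
            and any(p.shape != tif.pages[0].shape for p in tif.pages if p is not None)
        ):
            raise ValueError(f"dimensional inconsistency: pages of {path.name} differ in shape")
    pixels = _normalize_axes(arr, axes)
    needed = max(config.mito_channel, config.lyso_channel) + 1
    if pixels.shape[1] < needed:
        raise ValueError(
            f"channel count mismatch: config needs {needed} channels, "
            f"file has {pixels.shape[1]}"
        )
    return ImageStack(pixels=pixels, bit_depth_note=str(arr.dtype), preprocessed=False)


def write_stack(pixels: np.ndarray | ImageStack, path: str | Path) -> Path:
    """Write a TCYX array as a multipage TIFF readable by :func:`read_stack`."""
    if isinstance(pixels, ImageStack):
        pixels = pixels.pixels
    if pixels.ndim != 4:
        raise ValueError("expected a 4-D TCYX array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, pixels, metadata={"axes": "TCYX"})
    return path


def _rescale_channel_to_uint8(channel: np.ndarray) -> np.ndarray:
    lo = float(channel.min())
    hi = float(channel.max())
    if hi == lo:
        logger.warning("constant-intensity channel (value %s): emitting all-zero 8-bit channel", lo)
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = (channel.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def _upscale(frame: np.ndarray, factor: int, interpolation: str) -> np.ndarray:
    if factor == 1:
        return frame
    if interpolation == "nearest":
        return np.repeat(np.repeat(frame, factor, axis=0), factor, axis=1)
    out = resize(
        frame.astype(np.float64),
        (frame.shape[0] * factor, frame.shape[1] * factor),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def preprocess(stack: ImageStack, config: ChannelConfig) -> ImageStack:
    """8-bit conversion (per-channel stack-wide min--max) plus optional upscaling.

    Returns a new stack; the input is left untouched.
    """
    if stack.preprocessed:
        raise ValueError("stack is already preprocessed")
    T, C, H, W = stack.pixels.shape
    k = config.upscale_factor
    out = np.empty((T, C, H * k, W * k), dtype=np.uint8)
    for c in range(C):
        chan8 = _rescale_channel_to_uint8(stack.pixels[:, c])
        for t in range(T):
            out[t, c] = _upscale(chan8[t], k, config.interpolation)
    return ImageStack(pixels=out, bit_depth_note=stack.bit_depth_note, preprocessed=True)
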