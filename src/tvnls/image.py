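"""Image container and PNG/TIFF input/output.

Intensities are handled as floating-point reals on the native integer scale
``[0, 2**bit_depth - 1]`` (so a sigma-20 noise level means the same thing it
does for an 8-bit photograph).  Clipping and integer rounding happen only at
export time; every operation inside the package works on unclipped reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = ["Image", "load_image", "save_image"]


@dataclass
class Image:
    """A 2D grayscale or 3-channel image of real-valued intensities.

    Parameters
    ----------
    pixels:
        ``(H, W)`` or ``(H, W, 3)`` float array.  Values may lie outside the
        nominal range; they are clipped only when saved.
    bit_depth:
        Bits per sample ``k``; the nominal intensity range is
        ``[0, 2**k - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D or (H, W, 3)")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color images must have exactly 3 channels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    # -- geometry -----------------------------------------------------------
    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def peak(self) -> float:
        """Top of the nominal intensity range, ``2**k - 1``."""
        return float(2**self.bit_depth - 1)

    def channels(self):
        """Iterate over 2D channel arrays (one for grayscale, three for RGB)."""
        if self.pixels.ndim == 2:
            yield self.pixels
        else:
            for c in range(3):
                yield self.pixels[:, :, c]

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        return Image(pixels=pixels, bit_depth=self.bit_depth)

    def copy(self) -> "Image":
        return Image(pixels=self.pixels.copy(), bit_depth=self.bit_depth)


def load_image(path) -> Image:
    """Read an 8- or 16-bit PNG/TIFF as an :class:`Image`.

    Grayscale and RGB are supported; other channel counts are rejected.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported sample type {arr.dtype} (expected 8/16-bit)")
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[2]} (expected 1 or 3)")
    elif arr.ndim != 2:
        raise ValueError("unsupported image layout")
    return Image(pixels=arr.astype(np.float64), bit_depth=bit_depth)


def _quantize(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    peak = 2**bit_depth - 1
    clipped = np.clip(pixels, 0.0, float(peak))
    # round half away from zero; values are non-negative after clipping
    rounded = np.floor(clipped + 0.5)
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    return rounded.astype(dtype)


def save_image(image: Image, path) -> None:
    """Clip to the nominal range, round half away from zero, and write.

    The output format follows the file extension (PNG or TIFF).
    """
    iio.imwrite(path, _quantize(image.pixels, image.bit_depth))
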