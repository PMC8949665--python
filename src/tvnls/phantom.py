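"""Synthetic test-image generator.

The phantom mixes the two kinds of structure the two regularizers target:
piecewise-constant overlapping rectangles and disks (favouring total
variation) and a block of exactly periodic texture (favouring nonlocal
self-similarity, since every texture tile has many exact duplicates for the
block matcher to find).  It stands in for external photographic test images,
which are not shipped.
"""

from __future__ import annotations

import numpy as np

from .image import Image

__all__ = ["make_phantom"]

#: RNG algorithm used for every stochastic operation in the package.
RNG_ALGORITHM = "PCG64"

BACKGROUND = 60.0


def make_phantom(
    height: int = 256,
    width: int = 256,
    texture_period: int = 8,
    n_shapes: int = 6,
    seed: int = 0,
) -> Image:
    """Generate a deterministic piecewise-constant + periodic-texture phantom.

    Parameters
    ----------
    height, width:
        Image size; at least 32 each.
    texture_period:
        Side of the square texture tile, >= 2.  ``0`` disables the texture
        region entirely.
    n_shapes:
        Number of random rectangles/disks painted over the background.
    seed:
        Seed for the PCG64 generator; the output is a pure function of the
        arguments.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom must be at least 32x32")
    if texture_period != 0 and texture_period < 2:
        raise ValueError("texture_period must be 0 (off) or >= 2")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), BACKGROUND, dtype=np.float64)

    for _ in range(n_shapes):
        value = rng.uniform(20.0, 235.0)
        if rng.integers(2) == 0:  # rectangle
            h = int(rng.integers(height // 8, height // 2 + 1))
            w = int(rng.integers(width // 8, width // 2 + 1))
            r0 = int(rng.integers(0, height - h + 1))
            c0 = int(rng.integers(0, width - w + 1))
            img[r0 : r0 + h, c0 : c0 + w] = value
        else:  # disk
            radius = float(rng.uniform(min(height, width) / 12, min(height, width) / 4))
            cr = float(rng.uniform(radius, height - radius))
            cc = float(rng.uniform(radius, width - radius))
            rr, cc_grid = np.ogrid[:height, :width]
            img[(rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2] = value

    if texture_period:
        t = texture_period
        # bottom-right region, trimmed to a whole number of tiles, covering
        # roughly a quarter of the image
        th = (height // 2) // t * t
        tw = (width // 2) // t * t
        if th >= t and tw >= t:
            # oriented sinusoidal weave with fine-grain jitter: moderate
            # contrast comparable to natural fabric texture, and exactly
            # periodic so every tile-aligned block has many duplicates
            base = rng.uniform(90.0, 160.0)
            amp = rng.uniform(25.0, 45.0)
            fi, fj = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            ii, jj = np.meshgrid(np.arange(t), np.arange(t), indexing="ij")
            tile = base + amp * np.sin(2.0 * np.pi * (fi * ii + fj * jj) / t + phase)
            tile += rng.uniform(-8.0, 8.0, size=(t, t))
            texture = np.tile(tile, (th // t, tw // t))
            img[height - th :, width - tw :] = texture

    return Image(pixels=np.clip(img, 0.0, 255.0), bit_depth=8)
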