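"""Noise simulators: additive white Gaussian noise and salt-and-pepper.

Both are pure functions of (input, parameters, seed).  Per-pixel random
draws come from a single PCG64 stream filled in row-major scan order, so a
given (image, parameters, seed) triple always produces the same corruption
pattern.  Noisy outputs are NOT clipped to the nominal range (the solver
works on unclipped reals); pass ``clip=True`` to emulate a pipeline that
stores the noisy image at native bit depth before denoising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .image import Image

__all__ = ["NoiseSpec", "add_awgn", "add_salt_pepper", "apply_noise"]


@dataclass
class NoiseSpec:
    """Declarative description of a corruption process.

    ``kind`` is ``"awgn"`` (Gaussian, parameters ``sigma``/``mean``) or
    ``"salt_pepper"`` (impulses: intensity ``v_max`` with probability ``q1``,
    ``v_min`` with probability ``q2``).  When only a total impulse level ``q``
    is known, use the symmetric split ``q1 = q2 = q/2``.
    """

    kind: str = "awgn"
    sigma: float = 0.0
    mean: float = 0.0
    q1: float = 0.0
    q2: float = 0.0
    v_max: Optional[float] = None  # default: 2**k - 1 of the target image
    v_min: float = 0.0
    seed: int = 0
    clip: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("awgn", "salt_pepper"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.q1 < 0 or self.q2 < 0 or self.q1 + self.q2 > 1:
            raise ValueError("need q1, q2 >= 0 and q1 + q2 <= 1")

    @classmethod
    def salt_pepper_level(cls, q: float, seed: int = 0, **kw) -> "NoiseSpec":
        """Symmetric salt-and-pepper spec from a total level ``q = q1 + q2``."""
        return cls(kind="salt_pepper", q1=q / 2, q2=q / 2, seed=seed, **kw)


def _maybe_clip(pixels: np.ndarray, image: Image, clip: bool) -> np.ndarray:
    if clip:
        return np.clip(pixels, 0.0, image.peak)
    return pixels


def add_awgn(
    image: Image, sigma: float, mean: float = 0.0, seed: int = 0, clip: bool = False
) -> Image:
    """Add independent Gaussian(mean, sigma^2) noise to every sample."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(loc=mean, scale=sigma, size=image.pixels.shape) if sigma > 0 else mean
    return image.with_pixels(_maybe_clip(image.pixels + noise, image, clip))


def add_salt_pepper(
    image: Image,
    q1: float,
    q2: float,
    v_max: Optional[float] = None,
    v_min: float = 0.0,
    seed: int = 0,
    clip: bool = False,
) -> Image:
    """Set each sample to ``v_max`` w.p. ``q1``, ``v_min`` w.p. ``q2``.

    All other samples are left bit-identical to the input.
    """
    if q1 < 0 or q2 < 0:
        raise ValueError("q1 and q2 must be >= 0")
    if q1 + q2 > 1:
        raise ValueError("q1 + q2 must be <= 1")
    if v_max is None:
        v_max = image.peak
    rng = np.random.default_rng(seed)
    draw = rng.random(size=image.pixels.shape)
    out = image.pixels.copy()
    out[draw < q1] = v_max
    out[(draw >= q1) & (draw < q1 + q2)] = v_min
    return image.with_pixels(_maybe_clip(out, image, clip))


def apply_noise(image: Image, spec: NoiseSpec) -> Image:
    """Apply a :class:`NoiseSpec` to an image."""
    if spec.kind == "awgn":
        return add_awgn(image, spec.sigma, spec.mean, spec.seed, spec.clip)
    return add_salt_pepper(
        image, spec.q1, spec.q2, spec.v_max, spec.v_min, spec.seed, spec.clip
    )
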