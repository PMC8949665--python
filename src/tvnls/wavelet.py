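"""Wavelet-shrinkage denoising baseline.

The classical three-step scheme: multilevel orthogonal DWT, thresholding of
every detail subband with a single global threshold (the approximation band
is left untouched), inverse DWT.  The default threshold is the universal
rule ``S = sigma * sqrt(2 ln N)`` with ``N`` the pixel count, ``sigma``
known or MAD-estimated from the finest diagonal detail band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pywt

from .image import Image

__all__ = ["WaveletConfig", "universal_threshold", "estimate_sigma_mad", "wavelet_denoise"]

MAD_SCALE = 0.6745  # Phi^{-1}(0.75): MAD-to-sigma for a Gaussian


@dataclass
class WaveletConfig:
    wavelet: str = "db4"
    levels: Optional[int] = None  # None: min(4, feasible maximum)
    mode: str = "soft"  # soft | hard
    threshold: Union[float, str] = "universal"
    sigma: Union[float, str] = "estimate"
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels is not None and self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.mode not in ("soft", "hard"):
            raise ValueError(f"unknown thresholding mode {self.mode!r}")
        if isinstance(self.threshold, str) and self.threshold != "universal":
            raise ValueError("threshold must be a number or 'universal'")
        if not isinstance(self.threshold, str) and self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def universal_threshold(sigma: float, n_pixels: int) -> float:
    """``sigma * sqrt(2 ln N)`` (natural logarithm)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    return sigma * math.sqrt(2.0 * math.log(n_pixels))


def estimate_sigma_mad(image, wavelet: str = "db4") -> float:
    """Noise level from the finest diagonal detail band: ``median|d| / 0.6745``."""
    arr = image.pixels if isinstance(image, Image) else np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        return float(np.mean([estimate_sigma_mad(arr[..., c], wavelet) for c in range(3)]))
    _, (_, _, diag) = pywt.dwt2(arr, wavelet, mode="symmetric")
    return float(np.median(np.abs(diag)) / MAD_SCALE)


def _threshold(coeffs: np.ndarray, s: float, mode: str) -> np.ndarray:
    if mode == "soft":
        return np.sign(coeffs) * np.maximum(np.abs(coeffs) - s, 0.0)
    return np.where(np.abs(coeffs) > s, coeffs, 0.0)


def _denoise_channel(arr: np.ndarray, config: WaveletConfig, s: float) -> np.ndarray:
    max_level = pywt.dwtn_max_level(arr.shape, config.wavelet)
    levels = min(4, max_level) if config.levels is None else config.levels
    if levels > max_level or levels < 1:
        raise ValueError(
            f"{config.levels} levels infeasible for shape {arr.shape} "
            f"with {config.wavelet} (max {max_level})"
        )
    coeffs = pywt.wavedec2(arr, config.wavelet, mode=config.boundary, level=levels)
    out = [coeffs[0]] + [
        tuple(_threshold(d, s, config.mode) for d in detail) for detail in coeffs[1:]
    ]
    rec = pywt.waverec2(out, config.wavelet, mode=config.boundary)
    return rec[: arr.shape[0], : arr.shape[1]]


def wavelet_denoise(image: Image, config: WaveletConfig = WaveletConfig()) -> Image:
    """Denoise by global thresholding of all detail subbands."""
    if isinstance(config.threshold, str):  # universal rule
        if isinstance(config.sigma, str):
            sigma = estimate_sigma_mad(image, config.wavelet)
        else:
            sigma = float(config.sigma)
        s = universal_threshold(sigma, image.n_pixels)
    else:
        s = float(config.threshold)
    if image.n_channels == 1:
        pixels = _denoise_channel(image.pixels, config, s)
    else:
        pixels = np.stack(
            [_denoise_channel(image.pixels[..., c], config, s) for c in range(3)], axis=-1
        )
    return image.with_pixels(pixels)
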