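"""Image-quality metrics: MSE, PSNR, and SSIM.

PSNR uses the native peak ``2**k - 1`` of the declared bit depth, so 8-bit
images are scored against 255 regardless of their actual dynamic range.
SSIM is the product of luminance, contrast and structure comparisons; the
reporting default is the mean over sliding 8x8 uniform windows, with a
whole-image "global" mode also available.  With ``c3 = c2/2`` the structure
term can make SSIM negative for anti-correlated images; an optional clamp
maps the result into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import Image

__all__ = ["SSIMConfig", "mse", "psnr", "ssim"]


@dataclass
class SSIMConfig:
    k1: float = 0.01
    k2: float = 0.03
    window: str = "sliding"  # sliding | global
    window_size: int = 8
    clamp: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.k1 < 1 and 0 < self.k2 < 1):
            raise ValueError("K1 and K2 must be small positive constants")
        if self.window not in ("sliding", "global"):
            raise ValueError(f"unknown SSIM window mode {self.window!r}")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(u, u_hat) -> float:
    """Mean squared pixel difference (mean over channels for color)."""
    a, b = _pixels(u), _pixels(u_hat)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(u: Image, u_hat, k: int | None = None) -> float:
    """``10 log10(peak^2 / MSE)`` in dB; ``inf`` for identical images."""
    if k is None:
        k = u.bit_depth if isinstance(u, Image) else 8
    if k < 1:
        raise ValueError("bit depth must be >= 1")
    err = mse(u, u_hat)
    peak = float(2**k - 1)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def _ssim_terms(mu1, mu2, var1, var2, cov, c1, c2):
    # luminance * contrast * structure; with c3 = c2/2 the contrast and
    # structure factors combine exactly into (2*cov + c2)/(var1 + var2 + c2)
    lum = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
    cs = (2 * cov + c2) / (var1 + var2 + c2)
    return lum * cs


def _ssim_channel(a: np.ndarray, b: np.ndarray, peak: float, config: SSIMConfig) -> float:
    c1 = (config.k1 * peak) ** 2
    c2 = (config.k2 * peak) ** 2
    if config.window == "global":
        mu1, mu2 = a.mean(), b.mean()
        # uncentered second moments so cov(a, a) == var(a) bitwise
        var1 = (a * a).mean() - mu1 * mu1
        var2 = (b * b).mean() - mu2 * mu2
        cov = (a * b).mean() - mu1 * mu2
        return float(_ssim_terms(mu1, mu2, var1, var2, cov, c1, c2))
    ws = config.window_size
    if a.shape[0] < ws or a.shape[1] < ws:
        raise ValueError("image smaller than the SSIM window")
    wa = sliding_window_view(a, (ws, ws))
    wb = sliding_window_view(b, (ws, ws))
    mu1 = wa.mean(axis=(2, 3))
    mu2 = wb.mean(axis=(2, 3))
    var1 = (wa * wa).mean(axis=(2, 3)) - mu1 * mu1
    var2 = (wb * wb).mean(axis=(2, 3)) - mu2 * mu2
    cov = (wa * wb).mean(axis=(2, 3)) - mu1 * mu2
    return float(np.mean(_ssim_terms(mu1, mu2, var1, var2, cov, c1, c2)))


def ssim(u, u_hat, config: SSIMConfig = SSIMConfig()) -> float:
    """Structural similarity between two images (1 means identical)."""
    a, b = _pixels(u), _pixels(u_hat)
    _check_shapes(a, b)
    peak = u.peak if isinstance(u, Image) else 255.0
    if a.ndim == 2:
        val = _ssim_channel(a, b, peak, config)
    else:
        val = float(
            np.mean([_ssim_channel(a[..., c], b[..., c], peak, config) for c in range(3)])
        )
    if config.clamp:
        val = min(max(val, 0.0), 1.0)
    return val
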