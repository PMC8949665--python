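"""Discrete gradient, total variation, and the TV (w) subproblem.

Finite differences are forward differences with periodic (circular)
boundaries, so ``D^T D`` is diagonalized by the 2D DFT and the quadratic
u-update can be solved exactly in the Fourier domain.  The w-subproblem

    min_w  tau*||w||_1 - gamma^T (Du - w) + rho/2 * ||Du - w||_2^2

has the closed-form solution ``w = shrink(Du - gamma/rho, tau/rho)`` with
``shrink`` the soft-thresholding (l1 proximal) operator, applied
independently to the horizontal and vertical components (anisotropic TV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GradientField",
    "gradient",
    "gradient_adjoint",
    "total_variation",
    "soft_threshold",
    "solve_w_subproblem",
    "dtd_eigenvalues",
]


@dataclass
class GradientField:
    """Pair of per-pixel finite differences (``D_h u``, ``D_v u``).

    Also used as the container for the split variable ``w`` and the
    Lagrange multiplier ``gamma``, which live in the same space.
    """

    horizontal: np.ndarray
    vertical: np.ndarray

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=np.float64)
        self.vertical = np.asarray(self.vertical, dtype=np.float64)
        if self.horizontal.shape != self.vertical.shape:
            raise ValueError("gradient components must share a shape")

    @classmethod
    def zeros(cls, shape) -> "GradientField":
        return cls(np.zeros(shape), np.zeros(shape))

    # elementwise arithmetic, used by the solver updates
    def __add__(self, other: "GradientField") -> "GradientField":
        return GradientField(self.horizontal + other.horizontal, self.vertical + other.vertical)

    def __sub__(self, other: "GradientField") -> "GradientField":
        return GradientField(self.horizontal - other.horizontal, self.vertical - other.vertical)

    def __mul__(self, s: float) -> "GradientField":
        return GradientField(self.horizontal * s, self.vertical * s)

    __rmul__ = __mul__

    def norm(self) -> float:
        """Euclidean norm over both components."""
        return float(np.sqrt(np.sum(self.horizontal**2) + np.sum(self.vertical**2)))

    def dot(self, other: "GradientField") -> float:
        return float(
            np.sum(self.horizontal * other.horizontal) + np.sum(self.vertical * other.vertical)
        )

    def l1(self) -> float:
        return float(np.sum(np.abs(self.horizontal)) + np.sum(np.abs(self.vertical)))


def gradient(u: np.ndarray) -> GradientField:
    """Forward differences with periodic wrap: ``(D_h u)[i,j] = u[i,(j+1)%W] - u[i,j]``."""
    u = np.asarray(u, dtype=np.float64)
    return GradientField(
        horizontal=np.roll(u, -1, axis=1) - u,
        vertical=np.roll(u, -1, axis=0) - u,
    )


def gradient_adjoint(p: GradientField) -> np.ndarray:
    """Exact adjoint ``D^T p`` (negative divergence) under periodic wrap."""
    ph, pv = p.horizontal, p.vertical
    return (np.roll(ph, 1, axis=1) - ph) + (np.roll(pv, 1, axis=0) - pv)


def total_variation(u: np.ndarray, norm: str = "anisotropic_l1") -> float:
    """TV(u): l1 (anisotropic, default) or l2 (isotropic) norm of the gradient."""
    g = gradient(u)
    if norm == "anisotropic_l1":
        return g.l1()
    if norm == "isotropic_l2":
        return float(np.sum(np.sqrt(g.horizontal**2 + g.vertical**2)))
    raise ValueError(f"unknown TV norm {norm!r}")


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """``sgn(v) * max(|v| - t, 0)``: the proximal map of ``t*|.|``."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(v, dtype=np.float64)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def solve_w_subproblem(
    Du: GradientField, gamma: GradientField, rho_tv: float, tau: float
) -> GradientField:
    """Closed-form minimizer of the anisotropic-TV splitting subproblem."""
    if rho_tv <= 0:
        raise ValueError("rho_tv must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    t = tau / rho_tv
    return GradientField(
        soft_threshold(Du.horizontal - gamma.horizontal / rho_tv, t),
        soft_threshold(Du.vertical - gamma.vertical / rho_tv, t),
    )


def dtd_eigenvalues(shape) -> np.ndarray:
    """DFT symbol of ``D^T D`` (the periodic 5-point Laplacian ``-Delta``).

    Entry ``(l, k)`` is ``4 sin^2(pi l / H) + 4 sin^2(pi k / W)``; dividing by
    these (plus the data/penalty terms) in the Fourier domain solves the
    u-update exactly when ``A^T A = I``.
    """
    h, w = shape
    fy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(h) / h)
    fx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(w) / w)
    return fy[:, None] + fx[None, :]
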