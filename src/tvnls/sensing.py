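"""Linear measurement operators for compressed sensing.

A :class:`SensingOperator` is the map ``A`` in the measurement model
``f = A u`` (``u`` the vectorized image, row-major).  Three kinds are
provided:

``identity``
    ``M = N``; the pure-denoising case.
``subsampled_orthonormal``
    ``A = R F S``: a random diagonal +/-1 sign flip ``S``, an orthonormal
    DCT-II ``F``, and a random row selection ``R`` of ``M`` rows.  Applies in
    ``O(N log N)`` and has orthonormal rows (``A A^T = I``).
``explicit_matrix``
    A dense matrix, for tiny instances where a dense oracle is wanted.

Operators are deterministic functions of their stored parameters and can be
round-tripped through a plain dict for config-file serialization.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.fft import dct, idct

from .image import Image

__all__ = [
    "SensingOperator",
    "identity_operator",
    "subsampled_transform_operator",
    "matrix_operator",
    "measure",
]


class SensingOperator:
    """Matched apply/adjoint pair for a linear measurement map."""

    def __init__(
        self,
        kind: str,
        n_cols: int,
        n_rows: int,
        seed: int = 0,
        rows: Optional[np.ndarray] = None,
        signs: Optional[np.ndarray] = None,
        matrix: Optional[np.ndarray] = None,
    ):
        if kind not in ("identity", "subsampled_orthonormal", "explicit_matrix"):
            raise ValueError(f"unknown operator kind {kind!r}")
        if not (1 <= n_rows <= n_cols):
            raise ValueError("need 1 <= n_rows <= n_cols")
        self.kind = kind
        self.n_cols = int(n_cols)
        self.n_rows = int(n_rows)
        self.seed = int(seed)
        self.rows = rows
        self.signs = signs
        self.matrix = matrix

    # -- core contracts -----------------------------------------------------
    def apply(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64).ravel()
        if u.size != self.n_cols:
            raise ValueError(f"expected length-{self.n_cols} vector, got {u.size}")
        if self.kind == "identity":
            return u.copy()
        if self.kind == "explicit_matrix":
            return self.matrix @ u
        return dct(self.signs * u, norm="ortho")[self.rows]

    def adjoint(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=np.float64).ravel()
        if f.size != self.n_rows:
            raise ValueError(f"expected length-{self.n_rows} vector, got {f.size}")
        if self.kind == "identity":
            return f.copy()
        if self.kind == "explicit_matrix":
            return self.matrix.T @ f
        y = np.zeros(self.n_cols)
        y[self.rows] = f
        return self.signs * idct(y, norm="ortho")

    @property
    def gram_is_identity(self) -> bool:
        """True when ``A^T A = I`` (enables the spectral u-update path)."""
        return self.kind == "identity" or (
            self.kind == "subsampled_orthonormal" and self.n_rows == self.n_cols
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"kind": self.kind, "n_cols": self.n_cols, "n_rows": self.n_rows, "seed": self.seed}
        if self.kind == "explicit_matrix":
            d["matrix"] = np.asarray(self.matrix).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensingOperator":
        kind = d["kind"]
        if kind == "identity":
            return identity_operator(d["n_cols"])
        if kind == "subsampled_orthonormal":
            return subsampled_transform_operator(d["n_cols"], d["n_rows"], d["seed"])
        return matrix_operator(np.asarray(d["matrix"], dtype=np.float64))


def identity_operator(n: int) -> SensingOperator:
    """The identity map (M = N): measurement is the image itself."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return SensingOperator("identity", n_cols=n, n_rows=n)


def subsampled_transform_operator(n: int, m_rows: int, seed: int = 0) -> SensingOperator:
    """Randomly signed, row-subsampled orthonormal DCT measurement map."""
    if not (1 <= m_rows <= n):
        raise ValueError("need 1 <= m_rows <= n")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n)
    rows = np.sort(rng.choice(n, size=m_rows, replace=False))
    return SensingOperator(
        "subsampled_orthonormal", n_cols=n, n_rows=m_rows, seed=seed, rows=rows, signs=signs
    )


def matrix_operator(matrix: np.ndarray) -> SensingOperator:
    """Dense explicit operator for small oracle instances."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2D")
    m, n = matrix.shape
    return SensingOperator("explicit_matrix", n_cols=n, n_rows=m, matrix=matrix)


def measure(op: SensingOperator, image: Image) -> np.ndarray:
    """Acquire ``f = A vec(image)`` (row-major vectorization, per channel)."""
    if image.n_channels != 1:
        raise ValueError("measure operates on single-channel images")
    if op.n_cols != image.n_pixels:
        raise ValueError(
            f"operator expects {op.n_cols} pixels, image has {image.n_pixels}"
        )
    return op.apply(image.pixels.ravel())
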