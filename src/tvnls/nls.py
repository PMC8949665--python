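"""Nonlocal self-similarity: block matching, group transforms, aggregation.

An image is scanned with overlapping ``n x n`` reference blocks on a stride
grid.  For each reference block, the ``m - 1`` most similar blocks (squared
Euclidean distance, ties broken in row-major candidate order) inside an
``L x L`` search window are stacked with it into an ``n x n x m`` group.  An
orthonormal separable 3D transform sparsifies each group; the nonlocal
regularizer is the sum of l1 norms of all group coefficients.

The x-subproblem of the splitting scheme

    min_x  lambda*||theta(x)||_1 + rho/2*||u - x||_2^2 - phi^T (u - x)

is solved approximately, group by group, on ``r = u - phi/rho``: transform,
soft-threshold every coefficient at ``thr = c*K*lambda/(N*rho)`` (with
``K = n*n*m`` coefficients per group, ``N`` the image pixel count and ``c``
a threshold scale), inverse-transform, then aggregate overlapping blocks by
uniform averaging (each pixel divided by its coverage count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn

from .image import Image

__all__ = [
    "NLSParams",
    "BlockGroup",
    "CoefficientStack",
    "reference_grid",
    "find_similar_blocks",
    "group_transform",
    "group_inverse",
    "nls_norm",
    "solve_x_subproblem",
    "aggregate",
]


@dataclass
class NLSParams:
    """Block-matching and group-transform parameters.

    block_size ``n``: pixels per block side.  group_size ``m``: blocks per
    group including the reference.  search_window ``L``: side of the square
    matching window centred on the reference block.  step: stride of the
    reference-block grid (the last row/column position is always included so
    every pixel is covered).  threshold_scale ``c``: multiplier on the
    coefficient threshold ``K*lambda/(N*rho)``; the default 2 follows the
    source shrinkage rule, ``c = 1`` gives the plain proximal threshold.
    """

    block_size: int = 8
    group_size: int = 16
    search_window: int = 39
    step: int = 4
    transform: str = "dct3d"
    threshold_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.search_window < self.block_size:
            raise ValueError("search_window must be >= block_size")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.transform not in ("dct3d", "dct2d_haar1d"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class BlockGroup:
    """A reference block plus its matched companions.

    ``stack`` has shape ``(n, n, m)`` with the reference block at
    ``stack[:, :, 0]``; ``member_indices`` are top-left corners in
    nondecreasing distance order.
    """

    reference_index: Tuple[int, int]
    member_indices: List[Tuple[int, int]]
    stack: np.ndarray


@dataclass
class CoefficientStack:
    """3D transform coefficients of one group (same shape as the stack)."""

    coefficients: np.ndarray
    transform: str = "dct3d"


def _grid_1d(size: int, n: int, step: int) -> np.ndarray:
    pos = np.arange(0, size - n + 1, step)
    if pos[-1] != size - n:
        pos = np.append(pos, size - n)
    return pos


def reference_grid(shape, params: NLSParams) -> np.ndarray:
    """Top-left corners of the reference blocks, shape ``(G, 2)``, row-major."""
    h, w = shape
    n = params.block_size
    if h < n or w < n:
        raise ValueError("image smaller than one block")
    rows = _grid_1d(h, n, params.step)
    cols = _grid_1d(w, n, params.step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _window_bounds(ref: Tuple[int, int], shape, params: NLSParams):
    h, w = shape
    n, L = params.block_size, params.search_window
    lo = (L - n) // 2
    hi = L - n - lo
    ri, rj = ref
    return (
        max(0, ri - lo),
        min(h - n, ri + hi),
        max(0, rj - lo),
        min(w - n, rj + hi),
    )


def _match_one(view: np.ndarray, ref: Tuple[int, int], shape, params: NLSParams):
    """Member (row, col) arrays for one reference block.

    ``view`` is ``sliding_window_view(arr, (n, n))``.  Candidates are all
    blocks fully inside both the image and the search window; the reference
    is always member 0 and the remaining members are the stable
    (row-major tie-broken) distance sort of the other candidates.
    """
    a0, a1, b0, b1 = _window_bounds(ref, shape, params)
    ri, rj = ref
    refblk = view[ri, rj]
    cand = view[a0 : a1 + 1, b0 : b1 + 1]
    d = ((cand - refblk) ** 2).sum(axis=(2, 3)).ravel()
    n_cand = d.size
    if n_cand < params.group_size:
        raise ValueError(
            f"search window holds {n_cand} candidate blocks, "
            f"fewer than group_size={params.group_size}"
        )
    wb = b1 - b0 + 1
    ref_flat = (ri - a0) * wb + (rj - b0)
    order = np.argsort(d, kind="stable")
    order = order[order != ref_flat][: params.group_size - 1]
    rows = np.concatenate(([ri], a0 + order // wb))
    cols = np.concatenate(([rj], b0 + order % wb))
    return rows, cols


def find_similar_blocks(image, ref: Tuple[int, int], params: NLSParams) -> BlockGroup:
    """Group the reference block at ``ref`` with its nearest neighbours."""
    arr = image.pixels if isinstance(image, Image) else np.asarray(image, dtype=np.float64)
    n = params.block_size
    h, w = arr.shape
    ri, rj = ref
    if not (0 <= ri <= h - n and 0 <= rj <= w - n):
        raise ValueError("reference block does not fit inside the image")
    view = sliding_window_view(arr, (n, n))
    rows, cols = _match_one(view, ref, arr.shape, params)
    stack = np.moveaxis(view[rows, cols], 0, -1).copy()  # (n, n, m)
    return BlockGroup(
        reference_index=(ri, rj),
        member_indices=list(zip(rows.tolist(), cols.tolist())),
        stack=stack,
    )


# -- orthonormal separable 3D transforms -----------------------------------

def _haar_matrix(m: int) -> np.ndarray:
    """Orthonormal Haar matrix of size m (m must be a power of two)."""
    if m & (m - 1):
        raise ValueError("haar similarity transform needs a power-of-two group size")
    H = np.array([[1.0]])
    while H.shape[0] < m:
        k = H.shape[0]
        top = np.kron(H, [1.0, 1.0])
        bot = np.kron(np.eye(k), [1.0, -1.0])
        H = np.vstack([top, bot]) / np.sqrt(2.0)
    return H


def _forward_batch(stacks: np.ndarray, params: NLSParams) -> np.ndarray:
    """Transform a batch of groups, shape ``(G, m, n, n)``."""
    if params.transform == "dct3d":
        return dctn(stacks, type=2, norm="ortho", axes=(1, 2, 3))
    coeffs = dctn(stacks, type=2, norm="ortho", axes=(2, 3))
    H = _haar_matrix(stacks.shape[1])
    return np.einsum("ij,gjkl->gikl", H, coeffs)


def _inverse_batch(coeffs: np.ndarray, params: NLSParams) -> np.ndarray:
    if params.transform == "dct3d":
        return idctn(coeffs, type=2, norm="ortho", axes=(1, 2, 3))
    stacks = np.einsum("ji,gjkl->gikl", _haar_matrix(coeffs.shape[1]), coeffs)
    return idctn(stacks, type=2, norm="ortho", axes=(2, 3))


def group_transform(group: BlockGroup, params: NLSParams) -> CoefficientStack:
    """Orthonormal separable 3D transform of one group's stack."""
    batch = np.moveaxis(group.stack, -1, 0)[None]  # (1, m, n, n)
    coeffs = np.moveaxis(_forward_batch(batch, params)[0], 0, -1)
    return CoefficientStack(coefficients=coeffs, transform=params.transform)


def group_inverse(coeffs: CoefficientStack, params: NLSParams) -> np.ndarray:
    """Inverse of :func:`group_transform`; returns an ``(n, n, m)`` stack."""
    batch = np.moveaxis(coeffs.coefficients, -1, 0)[None]
    return np.moveaxis(_inverse_batch(batch, params)[0], 0, -1)


# -- batched matching over the whole reference grid -------------------------

def _match_grid(arr: np.ndarray, params: NLSParams):
    """Match every reference block; returns ``(rows, cols)`` of shape (G, m)."""
    n = params.block_size
    view = sliding_window_view(arr, (n, n))
    refs = reference_grid(arr.shape, params)
    rows = np.empty((len(refs), params.group_size), dtype=np.intp)
    cols = np.empty_like(rows)
    for g, ref in enumerate(refs):
        rows[g], cols[g] = _match_one(view, (int(ref[0]), int(ref[1])), arr.shape, params)
    return rows, cols


def _gather(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray, n: int) -> np.ndarray:
    view = sliding_window_view(arr, (n, n))
    return view[rows, cols]  # (G, m, n, n)


def nls_norm(image, params: NLSParams = NLSParams()) -> float:
    """Sum over reference blocks of the l1 norm of group coefficients."""
    arr = image.pixels if isinstance(image, Image) else np.asarray(image, dtype=np.float64)
    rows, cols = _match_grid(arr, params)
    stacks = _gather(arr, rows, cols, params.block_size)
    return float(np.abs(_forward_batch(stacks, params)).sum())


def aggregate(
    groups: Sequence[BlockGroup], shape, fill: np.ndarray | None = None
) -> np.ndarray:
    """Scatter group blocks back and average overlaps (uniform weights).

    Pixels covered by no block take their value from ``fill`` (or 0 if no
    fill image is given).
    """
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for g in groups:
        n = g.stack.shape[0]
        for k, (r, c) in enumerate(g.member_indices):
            acc[r : r + n, c : c + n] += g.stack[:, :, k]
            cnt[r : r + n, c : c + n] += 1.0
    covered = cnt > 0
    out = np.where(covered, acc / np.where(covered, cnt, 1.0), 0.0)
    if fill is not None:
        out = np.where(covered, out, fill)
    return out


def _scatter_average(
    blocks: np.ndarray, rows: np.ndarray, cols: np.ndarray, shape, fill: np.ndarray
) -> np.ndarray:
    """Vectorized uniform-weight aggregation for the batched path."""
    h, w = shape
    n = blocks.shape[-1]
    base = rows * w + cols  # (G, m)
    offs = (np.arange(n)[:, None] * w + np.arange(n)).ravel()  # (n*n,)
    lin = (base[..., None] + offs).ravel()
    vals = blocks.reshape(-1, n * n).ravel()
    acc = np.bincount(lin, weights=vals, minlength=h * w)
    cnt = np.bincount(lin, minlength=h * w)
    covered = cnt > 0
    out = np.where(covered, acc / np.where(covered, cnt, 1), fill.ravel())
    return out.reshape(shape)


def solve_x_subproblem(
    u: np.ndarray,
    phi: np.ndarray,
    lambda_nls: float,
    rho_nls: float,
    params: NLSParams = NLSParams(),
    shape=None,
    matching=None,
    return_matching: bool = False,
):
    """Approximate proximal step for the nonlocal regularizer.

    Operates on ``r = u - phi/rho_nls``; returns ``x`` with the same layout
    as ``u`` (flattened if ``u`` was given flattened, in which case ``shape``
    must supply the 2D geometry).  ``matching`` may supply a precomputed
    ``(rows, cols)`` group membership to reuse (the solver freezes matching
    once the iterate has stabilized); by default groups are rematched on the
    current ``r``.  With ``return_matching=True`` the membership used is
    returned alongside ``x``.
    """
    if rho_nls <= 0:
        raise ValueError("rho_nls must be > 0")
    if lambda_nls < 0:
        raise ValueError("lambda_nls must be >= 0")
    u = np.asarray(u, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    flat_in = u.ndim == 1
    if flat_in:
        if shape is None:
            raise ValueError("shape is required for flattened input")
        r = (u - phi / rho_nls).reshape(shape)
    else:
        r = u - phi.reshape(u.shape) / rho_nls
        shape = r.shape

    n, m = params.block_size, params.group_size
    K = n * n * m
    N = shape[0] * shape[1]
    thr = params.threshold_scale * K * lambda_nls / (N * rho_nls)

    rows, cols = _match_grid(r, params) if matching is None else matching
    stacks = _gather(r, rows, cols, n)
    coeffs = _forward_batch(stacks, params)
    if thr > 0:
        coeffs = np.sign(coeffs) * np.maximum(np.abs(coeffs) - thr, 0.0)
    blocks = _inverse_batch(coeffs, params)
    x = _scatter_average(blocks, rows, cols, shape, fill=r)
    x = x.ravel() if flat_in else x
    if return_matching:
        return x, (rows, cols)
    return x
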