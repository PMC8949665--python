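"""Augmented-Lagrangian / alternating-direction reconstruction solver.

The reconstruction model is

    min_u  1/2 ||A u - f||_2^2 + tau * TV(u) + lambda_nls * NLS(u)

split with auxiliary variables ``w = D u`` (gradient) and ``x = u`` (image
copy for the nonlocal step), giving the augmented Lagrangian

    L_A = 1/2||Au - f||^2 + tau||w||_1 + lambda||theta(x)||_1
          - gamma^T (Du - w) - phi^T (u - x)
          + rho_tv/2 ||Du - w||^2 + rho_nls/2 ||u - x||^2.

Each outer iteration performs inner sweeps w -> u -> x (each a closed-form
or linear-system solve) followed by the multiplier updates

    gamma <- gamma - rho_tv (Du - w),    phi <- phi - rho_nls (u - x).

Weight selection
----------------
At a fixed point with ``A = I`` and unit penalties, the converged image
equals the proximal shrinkage of ``f`` at the *per-iteration* thresholds:
``tau`` for the gradient and ``c*K*lambda/(N*rho)`` for group coefficients.
Useful denoising therefore requires those thresholds to be commensurate with
the noise level.  The ``"auto"`` weights set ``tau = C_TV_AUTO * sigma_hat``
and choose ``lambda_nls`` so the group-coefficient threshold equals
``C_NLS_AUTO * sigma_hat``, with ``sigma_hat`` the supplied or MAD-estimated
noise standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Union

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from . import nls as _nls
from . import tv as _tv
from .image import Image
from .metrics import psnr
from .noise import NoiseSpec, apply_noise
from .sensing import SensingOperator, identity_operator
from .wavelet import estimate_sigma_mad

__all__ = [
    "SolverConfig",
    "SolverState",
    "solve_u_subproblem",
    "update_multipliers",
    "augmented_lagrangian_value",
    "reconstruct",
    "denoise_image",
    "run_ablation",
]

# Calibrated effective-threshold coefficients for the "auto" weights
# (grid search on held-out phantom seeds; see docs/methods.md).
C_TV_AUTO = 0.05
C_NLS_AUTO = 1.25


@dataclass
class SolverConfig:
    """Weights, penalties, and iteration controls for :func:`reconstruct`.

    ``tau`` (TV weight) and ``lambda_nls`` (nonlocal weight) may be numbers
    or ``"auto"``; ``sigma`` is the noise standard deviation used by the
    auto rule (``None`` means estimate it by the wavelet MAD rule).
    """

    tau: Union[float, str] = "auto"
    lambda_nls: Union[float, str] = "auto"
    rho_tv: float = 1.0
    rho_nls: float = 1.0
    nls: _nls.NLSParams = field(default_factory=_nls.NLSParams)
    max_outer: int = 40
    max_inner: int = 1
    tol_rel_change: float = 1e-4
    tol_residual: float = 1e-3
    u_solver: str = "auto"  # auto | spectral | conjugate_gradient
    enable_tv: bool = True
    enable_nls: bool = True
    #: rematch blocks on the current iterate for this many outer iterations,
    #: then freeze the grouping so the splitting scheme can converge
    freeze_matching_after: int = 10
    sigma: Optional[float] = None
    cg_maxiter: int = 500
    record_objective: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_tv", "rho_nls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tol_rel_change", "tol_residual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.u_solver not in ("auto", "spectral", "conjugate_gradient"):
            raise ValueError(f"unknown u_solver {self.u_solver!r}")
        for name in ("tau", "lambda_nls"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a number or 'auto'")
            elif v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SolverState:
    """Iterates, multipliers, and per-iteration history of one run."""

    u: np.ndarray
    w: _tv.GradientField
    x: np.ndarray
    gamma: _tv.GradientField
    phi: np.ndarray
    shape: tuple
    outer_iter: int = 0
    inner_iter: int = 0
    tau: float = 0.0
    lambda_nls: float = 0.0
    sigma_hat: float = 0.0
    converged: bool = False
    matching: Optional[tuple] = None
    history: List[dict] = field(default_factory=list)


def _resolve_weights(config: SolverConfig, f, A, shape):
    """Materialize 'auto' weights from the (estimated) noise level."""
    sigma_hat = config.sigma
    if sigma_hat is None:
        back = A.adjoint(np.asarray(f, dtype=np.float64).ravel()).reshape(shape)
        sigma_hat = estimate_sigma_mad(back)
    tau = C_TV_AUTO * sigma_hat if config.tau == "auto" else float(config.tau)
    if config.lambda_nls == "auto":
        p = config.nls
        K = p.block_size * p.block_size * p.group_size
        N = shape[0] * shape[1]
        # chosen so the group-coefficient threshold c*K*lambda/(N*rho) equals
        # C_NLS_AUTO * sigma_hat
        lam = C_NLS_AUTO * sigma_hat * N * config.rho_nls / (p.threshold_scale * K)
    else:
        lam = float(config.lambda_nls)
    return tau, lam, float(sigma_hat)


def solve_u_subproblem(
    f: np.ndarray,
    A: SensingOperator,
    w: Optional[_tv.GradientField],
    gamma: Optional[_tv.GradientField],
    x: Optional[np.ndarray],
    phi: Optional[np.ndarray],
    config: SolverConfig,
    shape,
    u0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact quadratic u-update.

    Solves the normal equations of the u-subproblem,

        (A^T A + rho_tv D^T D + rho_nls I) u
            = A^T f + D^T (rho_tv w + gamma) + rho_nls x + phi,

    with TV/NLS terms present only when the corresponding splitting is
    active (``w``/``x`` not None).  Uses the closed-form Fourier solve when
    ``A^T A = I``, otherwise conjugate gradients.
    """
    f = np.asarray(f, dtype=np.float64).ravel()
    n_pix = shape[0] * shape[1]
    tv_on = w is not None
    nls_on = x is not None

    rhs = A.adjoint(f)
    if tv_on:
        rhs = rhs + _tv.gradient_adjoint(config.rho_tv * w + gamma).ravel()
    if nls_on:
        rhs = rhs + config.rho_nls * np.asarray(x).ravel() + np.asarray(phi).ravel()

    method = config.u_solver
    if method == "auto":
        method = "spectral" if A.gram_is_identity else "conjugate_gradient"
    if method == "spectral" and not A.gram_is_identity:
        raise ValueError("spectral u-update requires A^T A = I")

    if method == "spectral":
        scalar = 1.0 + (config.rho_nls if nls_on else 0.0)
        if not tv_on:  # diagonal system: exact scalar division, no FFT
            return rhs / scalar
        denom = scalar + config.rho_tv * _tv.dtd_eigenvalues(shape)
        return np.fft.ifft2(np.fft.fft2(rhs.reshape(shape)) / denom).real.ravel()

    def matvec(v):
        out = A.adjoint(A.apply(v))
        if tv_on:
            out = out + config.rho_tv * _tv.gradient_adjoint(
                _tv.gradient(v.reshape(shape))
            ).ravel()
        if nls_on:
            out = out + config.rho_nls * v
        return out

    op = LinearOperator((n_pix, n_pix), matvec=matvec, dtype=np.float64)
    u, info = cg(op, rhs, x0=u0, rtol=1e-12, atol=0.0, maxiter=config.cg_maxiter)
    res = np.linalg.norm(matvec(u) - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if info != 0 and res > 1e-8:
        raise RuntimeError(
            f"conjugate gradients did not converge (relative residual {res:.2e})"
        )
    return u


def update_multipliers(state: SolverState, config: SolverConfig) -> SolverState:
    """Steepest-ascent multiplier step on both constraints (in place)."""
    if state.w is not None:
        Du = _tv.gradient(state.u.reshape(state.shape))
        state.gamma = state.gamma - config.rho_tv * (Du - state.w)
    if state.x is not None:
        state.phi = state.phi - config.rho_nls * (state.u - state.x)
    return state


def augmented_lagrangian_value(
    state: SolverState, f: np.ndarray, A: SensingOperator, config: SolverConfig
) -> float:
    """Diagnostic evaluation of the augmented Lagrangian at the state."""
    f = np.asarray(f, dtype=np.float64).ravel()
    u2d = state.u.reshape(state.shape)
    val = 0.5 * float(np.sum((A.apply(state.u) - f) ** 2))
    if state.w is not None:
        Du = _tv.gradient(u2d)
        resid = Du - state.w
        val += state.tau * state.w.l1()
        val -= state.gamma.dot(resid)
        val += 0.5 * config.rho_tv * resid.norm() ** 2
    if state.x is not None:
        r = state.u - state.x
        val += state.lambda_nls * _nls.nls_norm(state.x.reshape(state.shape), config.nls)
        val -= float(np.dot(state.phi, r))
        val += 0.5 * config.rho_nls * float(np.dot(r, r))
    return val


def _inner_sweep(state: SolverState, f, A, config: SolverConfig) -> SolverState:
    """One w -> u -> x sweep with multipliers held fixed (in place)."""
    if state.w is not None:
        Du = _tv.gradient(state.u.reshape(state.shape))
        state.w = _tv.solve_w_subproblem(Du, state.gamma, config.rho_tv, state.tau)
    state.u = solve_u_subproblem(
        f, A, state.w, state.gamma, state.x, state.phi, config, state.shape, u0=state.u
    )
    if state.x is not None:
        reuse = (
            state.matching
            if state.outer_iter >= config.freeze_matching_after
            else None
        )
        state.x, state.matching = _nls.solve_x_subproblem(
            state.u,
            state.phi,
            state.lambda_nls,
            config.rho_nls,
            config.nls,
            state.shape,
            matching=reuse,
            return_matching=True,
        )
    return state


def reconstruct(
    f: np.ndarray,
    A: SensingOperator,
    shape,
    config: SolverConfig = SolverConfig(),
    ground_truth: Optional[Image] = None,
) -> tuple[Image, SolverState]:
    """Run the full alternating-direction reconstruction.

    Parameters
    ----------
    f:
        Measurement vector (``A = identity``: the noisy image, flattened).
    A:
        Sensing operator with ``n_cols == shape[0]*shape[1]``.
    shape:
        2D image geometry of the unknown.
    ground_truth:
        Optional clean image; when given, per-iteration PSNR is recorded.

    Returns the reconstructed :class:`Image` (unclipped reals) and the final
    :class:`SolverState` with its per-iteration history.
    """
    f = np.asarray(f, dtype=np.float64).ravel()
    n_pix = shape[0] * shape[1]
    if A.n_cols != n_pix:
        raise ValueError("operator size does not match image shape")
    tau, lam, sigma_hat = _resolve_weights(config, f, A, shape)
    # a zero-weight regularizer is dropped from the splitting entirely: the
    # ADMM limit coincides and the no-regularization path stays exact
    tv_on = config.enable_tv and tau > 0
    nls_on = config.enable_nls and lam > 0

    u = f.copy() if A.kind == "identity" else A.adjoint(f)
    state = SolverState(
        u=u,
        w=_tv.GradientField.zeros(shape) if tv_on else None,
        x=np.zeros(n_pix) if nls_on else None,
        gamma=_tv.GradientField.zeros(shape) if tv_on else None,
        phi=np.zeros(n_pix) if nls_on else None,
        shape=tuple(shape),
        tau=tau,
        lambda_nls=lam,
        sigma_hat=sigma_hat,
    )

    gt = ground_truth.pixels.ravel() if ground_truth is not None else None
    peak_bits = ground_truth.bit_depth if ground_truth is not None else 8
    sqrt_n = math.sqrt(n_pix)

    for k in range(config.max_outer):
        u_prev = state.u
        for _ in range(config.max_inner):
            state = _inner_sweep(state, f, A, config)
            state.inner_iter += 1
        state = update_multipliers(state, config)
        state.outer_iter = k + 1

        if not np.all(np.isfinite(state.u)):
            raise RuntimeError("u-update produced non-finite values")

        r_tv = (
            ( _tv.gradient(state.u.reshape(shape)) - state.w).norm() if tv_on else 0.0
        )
        r_nls = float(np.linalg.norm(state.u - state.x)) if nls_on else 0.0
        rel = float(
            np.linalg.norm(state.u - u_prev) / max(np.linalg.norm(u_prev), 1e-300)
        )
        rec = {
            "outer_iter": state.outer_iter,
            "rel_change": rel,
            "residual_tv": r_tv,
            "residual_nls": r_nls,
        }
        if config.record_objective:
            rec["objective"] = augmented_lagrangian_value(state, f, A, config)
        if gt is not None:
            rec["psnr_db"] = psnr(
                Image(gt.reshape(shape), peak_bits),
                Image(state.u.reshape(shape), peak_bits),
            )
        state.history.append(rec)

        if (
            rel <= config.tol_rel_change
            and r_tv <= config.tol_residual * sqrt_n
            and r_nls <= config.tol_residual * sqrt_n
        ):
            state.converged = True
            break
        if not (tv_on or nls_on):
            # pure least squares: the first u-update is already exact
            state.converged = True
            break

    return Image(state.u.reshape(shape), bit_depth=peak_bits), state


def denoise_image(
    image: Image, config: SolverConfig = SolverConfig(), ground_truth: Optional[Image] = None
) -> tuple[Image, List[SolverState]]:
    """Denoise a (possibly 3-channel) image with ``A = identity``.

    Channels are processed independently with shared parameters.
    """
    shape = (image.height, image.width)
    A = identity_operator(image.n_pixels)
    outs, states = [], []
    gt_channels = list(ground_truth.channels()) if ground_truth is not None else None
    for idx, ch in enumerate(image.channels()):
        gt = (
            Image(gt_channels[idx], ground_truth.bit_depth)
            if gt_channels is not None
            else None
        )
        out, st = reconstruct(ch.ravel(), A, shape, config, ground_truth=gt)
        outs.append(out.pixels)
        states.append(st)
    pixels = outs[0] if image.n_channels == 1 else np.stack(outs, axis=-1)
    return Image(pixels, image.bit_depth), states


ABLATION_VARIANTS = [
    ("cs", False, False),
    ("cs_tv", True, False),
    ("cs_nls", False, True),
    ("cs_tv_nls", True, True),
]


def run_ablation(
    image: Image,
    noise: NoiseSpec,
    config: SolverConfig,
    seeds,
    A: Optional[SensingOperator] = None,
) -> List[dict]:
    """Rerun the solver with each regularizer switched on/off.

    For every seed, the same noisy realization feeds all four variants
    (no regularization, TV only, NLS only, both).  Returns one row per
    (variant, seed) with PSNR and SSIM against the clean image.
    """
    from .metrics import ssim  # local import to avoid cycle at module load

    if A is None:
        A = identity_operator(image.n_pixels)
    shape = (image.height, image.width)
    rows = []
    for seed in seeds:
        noisy = apply_noise(image, replace(noise, seed=int(seed)))
        f = A.apply(noisy.pixels.ravel())
        for name, use_tv, use_nls in ABLATION_VARIANTS:
            cfg = replace(config, enable_tv=use_tv, enable_nls=use_nls)
            out, _ = reconstruct(f, A, shape, cfg, ground_truth=image)
            rows.append(
                {
                    "variant": name,
                    "seed": int(seed),
                    "psnr_db": psnr(image, out),
                    "ssim": ssim(image, out),
                }
            )
    return rows
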