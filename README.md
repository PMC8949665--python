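# tvnls

Compressed-sensing image reconstruction and denoising that combines **total
variation (TV)** and **nonlocal self-similarity (NLS)** regularization,
solved with an augmented-Lagrangian / alternating-direction scheme.

## The problem

Recovering an image `u` from noisy or compressed measurements
`f = A u + ε` is ill-posed: the data alone do not determine a good
solution. TV regularization (the l1 norm of the discrete gradient,
`TV(u) = ‖Du‖₁`) preserves edges and flat regions but smooths away
texture. Nonlocal self-similarity exploits the fact that natural images
contain many mutually similar patches: similar n×n blocks are stacked into
3D groups, and the l1 norm of their joint orthonormal 3D-transform
coefficients, `NLS(u) = Σᵢ ‖T₃D(Z_uᵢ)‖₁`, is sparse for repetitive
structure. The reconstruction model minimizes

    ½‖Au − f‖₂² + τ·TV(u) + λ·NLS(u)

Splitting variables `w = Du` and `x = u` give the augmented Lagrangian

    L_A = ½‖Au−f‖² + τ‖w‖₁ + λ‖θx‖₁ − γᵀ(Du−w) − φᵀ(u−x)
          + ρ_tv/2·‖Du−w‖² + ρ_nls/2·‖u−x‖²

which is minimized by alternating three closed-form (or linear-system)
subproblems — soft-thresholding for `w`, a Fourier-diagonal or
conjugate-gradient normal-equation solve for `u`, and group-wise transform
shrinkage plus overlap averaging for `x` — followed by gradient-ascent
multiplier updates. The same solver handles pure denoising (`A = I`,
Gaussian or salt-and-pepper noise) and compressed-sensing recovery
(`A` a randomly signed, row-subsampled orthonormal DCT).

The package also provides a synthetic phantom generator (piecewise-constant
shapes + exactly periodic texture), both noise simulators, a classical
wavelet-shrinkage baseline with the universal threshold `σ√(2 ln N)`, and
PSNR/SSIM quality metrics. See `docs/methods.md` for model details and
parameter choices.

## Worked example

```sh
tvnls phantom --height 128 --width 128 --seed 0 --out p
tvnls simulate-noise p/phantom.png --kind awgn --sigma 20 --seed 0 --out n
tvnls evaluate p/ground_truth.png n/noisy.png
tvnls denoise n/noisy.png --reference p/ground_truth.png --out d
tvnls denoise n/noisy.png --method wavelet --reference p/ground_truth.png --out dw
```

prints (noisy input, combined TV+NLS reconstruction, wavelet baseline):

```
{"mse": 389.39, "psnr_db": 22.23, "ssim": 0.438, ...}
{"mse": 43.81, "psnr_db": 31.72, "ssim": 0.886}
{"mse": 307.73, "psnr_db": 23.25, "ssim": 0.635}
```

The noisy σ=20 input sits at 22.2 dB PSNR. The combined reconstruction
reaches 31.7 dB (+9.5 dB) with SSIM 0.886 — removing the noise while
keeping both the sharp shape edges (TV) and the periodic texture (NLS) —
whereas universal-threshold wavelet shrinkage only reaches 23.2 dB because
it oversmooths the texture. `d/run_log.jsonl` holds the per-iteration
residuals and PSNR; `d/run_config.yaml` records every resolved parameter
so the run can be reproduced bit-exactly.

The same calls are available as library functions:

```python
from tvnls import make_phantom, add_awgn, denoise_image, SolverConfig, psnr

clean = make_phantom(128, 128, seed=0)
noisy = add_awgn(clean, sigma=20, seed=0)
recon, states = denoise_image(noisy, SolverConfig(), ground_truth=clean)
print(psnr(clean, recon))
```

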