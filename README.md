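# microdeblur

Blind deconvolution for light-microscopy images with
**bi-l0-l2 gradient regularization**.

Transmitted-light micrographs are blurred by the system point-spread
function (PSF) and carry additive background noise:

    g = psf ** f + N

Deconvolution sharpens, but with an *unknown* PSF and real noise it
usually amplifies that noise or leaves staircase artifacts. This
package implements a blind deconvolution loop aimed at microscopists
and image-analysis developers who want to recover resolution from a
single 2-D image without characterizing the optics first:

* **PSF estimation** — conjugate gradients on the least-squares problem
  `min_k ||lap(f) ** k − lap(g)||²` over a small odd kernel support
  (Laplacian filtering concentrates the fit on edges).
* **Image restoration** — minimize, over a box Q of admissible
  intensities,

      (L²/2)·||k ** f − g||² + α( β_f·||∇f||₀ + λ_f β_f·||∇f||₂² )

  with α=500, β_f=0.25, λ_f=5 and L=255 the 8-bit dynamic range.
  The l0 gradient count prunes noise gradients while keeping true
  edges sharp; the l2 term tames high-frequency amplification. The
  energy is solved by half-quadratic splitting with a closed-form
  hard-threshold step and a gradient-projection Barzilai–Borwein (GPBB)
  inner solver.
* **Blind alternation** — the two solvers are alternated per color
  channel from `f₀ = g` until the relative change of the image iterate
  falls below 1e-6 (hard cap 40 iterations).
* **Evaluation** — RMSE, PSNR, SSIM, edge-preservation index (EPI,
  Laplacian correlation), line profiles, and the radially averaged
  normalized noise power spectrum (NNPS) in line pairs per micrometre.
* **Simulation** — a Siemens-star resolution chart generator plus the
  forward degradation model, so the whole pipeline is testable without
  any measured data.

See `docs/methods.md` for the model, the solver schedules, and the
design decisions.

## Worked example

Simulate a degraded star chart and deconvolve it blind (a small frame
so it runs in seconds):

```python
import numpy as np
from microdeblur import (
    StarPhantomSpec, DegradationSpec, generate_star_phantom,
    gaussian_psf, degrade, blind_deconvolve, BlindDeconvConfig,
    CGConfig, fit_gaussian_sigma, rmse, ssim, epi,
)

spec = StarPhantomSpec(image_size=256, n_spoke_pairs=18)
reference = generate_star_phantom(spec)
psf = gaussian_psf(15, 1.5)                       # true blur: sigma 1.5 px
degraded = degrade(reference, DegradationSpec(psf=psf, noise_variance=0.01, rng_seed=5))

result = blind_deconvolve(degraded, BlindDeconvConfig(
    max_outer_iterations=12, cg=CGConfig(kernel_size=15)))
restored = result.restored[0]

print(f"degraded : RMSE {rmse(degraded, reference):.3f}  "
      f"SSIM {ssim(degraded, reference):.3f}  EPI {epi(degraded, reference):.3f}")
print(f"restored : RMSE {rmse(restored, reference):.3f}  "
      f"SSIM {ssim(restored, reference):.3f}  EPI {epi(restored, reference):.3f}")
print(f"estimated kernel sigma: {fit_gaussian_sigma(result.kernels[0]):.2f} px")
```

Output:

```
degraded : RMSE 0.158  SSIM 0.352  EPI 0.050
restored : RMSE 0.086  SSIM 0.792  EPI 0.633
estimated kernel sigma: 1.50 px
```

The blind loop recovers the blur width from the degraded image alone
(1.50 px against the true 1.5 px), roughly halves the RMSE against the
clean chart, and more than doubles SSIM — with the background noise
*suppressed*, not amplified (compare the flat-field NNPS of the two
images with `compute_nnps`).

## Command line

```bash
microdeblur simulate --size 2000 --spokes 36 --psf-sigma 1.5 --noise-var 0.01 --seed 0 --out sim/
microdeblur deconvolve --image sim/degraded.tif --out out/
microdeblur evaluate --test out/restored.tif --ref sim/reference.tif
microdeblur reproduce-simulation            # the full simulation study
```

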