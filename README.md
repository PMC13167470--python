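# chansplit

Semantic unmixing of superimposed fluorescence micrographs: a hierarchical
variational splitting encoder–decoder predicts `k` denoised structure channels
from a single mixed image. The package includes

- **phantoms** — synthetic multi-structure micrographs (filaments, blobs,
  puncta, rings) with controllable mixing skew, Poisson–Gaussian noise and
  scaled-copy similarity tasks, assembled into training pairs under four
  acquisition modes (I: co-located sums, II: cross-sample sums, IIb: pure-region
  sums, III: separately acquired superimposed input);
- **noise_model** — pixel-wise observation likelihoods p(noisy | clean):
  Gaussian, analytic Poisson–Gaussian, and a fittable signal-dependent
  Gaussian mixture;
- **lc_patching** — lateral-context pyramids: progressively larger patches
  centred on the primary input, downscaled to identical pixel dimensions;
- **vse / losses / training** — the model (lean/deep LC variants, 2D and 3D),
  the combined denoising + reconstruction objective with centre-cropped
  per-level KL (z-averaged for volumetric latents), and an
  Adamax + reduce-on-plateau training loop — all on a small NumPy autodiff
  engine (`chansplit.nn`), no GPU required;
- **inference** — posterior sampling, MMSE and pixel-wise uncertainty
  estimates, inner-tiled full-frame prediction (64/32 tiles, 50 samples by
  default);
- **evaluation** — range-invariant PSNR and multi-scale SSIM, plus the
  RMV-vs-RMSE calibration analysis.

## CLI

```bash
chansplit generate --kind filaments --size 256 --out phantom.tif
chansplit fit-noise reference.tif noisy.tif --out noise_model.json
chansplit run --preset tiny-2ch --out runs/tiny      # full pipeline
chansplit predict checkpoint.npz input.tif --samples 50 --tile 64 --center 32
chansplit evaluate pred.tif ref.tif
chansplit calibrate rmse.tif mmse.tif ref.tif
```

`chansplit run` executes generate → train → predict → evaluate → calibrate and
writes a manifest with file hashes, metrics and the calibration summary.
Experiment configs are YAML validated against a pydantic schema (see
`chansplit.config.ExperimentConfig`).

## Conventions

Arrays are `(C, [Z,] Y, X)`, float32, photon-count scale; images are
TIFF/OME-style with an explicit axes tag. All randomness flows from explicit
seeds; a global seed fans out to per-module seeds via `config.module_seed`.
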