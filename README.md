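# ctpm — CT perfusion mapping for functional lung avoidance radiotherapy

`ctpm` translates 3D anatomic lung CT volumes into pulmonary perfusion maps.
Pulmonary perfusion (regional blood flow, clinically imaged with
⁹⁹ᵐTc-MAA SPECT) guides functional lung avoidance radiotherapy (FLART), but
SPECT is slow, resource-demanding and involves injected radiotracer.  Many
pulmonary diseases alter parenchymal CT texture in ways that carry functional
information, so a convolutional network can learn a voxelwise CT → perfusion
mapping from paired SPECT/CT scans.

The package implements the whole framework end to end:

* **phantom** — digital lung phantoms: paired CT/perfusion cohorts with
  ellipsoidal lungs, a carved-out trachea, gravity-gradient perfusion with
  SPECT-like count speckle, and low-functional defects of two archetypes
  (sharp step and 10-mm linear ramp) whose CT texture is informatively
  coupled to the perfusion deficit.  All tests and examples run on phantoms;
  clinical SPECT/CT cohorts are not redistributable.
* **prep** — isotropic resampling, parenchyma-mask application, left/right
  lung separation (84 single-lung samples from 42 subjects), tight crop and
  resize to the 128×64×64 network grid, and the inverse mapping back to the
  original grid.
* **processing** — SPECT normalization by the high-intensity-region value
  (HIR, the 75th-percentile in-mask count) and discretization into 11 uniform
  levels on [0, 1]; CT enhancement by cumulative-histogram equalization in
  the [−1000, −300] HU window followed by a 10-voxel median and a 5-voxel
  mean filter (mask-aware).  Every step is independently toggleable.
* **model** — a configurable 3D encoder-decoder CNN: three 2×2×2 stride-2
  convolutions, 5×5×5 convolutions with batch norm + PReLU + spatial dropout,
  eight residual blocks at the 128-channel bottleneck (width 4×32), additive
  attention gates on the two highest-resolution skips, a multiplicative ROI
  gate on first-layer features, and a sigmoid output in [0, 1].  Built on a
  compact NumPy reverse-mode autodiff core (`ctpm.nn`).
* **training** — Kaiming-uniform init, Adam, masked binary cross-entropy on
  the [0, 1] labels, 500-epoch cap with the 0.2%-for-5-epochs early stop,
  single-seed bit-reproducibility.
* **evaluation** — masked Spearman correlation R, volumetric SSIM
  (k₁ = 0.01, k₂ = 0.03, L = 1), the SSIM+R composite with percent difference
  vs. a baseline, and low/high functional-region Dice at the 0.66 threshold
  on the recovered original grid.
* **experiments** — a declarative ablation harness with the built-in
  image-processing suite (5 rows) and architecture grid (12 rows), emitting
  CSV/Markdown comparison tables; every row regenerable from its manifest.

## Worked example

```python
from ctpm.experiments import small_run_config, run_pipeline

cfg = small_run_config(n_subjects=6, seed=0, epochs=12)   # 32x16x16 lungs
res = run_pipeline(cfg)
print(res["n_train"], res["n_test"])
print({k: round(v["mean"], 3) for k, v in res["summary"].items()})
```

prints (8 training and 4 held-out single-lung samples):

```
8 4
{'R': 0.792, 'SSIM': 0.769, 'SSIM_plus_R': 1.562, 'DSC_high': 0.871, 'DSC_low': 0.307}
```

i.e. on held-out phantom lungs the reduced network reaches voxelwise rank
correlation R ≈ 0.79 and SSIM ≈ 0.77 against the processed perfusion label,
and Dice ≈ 0.87 for the high-functional region on the recovered grid.  The
low-functional Dice is small and variable on this tiny cohort because
several held-out lungs have little or no defect.

The same run with CT contrast enhancement disabled
(`cfg.processing.contrast_enhance = False`) drops SSIM+R from 1.562 to
1.324 (−15%), reproducing the dominant ablation effect: low-functional
tissue occupies a narrow dark HU band that the equalization spreads out.

From the shell:

```bash
ctpm phantom --out cohort/ --n-subjects 8 --seed 0
ctpm train --out run/ --seed 0
ctpm ablate --suite table2 --out ablation/ --n-subjects 8 --epochs 30
```

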