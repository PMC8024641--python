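# Methods

## The mapping problem

The package learns a voxelwise translation from anatomic lung CT to a
relative pulmonary perfusion map.  Ground truth during training is a
processed SPECT perfusion volume; the network output is a value in [0, 1]
per voxel, interpreted as perfusion relative to normally functional tissue.
The pipeline is: image preparation → image processing → CNN training →
evaluation, with every processing and architecture component removable for
ablation studies.

## Image preparation (`ctpm.prep`)

Volumes are resampled to 1 mm isotropic spacing (trilinear for continuous
volumes, nearest-neighbour for label volumes; output shape =
`round(shape * spacing / target)` per axis, so physical extent is preserved
to within one voxel).  The parenchyma mask — an input, with trachea and
tumour already excluded — is applied to both CT and perfusion; left and
right lungs are then treated as independent samples, doubling the cohort
(42 subjects → 84 single-lung samples; a 31/11 subject split gives 62/22).

Axis convention: `(z, y, x)` = (superior-inferior, anterior-posterior,
left-right).  Each lung is cropped to the *tight* bounding box of its mask
and anisotropically resized to the network grid, 128×64×64 by default with
the long axis cranio-caudal.  Aspect ratio is deliberately not preserved —
the inverse mapping (`recover_original_grid`) resizes back to the recorded
bounding box and re-embeds at the recorded offsets, zero outside.  On smooth
fields the crop→recover round trip preserves the in-mask mean to within 2%
(tested); masked volumes additionally blend with background zeros at the
pleural boundary, which is inherent to any crop-resize pipeline of this
shape.

For unlabelled binary masks, lungs are split by connected components and
sides assigned by centroid along x (smaller x centroid → left); ties break
toward the larger component = right; residual small components merge into
the nearer lung.

## Image processing (`ctpm.processing`)

**Perfusion label.** In-mask SPECT counts are divided by the HIR — the
75th-percentile in-mask value (linear-interpolation percentile), a proxy for
normally perfused tissue — then clipped to [0, 1] and snapped to the nearest
of 11 uniform levels {0, 0.1, …, 1.0}; midpoint ties round up.
Discretization suppresses count noise at the cost of label granularity.
HIR is computed over in-mask voxels only (background is zeroed upstream);
a config flag (`hir_in_mask_only`) exposes the alternative reading.

**CT enhancement.** In-mask HU values are clipped to the aerated-lung window
[−1000, −300] (outliers take the bound value) and equalized by the empirical
cumulative histogram of in-mask clipped values:
`eq(v) = #{values ≤ v} / N`.  This maps to (0, 1], is monotone in HU, and is
well defined for degenerate (constant) volumes, which map to 1.0.  The
cumulative count *below* the window low bound is zero after clipping, so the
normalizing difference reduces to N.  Equalization is followed by a
10-voxel-edge median filter and a 5-voxel-edge mean filter, in that fixed
order.  The even median kernel uses floor-centred offsets (−5…+4 per axis);
this literal even size is kept and tested rather than silently rounded.

Filters are mask-aware by default: window statistics use in-mask neighbours
only, so the background cannot darken the pleural edge.  A `mask_aware_filters`
flag exposes plain filtering.  The mask-aware rank-order (median) filter is
a numba kernel; no SciPy primitive supports masked medians.

## Network (`ctpm.model`, `ctpm.nn`)

A 4-level 3D encoder-decoder.  Channel schedule at depth d (0-based, L
stride levels): `round(32·(1 + d(w−1)/L))` for width multiplier w — exact
for the optimal configuration (w=4: 32, 64, 96, 128; bottleneck always
32·w).  Encoder: a kernel-k 'same' convolution per level plus a 2×2×2
stride-2 convolution between levels; every convolution is followed by batch
normalization, a PReLU-family activation and channelwise (spatial) 3D
dropout.  Bottleneck: 8 channel-preserving residual blocks
(conv–BN–act–dropout–conv–BN + identity, then act).  Decoder: kernel-2
stride-2 transposed convolutions; skip features are concatenated and fused
by a kernel-k convolution.  Additive attention gates (1×1×1 projections of
skip and gating signal, ReLU, 1×1×1 squeeze, sigmoid coefficient map) sit on
the two highest-resolution skips, where small low-functional structures
survive.  ROI attention multiplies first-layer features by the binary
parenchyma mask — a parameter-free gate, so ablating it changes behaviour
but not the parameter count.  A 1×1×1 convolution plus voxelwise sigmoid
produces the [0, 1] prediction.

Defaults reproduce the optimal configuration: width 4×32, kernel 5,
dropout 0.1, PReLU (learnable per-channel slope, init 0.25), all components
on.  LeakyReLU(0.5) and ReLU are the fixed-slope special cases.  Activations
in decoders and gates reuse the configured family except the gate's internal
ReLU, which follows the standard additive-gating design.

Input shapes must be divisible by 2^L; a configuration error is raised if
the requested kernel edge exceeds the deepest feature-map edge (min axis).

`ctpm.nn` is a compact reverse-mode autodiff over float32 NumPy arrays:
convolution via block-copy im2col + GEMM, non-overlapping transposed
convolution, batch norm with running statistics, sigmoid, spatial dropout,
concatenation and a masked BCE loss.  Determinism comes from seeded
`numpy.random.Generator` streams (init, dropout, shuffling) and single-device
execution.

## Training (`ctpm.training`)

Kaiming-uniform initialization (bound `gain·sqrt(3/fan_in)`, gain matched to
the activation's negative slope; biases uniform ±1/sqrt(fan_in)).  Adam
(lr 1e-3, batch size 2 by default — both config keys; the protocol only
fixes the optimizer family).  Loss: mean binary cross-entropy over in-mask
voxels with soft targets (the 11-level labels are fractional); predictions
are clamped to [1e-7, 1−1e-7] so the loss is always finite.  Epoch cap 500;
training stops early once the last five consecutive relative changes of the
training-epoch mean loss are all below 0.2%.  The rule monitors training
loss (no validation split is defined for it).  The best-loss epoch's weights
are restored at the end.  Non-finite loss aborts with a learning-rate
diagnostic.  At evaluation, batch-norm uses running statistics and dropout
is off.

## Evaluation (`ctpm.evaluation`)

* **R** — the product-moment correlation formula applied to average-ranked
  in-mask values (true Spearman).  The protocol names the metric Spearman
  while printing the Pearson form; the default honours the name, and
  `pearson_raw` applies the formula to raw values.  "Non-zero voxels" is
  read as in-ROI voxels, since masking zeroes the background.  Zero variance
  raises an explicit error rather than returning 0.
* **SSIM** — luminance × contrast/structure terms with C1=(0.01·L)²,
  C2=(0.03·L)², L=1 (labels live in [0, 1]); local statistics over a
  sliding 7³ uniform window (population normalization, reflect boundaries),
  averaged over in-mask window centres.  The windowing is a package choice
  (the protocol leaves it unstated); both the window edge and L are
  configurable.  Cross-checked against scikit-image's implementation in
  tests.
* **SSIM+R** and percent difference `100·(score − baseline)/baseline`
  (ablation below baseline ⇒ negative).
* **DSC** — predictions are first recovered to the original grid; in-mask
  voxels partition into high (> 0.66) and low (≤ 0.66) functional regions,
  Dice computed per region against the *normalized, undiscretized* perfusion.
  If a region is empty on both sides DSC = 1, on one side only DSC = 0.

## Phantoms (`ctpm.phantom`)

The phantom cohort emulates the statistical structure the framework needs,
not anatomy:

* Two axis-aligned ellipsoidal lungs (semi-axes 0.40/0.28/0.17 of the grid
  extent, ±15% jitter), labelled left/right; a trachea-like tube carved out
  of the mask.  The tube's CT value is −300 HU, the floor of the permitted
  background range — a compromise, since real tracheal air (≈ −1000 HU)
  would violate the generator's background contract.
* Perfusion: a gravity-like anterior→posterior gradient (amplitude 0.8)
  with multiplicative log-normal speckle (σ = 0.2), generated on a 4-mm grid
  and trilinearly upsampled — reproducing the SPECT/CT resolution mismatch —
  then scaled to counts.
* Defects: per subject one of {sharp, gradient, none}; an anisotropic
  distance field from a random in-lung centre is thresholded at the exact
  k-th order statistic, so the defect occupies the requested parenchyma
  fraction to within one voxel.  Sharp defects step to a deficit depth drawn
  from U(0.5, 0.85); gradient defects ramp linearly over 10 mm from the
  boundary.
* CT coupling: in-mask HU = −950 + 600·clip(c·q² + (1−c)·t), where q is the
  noise-free perfusion quantile, t an independent smooth texture field and
  c the coupling strength.  The q² compression concentrates low-functional
  tissue in a narrow dark HU band — precisely the condition under which
  cumulative-histogram equalization helps, so the contrast-enhancement
  ablation has a real mechanism to reveal.  At c=0 the CT carries no
  functional information.  `noise_sd` adds multiplicative perfusion noise
  and additive CT noise (100·noise_sd HU).
* Defaults are the emulated study conditions: 42 subjects, CT grids
  160×96×96 at 1.25×0.977×0.977 mm (a reduced-size replica of the clinical
  resolution mismatch), coupling 0.9, noise 0.05, defect mix
  0.4/0.4/0.2 (sharp/gradient/none), defect fraction U(0.10, 0.40).

What phantoms do **not** model: airway trees, lobar fissures, cardiac
structures, tumours, scanner physics, or clinically realistic defect
contrast.  Passing tests therefore demonstrate that the implementation is
correct and that the framework recovers a learnable CT–perfusion coupling —
not clinical-grade accuracy on real scans.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced configurations chosen as the
package's desk-scale defaults: phantom grids 32×24×24–48×32×32 at 1 mm,
network inputs 16×12×12–32×16×16 with 2 stride levels, width 3×32, kernel 3,
2 residual blocks, 2–15 training epochs, cohorts of 3–8 subjects.  The
`--full-scale` path restores 128×64×64 inputs, width 4×32, kernel 5, 8
residual blocks and the 500-epoch cap.  Under the reduced settings the
held-out phantom metrics land near the full framework's working range
(Spearman R ≈ 0.8, SSIM ≈ 0.7), and removing CT contrast enhancement costs
10–20% of SSIM+R for every tested seed.

Numerical conventions worth knowing: discretization ties round up;
equalization of an all-constant volume returns 1.0; correlation requires ≥3
in-mask voxels and nonzero variance; empty-region Dice follows the
conventions above; BCE clamps at 1e-7; all tensors are float32; RNG streams
are keyed as `(seed, purpose, index)` so any subject or run is reproducible
independently of cohort size.

## Known limitations

* The exact layer graph of the original architecture is under-specified in
  places (convolutions per level, transposed-convolution kernels, attention
  gate internals); the choices above are declared approximations and are
  parameterized.
* Bit-reproducibility is best-effort single-device: BLAS reduction order may
  differ across builds, though all tested contracts use margins far above
  float noise.
* The NumPy CNN core is CPU-only and optimized for clarity at desk scale,
  not for full-resolution clinical training throughput.
* DSC ground truth uses per-lung HIR normalization on the original grid,
  which can differ slightly from the network-grid normalization of the
  training label.
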