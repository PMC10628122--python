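# Methods

This note documents the models and procedures implemented in `virtustain`,
the synthetic testbed they are validated on, and the design decisions taken
where the method description leaves choices open.

## Synthetic testbed

Real acridine-orange sperm data consists of brightfield micrographs (BFI)
with green (dsDNA) and red (ssDNA) fluorescence counterparts, acquired per
donor with an unknown projective misalignment between the brightfield and
fluorescence optical paths.  The generator emulates exactly the properties
the pipeline depends on, with exact ground truth for each:

* **Cells** are ellipses (semi-axes 10–14 × 6–9 px, random orientation),
  non-overlapping, placed with a configurable border margin.  Head size
  matches a ~4–5 µm sperm head at ~0.3 µm/px.
* **Texture.**  All three modalities share one band-limited speckle field
  per scene (Gaussian-filtered white noise, σ = 1.4 px, rescaled to
  [0.35, 1]).  The brightfield shows cells as bright textured ellipses on a
  mid-gray (110) background; each fluorescence channel shows the same
  texture scaled by the cell's channel intensity on a dark background.
  Sharing the texture (up to an affine intensity map per channel) is what
  makes cross-modality keypoint descriptors matchable — with constant-fill
  fluorescence ellipses the registration stage would have nothing to match
  and would be untestable.  Because both channels share the same mask and
  texture, the texture factor cancels in the DFI ratio, so the analytic
  per-cell DFI is exact.
* **DFI encoding.**  Per-cell dsDNA and ssDNA intensities satisfy
  `ds + ss = 240` (8-bit scale), so a cell's DFI fixes both.  The
  brightfield in-cell brightness is an affine function of `(ds, ss)`
  (`110 + (0.35·ds + 0.15·ss)·t`); with the fixed intensity total, the
  brightfield appearance determines the fluorescence intensities, i.e., the
  morphology genuinely encodes the molecular signal the GAN must learn.
  Donors differ in mean DFI (uniform in [15, 45]); per-cell DFI is normal
  around the donor mean (SD 12, clipped to [3, 75]), spanning the range
  seen across sperm donors.
* **Background.**  Each fluorescence frame carries an additive integer
  background drawn i.i.d. per pixel from
  `{level − jitter, …, level + jitter}` (defaults: dsDNA level 10, ssDNA
  level 14, jitter 1).  Additivity matters: cells sit on top of the
  background glow, which is the model under which scalar background
  subtraction is exact.
* **Misalignment.**  Ground-truth homographies are similarity transforms
  (translation ±20 px, rotation ±5°, scale 0.95–1.05) mapping
  fluorescence to brightfield coordinates; the noise-free cell render is
  warped bilinearly and background noise is added in the fluorescence
  frame (i.i.d. noise is invariant under resampling, so adding it after
  the warp preserves the stated background distribution exactly).
* **Truth.**  Per-cell DFI is computed from the noise-free, pre-warp float
  renders; patch boxes are squares of 1.2× the major semi-axis around each
  center, recorded half-open in brightfield coordinates.

What the testbed does **not** emulate: real head morphology (acrosome,
vacuoles, midpiece, tails), optical PSF and defocus blur, shot noise,
illumination gradients, occlusion, or any biological link between shape and
fragmentation beyond the constructed intensity encoding.  Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
GAN can learn an intensity mapping that is decodable from brightfield
appearance — not that real sperm DFI is predictable from brightfield
morphology; that question is settled only on real data.

## Registration

Per frame pair: SIFT keypoints and descriptors on 8-bit renderings
(detector at raised sensitivity, DoG threshold 0.006, edge ratio 12 —
micrographs are low-texture relative to natural images); k = 2
nearest-neighbor descriptor matching (KD-tree, fluorescence → brightfield);
Lowe's ratio filter (default 0.75); RANSAC over a projective model
(reprojection threshold 3 px, 5000 trials, seeded).  Three robustness
measures beyond the textbook recipe:

* **One-to-one correspondences.**  Several source keypoints may match one
  destination keypoint; at most one can be right, and duplicated
  destinations let rank-deficient "collapse" homographies accumulate fake
  RANSAC consensus.  Only the best match per destination enters the fit
  (the returned inlier mask still indexes the caller's match list), and
  degenerate candidate models are rejected inside RANSAC.
* **Guided refinement.**  The RANSAC estimate is polished by re-matching
  all detected keypoints geometrically (one-to-one, annealed gates
  2.5 → 1.25 → 0.8 px) and refitting by iteratively reweighted least
  squares with Huber weights (δ = 0.3 px) on subpixel keypoint positions.
* **Model selection.**  The refit is computed for both an affine and a full
  projective model; the projective one is kept only when it clearly reduces
  the residual (by > 30 %).  Two unsupported perspective degrees of freedom
  otherwise amplify keypoint noise into corner-extrapolation error — the
  quantity that decides whether distant patch crops are aligned.

The minimum consensus size defaults to 8 (after deduplication); 4 points
determine a homography, and requiring more than 8 rejects recoverable dim
frames.  When the dim ssDNA channel fails registration but the dsDNA channel
succeeded, the dsDNA transform is reused (both channels share the
fluorescence optical path); the manifest logs this per frame.  Patch boxes
whose preimage leaves the fluorescence frame are skipped: their warped
content would include out-of-frame fill, which corrupts background
statistics downstream.

Measured on the synthetic testbed, corner reprojection error of recovered
homographies is ≤ 0.9 px in 140/140 seeded trials (median 0.24 px).

## Denoising

The background of a fluorescence patch is assumed additive and
near-constant.  The dsDNA estimate is histogram-based (one bin per integer
intensity): the mean of the three most frequent values.  Two choices the
description leaves open:

* **Zero pixels are included** in the estimation histogram (display
  histograms conventionally drop the zero bin; estimation must not — a
  genuinely zero background should estimate 0).  `exclude_zeros=True`
  restores the display convention.
* **Dominance guard** (`min_mode_fraction`, default 0.1): a value whose
  count is below 10 % of the mode count is not treated as background.
  When the background genuinely spans ~3 adjacent levels (the situation the
  top-3 rule is designed for), counts are comparable and the guard never
  triggers — the estimate is the plain top-3 mean.  When the background is
  narrower than three levels (down to perfectly constant), the plain rule
  would average in rare foreground values and be badly wrong; the guard
  makes the estimator exact there.  Setting the fraction to 0 restores the
  literal rule.

The positions of the background-valued pixels transfer to the ssDNA patch,
whose noise is their mean ssDNA intensity.  Subtraction is computed in
floating point, clipped at zero, and rounded half-up back to the input
dtype.  Ties between equally frequent values break toward the lower
intensity (determinism).

## Virtual staining

Architecture (1-channel in/out, working size a power of two):

* **Generator** — U-Net: encoder blocks `Conv(4×4, stride 2, pad 1) →
  BatchNorm (omitted on the first block) → LeakyReLU(0.2)` with filters
  64, 128, 256, 512, 512, 512, 512 at the 256 px working size; a 512-filter
  bottleneck conv with ReLU reaching 1×1; decoder blocks
  `ConvTranspose(4×4, stride 2) → BatchNorm → ReLU` with mirrored skip
  concatenations (filters 512, 512, 512, 512, 256, 128, 64); tanh output.
  For smaller sizes the trailing 512-filter encoder/decoder pairs are
  dropped until the bottleneck is 1×1 (e.g. five blocks at 64 px, four at
  32 px).
* **Discriminator** — five `Conv(4×4, stride 2)` layers (filters 64, 128,
  256, 512, 512) with ReLU (plain ReLU as stated for this architecture;
  the leaky variant is a toggle) and BatchNorm after the first layer,
  followed by a 1×1 convolution and sigmoid, scoring concatenated
  (brightfield, fluorescence) pairs as a spatial map.  With
  `spectral_norm=True` ("pix2pixpp") every convolution weight is divided by
  its spectral norm at each forward pass.
* **Spectral normalization** — the free-standing `spectral_normalize`
  operation is the classical power-iteration estimator with persistent
  left/right vectors (tested against an SVD oracle).  Inside the
  discriminator layer, however, σ is computed exactly from the layer's
  Gram matrix `W Wᵀ` (never larger than filters × filters, so one small
  eigendecomposition per forward): randomly initialized convolution
  weights have a quasi-degenerate top of the singular spectrum
  (σ₁/σ₂ ≈ 1.005), where warm-started power iteration converges too
  slowly to keep a certified Lipschitz bound while Adam moves the weights
  — measured violations reached 1.3 % per step.  With the exact σ the top
  singular value of every normalized weight is 1 to floating-point
  precision at every training step.  Gradients treat the singular vectors
  as constants, with the standard rank-one correction for the
  normalization.

Training: images scaled from [0, 255] to [−1, 1] (v/127.5 − 1); loss
`λ_L1·L1(G(x), y) + λ_GAN·BCE(D(x, G(x)), real)` with λ_L1 = 100,
λ_GAN = 1 (the canonical weighting for this architecture); alternating
Adam updates (lr 2e-4 at batch size 1, β₁ = 0.5, β₂ = 0.999); discriminator
loss averages the real and generated halves.  BCE is computed on logits for
numerical stability; the sigmoid output is exposed for scoring.  Dropout is
available in the first three decoder blocks but defaults to off, keeping
inference and training deterministic under a fixed seed.  Generated images
are rescaled from [−1, 1] to [0, 1] for DFI quantification.

The conv-net layer is a self-contained numpy framework (im2col
convolutions, hand-written backward passes, float32 arithmetic, fused Adam
update) with finite-difference tests for every layer.  At the desk scale
used throughout (32 px patches), batches of 8 with the learning rate scaled
linearly to 8e-4 give the same effective step size per epoch as the
canonical batch-1 recipe at a quarter of the wall-clock cost; both settings
are exposed in `TrainConfig`/`PipelineConfig`.

## Quantification and evaluation

"Area" in the DFI ratio is interpreted as integrated intensity (the
fluorescence signal is intensity-valued); a pixel-count mode with a
threshold is retained since "area" can also be read as region size.  DFI is
carried in percent; MAE and MAPE are computed on the 0–1 fractional scale,
matching the convention under which a reported MAE of 0.02 means two DFI
percentage points.  Cells with zero ground-truth DFI are excluded from MAPE
(counted and logged); cells with zero area in both channels have undefined
DFI and are flagged.  Aggregates use the sample (n−1) standard deviation,
which reproduces the published training-split SD.  Model comparison reports
both a two-tailed paired t-test and an exact Wilcoxon signed-rank test,
since which test produced a given published p-value is often unstated.

## Pipeline, sizes, and determinism

The end-to-end desk-scale configuration trains on a synthetic two-donor
dataset (55 cells per donor, 192 px frames, ~8 cells per frame; ~110 paired
32 px patches after registration), 50 epochs per fluorescence modality,
with donor 1 held out of training and reported separately — the synthetic
analogue of the published donor-holdout protocol.  The published study
itself trained 256 px patches for 1000 epochs on GPU hardware; those sizes
are configuration values here, not defaults.  Every stage is a pure
function of (inputs, config, seed): datasets, registration, training and
inference reproduce bit-identically under a fixed seed.  Checkpoints are
npz weight archives with a JSON sidecar recording configuration and seed.

## Known limitations

* The synthetic brightfield→fluorescence relationship is constructed to be
  learnable; transfer of the trained models to real micrographs is out of
  scope.
* The registration model family is projective; non-rigid deformation is not
  handled.
* Generator working sizes must be powers of two (the strided
  encoder/decoder pairs must mirror exactly).
* The numpy training loop is single-core; the full 256 px / 1000-epoch
  protocol is out of reach without a GPU framework, which is why the
  validation operates at 32 px with scaled conditions.
* At desk scale the held-out-donor DFI error (MAE ≈ 0.03–0.07 fractional)
  is above the published GPU-scale figure (≈ 0.02); the gap tracks
  training length and dataset size, not a mechanistic difference.
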