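# Methods

## Scope and design

`octstain` implements unpaired OCT→H&E virtual staining for coronary
tissue as a cycle-consistent GAN whose generators carry a Swin-style
transformer block (STB) and a structure-constraint / pathology-awareness
(SCPA) head.  The clinical data such a model is normally trained on is not
distributable, so the package ships a phantom generator that emulates the
statistical structure of coronary OCT/H&E patches and makes every
component testable on one CPU.

All tensors flow through `octstain.nn`, a small numpy reverse-mode
autodiff engine (conv / transposed-conv via im2col-col2im, fused layer and
instance normalisation, windowed attention, Adam).  Gradients of every
primitive are verified against central finite differences in the test
suite.

## Phantom model

A specimen is a locally planar three-layer slab: background/lumen above
the tissue surface, then intima, media, adventitia (default height
fractions 0.18 / 0.30 / 0.32, remainder background).  Interfaces get a
common tilt plus low-frequency sinusoidal undulation and small
per-interface jitter; the exact per-column interface rows and all
inclusion ellipses are stored with each sample so masks and labels can be
re-derived independently.  Planar rather than annular geometry is
deliberate: training patches cropped from B-scans are locally laminar, and
modelling lumen curvature would add nothing at patch scale.

* **OCT rendering** — per-layer mean reflectivity (intima 0.62, media
  0.30, adventitia 0.48, background 0.04), exponential depth attenuation
  (0.006 per pixel below the surface), multiplicative unit-mean gamma
  speckle with shape `1/contrast²` (default contrast 0.35), clipped to
  [0, 1].  This is the standard first-order speckle statistic; values were
  chosen once to give visually OCT-like layered B-scans with distinct but
  overlapping layer distributions.
* **H&E rendering** — per-layer RGB palette (pinks for intima/adventitia,
  a saturated purple-pink for media, near-white background) plus Gaussian
  pixel noise (sd 0.025).
* **Pathology** — elliptical inclusions placed in tissue: lipid renders as
  a soft-edged near-white hole in H&E and a blurred low-signal void in
  OCT; calcium as a sharp dark-purple region in H&E and a low-signal
  region with a bright specular rim in OCT.  An image is labelled
  pathological iff at least one inclusion was placed.

`generate_dataset` emits one image per sample, alternating domains across
samples with independent geometries — the OCT and H&E pools are therefore
unpaired by construction, mirroring how such cohorts are actually
collected.  A seeded choice of `round(labeled_fraction · n)` samples
carries pixel masks; the default `labeled_fraction = 0.5` is an arbitrary
stand-in for "a subset of images is pixel-wise annotated" and is flagged
as such.  Equal master seeds give byte-identical datasets.

What the phantoms do *not* model: physical wave propagation, catheter/polar
geometry, stain chemistry, inter-patient variability beyond geometric
jitter.  Tests passing on phantoms show the pipeline's mechanics and
optimisation behave correctly; they do not certify clinical image quality.

## Generator

Encoder: a stride-1 stem then three stride-2 3×3 convolutions (widths w,
2w, 4w, 4w), instance-normalised with ReLU.  The deepest grid (image/8)
feeds:

* **STB** — a 1×1 projection to `d_model`, then RSTBs.  Each RSTB chains
  STLs and ends in a 3×3 convolution; because every STL is residual, the
  convolution input equals the block input plus the accumulated STL
  features.  Each STL is pre-norm: `x + MHA(LN(x))`, then `x + MLP(LN(x))`
  with GELU.  Attention is windowed (`window × window` tokens, row-major),
  with a per-head relative-position bias table of (2·window−1)² entries
  indexed by 2-D offsets and shared across windows; every second STL uses
  a cyclic shift of `window/2` with the standard masked attention at the
  borders (skipped when the window already covers the grid).  Grids not
  divisible by the window are zero-padded bottom/right and cropped back.
* **SCPA** — deepest features are cut into P×P patches, flattened,
  linearly embedded and given learnable position embeddings
  (`z0 = x0 + pos`); a transformer encoder produces `z_L`; a decoder
  processes `[z_L; cls_intima, cls_media, cls_adventitia]` jointly
  (Segmenter-style) and splits into patch embeddings `z_M` and class
  vectors `c`.  Segmentation logits are the scalar products `z_M cᵀ`,
  nearest-upsampled to image resolution before the per-pixel softmax; the
  pathology score is a sigmoid two-level MLP on mean-pooled `z_M`.  `z_M`
  itself (as the same tensor object) is reshaped to the deep grid and
  concatenated channel-wise with the STB output.

Decoder: a 3×3 merge convolution, three stride-2 transposed convolutions
with U-Net skip concatenations from the matching encoder scales, and a
3×3 sigmoid head enforcing the [0, 1] output range.

Defaults follow Swin/SwinIR conventions at minimal viable size
(base_width 32, d_model 96, 2 RSTBs × 2 STLs, 3 heads, window 8 at the
368×368 full-scale preset).  The desk-scale `test_preset` used throughout
the tests (base_width 8, d_model 24, 1 RSTB × 2 STLs, window 4, SCPA patch
1 at 64×64) is the package's own choice of the smallest configuration
whose behaviour is still representative; with SCPA patch 1 the
segmentation grid is 8×8, fine enough to resolve the phantom layers.

The background class (code 3) exists only in masks for completeness; the
segmentation head is K = 3 and background pixels are excluded from the
structural loss and from accuracy metrics.

## Objective and training

* `L_adv`: least-squares form — generator term `E[(D(fake)−1)²]`,
  discriminator term `E[(D(real)−1)²] + E[D(fake)²]` on detached fakes.
* `L_cycle`: mean L1 of both reconstructions.
* `L_embedding`: the cited stain-transfer work does not restate its form;
  here it is pinned to the mean L1 distance between an input's bottleneck
  embedding (deepest encoder features, pre-STB) and that of its cycle
  reconstruction, both directions.  The term is isolated behind β so
  alternative readings can be plugged in.
* `L_SC`: pixel-wise cross-entropy of each generator's SCPA segmentation
  of *its own input* against that input's mask (domains are unpaired, so
  the input's own annotation is the only coherent supervision), restricted
  to labeled samples and non-background pixels; exact zero when nothing is
  valid.
* `L_PA`: binary cross-entropy on the pathology score, probabilities
  clamped at 1e−7; image-level labels exist for all samples.
* Weights default to (α, β, γ, ι) = (1, 0.2, 5, 5).

Discriminators are 70×70 PatchGAN stacks (three stride-2 and two stride-1
4×4 convolutions; the receptive field is computed analytically and tested).
Optimisation is Adam with betas (0.5, 0.999) for all four networks; the
learning rate starts at 1e−4 and decays linearly to zero in 2-epoch
blocks across the configured horizon.  One epoch is one pass over the
union of manifest rows (`ceil(n_rows / batch)` steps); each domain cycles
through its own shuffled queue, so OCT/H&E pairings are random and
independent.  Left-right flips are applied with probability 0.5 when
enabled.  No fake-image history pool by default (determinism of tests);
it is exposed as an option.  All randomness flows from one seeded
generator, so runs are bit-reproducible single-threaded, and checkpoints
carry parameters, optimizer state and the step counter — a resumed run
replays the data stream from the seed and is bit-identical to an
uninterrupted one.

### Desk-scale study

The acceptance study uses the phantom generator's default conditions
(inclusion radii 4–9 px at 64 px, scaled proportionally at other sizes).
It trains at 64×64, batch 1, 5,000 steps on 60 phantoms
(35 normal / 25 pathological, mirroring a 112:82 cohort; half labeled) and
evaluates on 24 held-out phantoms: generator-loss trend (first vs last
quintile medians), SCPA pathology accuracy, per-layer output colour vs the
H&E palette, and a T-GAN-style ablation (γ = ι = 0, architecture
unchanged) compared on segmentation accuracy over 3 seeds at 32×32.
Batch 1 with these problem sizes is the package's desk-scale choice; the
full-scale schedule (batch 9, 10,000 epochs) is preserved as the
`TrainConfig` defaults.

## Metrics

* **FID** `|μ_A−μ_B|² + Tr(Σ_A+Σ_B−2(Σ_AΣ_B)^{1/2})` over Gaussian fits
  to per-image pooled deep features.  The matrix square root uses the
  symmetric eigendecomposition `√Σ_A · Σ_B · √Σ_A` with eigenvalues below
  −1e−6 treated as numerical noise and clipped; singular covariances get
  1e−10 diagonal loading (logged).  The independent test oracle uses
  scipy's Schur-based `sqrtm`.
* **PHV** — each image is average-pooled per channel, pooled activations
  are averaged over each set, and the score is the percentage of channels
  whose set means agree within T (default 0.02).  Two readings were
  possible for the step direction; counting *agreements* is used so that
  higher = more similar, consistent with how the metric is ranked.
  Set-level (not per-image) differencing is forced by the unpaired
  setting.
* The default extractor is a seeded fixed-weight three-stage conv
  backbone: deterministic, no downloads.  Any callable with the same
  signature (e.g. a pretrained 101-layer residual network) can be plugged
  in; metric *values* depend on the extractor, the closed-form properties
  do not.
* **Reader study** — accuracy/precision/sensitivity/specificity per
  reader with "real" as the positive class; zero-denominator statistics
  are reported as undefined, never 0; averages are unweighted over
  readers.  ICC uses the two-way random-effects, absolute-agreement,
  single-rater form (via pingouin) and needs per-image ratings, not just
  counts.

## Inference

`stain_image` tiles large inputs with linear feathering in the overlap
(weights normalised to 1); a tile covering the image reproduces the
un-tiled forward pass bit-exactly.  `stain_volume` stains volumes
slice-by-slice, preserving slice count and spacing metadata.  8-bit
quantisation rounds half away from zero; 16-bit grayscale TIFF and
multi-page TIFF volumes are supported.

## Numerical choices and edge cases

* float32 throughout; losses reduced in float32, reported as Python floats.
* Softmax is shift-normalised; BCE clamps probabilities at 1e−7; the
  empty-supervision structural loss returns exact 0.
* Attention masks use −100 additive logits (soft exclusion, as in Swin).
* `sc_loss` rejects labels outside {0, 1, 2} on valid pixels; `total_loss`
  rejects non-finite components naming the offending term.
* Checkpoints are versioned npz archives; loading rejects unknown
  versions and shape mismatches.

## Known limitations

* The bundled autodiff engine is single-threaded numpy: full-scale
  (368×368, 10,000-epoch) training is out of desk scope by design.
* Phantoms are statistically, not physically, OCT-like; conclusions about
  clinical image quality require real data.
* The embedding-loss form and the exact pairing of labels in the printed
  structural/pathology expectations are ambiguous in the source
  formulation; the readings above are documented choices behind isolated
  weights.
* The relative-position bias shape is implemented in the standard Swin
  form; the printed `(2N−1)×(2N+1)` shape cannot index N²×N² attention
  logits and is treated as a typo.
* FID as printed omits the matrix square root (and carries a sign typo);
  the standard Fréchet form is implemented.
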