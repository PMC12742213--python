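# Methods

## Model

`swinreg` estimates a 12-parameter affine alignment `[t, r, s, h]` of a moving
3-D brain volume to a fixed atlas, unsupervised. The transform is the ordered
product `A = T · R · S · H` with `R = R_x(r_x) R_y(r_y) R_z(r_z)`; rotation,
scale and shear are conjugated to pivot about a centre point, by default the
moving image's intensity centre of mass `c_I = Σ p·I(p) / Σ I(p)`.

**Coordinate convention.** All matrices act in a normalized frame: each axis
of the volume maps to [−1, 1] with voxel centres at the interval ends and the
origin at the geometric centre. This makes parameters independent of grid
size across pyramid levels. Translation components are fractions of the
half-extent (so `t_x = 0.5` means half of one half-axis). Matrices are
*sampling* (pull) transforms: warping `M` by `A` yields `W(x) = M(A x)` with
trilinear interpolation and zero fill; label maps use nearest-neighbour.
Consequently applying stage transforms sequentially, stage 1 first, equals a
single warp by the left-to-right product `A₁A₂…A_n` — the accumulated matrix
is always applied to the *original* moving image, so interpolation error does
not stack.

**Constraints.** Raw head outputs are squashed smoothly:
`t = 0.5·tanh(·)`, `r = π·tanh(·)`, `s = 1 + 0.5·tanh(·)`, `h = π·tanh(·)`,
giving rotation/shear in [−π, π], translation in [−0.5, 0.5] and scale in
[0.5, 1.5]. The squashing (rather than clipping) keeps training
differentiable everywhere and makes the zero raw vector the exact identity.
Within these ranges the linear block has positive determinant: no
reflections.

## Architecture

Three stages over a trilinear image pyramid at scales 0.25/0.5/1.0 (levels
built by repeated 2× halving; each halving samples at the coarse voxel
centres, i.e. exact 8-neighbour averages, so mean intensity is preserved).
Per stage:

1. **Patch embedding** — non-overlapping windows of edge 2/4/8 (stage 1/2/3)
   flattened to vectors of length 8/64/512 and projected linearly to width
   `C`. A learned linear embedding of each patch's normalized centre
   coordinate is added: after mean pooling (below), pose information can only
   survive in position–content couplings, so tokens must carry absolute
   position. The initialisation is deliberately informative — position
   features start at content-comparable scale, one projection channel is
   seeded with the patch mean and three position channels with the raw
   coordinates — so attention can express content-selective normalized
   spatial moments (the sufficient statistics of an affine misalignment)
   from the first optimisation step. Volumes not divisible by the window are
   zero-padded high-side; such pad tokens stay in the grid.
2. **Fusion** — atlas and moving token sets are concatenated feature-wise
   (2C) and projected back to C. (Cross-attention is a possible alternative;
   concatenation keeps both stage inputs symmetric in treatment and cheap.)
3. **Attention block pairs** — each pair is LN→W-MSA→residual, LN→MLP→
   residual, LN→SW-MSA→residual, LN→MLP→residual. Window edge equals the
   stage's patch window; the shifted half cyclically shifts the (padded)
   token grid by half a window with the standard region-id mask so no
   attention crosses the wrap-around; a learned relative-position bias
   (one scalar per head per 3-D offset, zero-initialised) is added to the
   scores. 2 heads everywhere. With more than one pair per stage, a 2×2×2
   patch merge (concatenate 8 neighbours → linear 8C→2C) halves the grid
   between pairs.
4. **Dilated convolutional block** — tokens reshaped to a spatial map, then
   3×3×3 conv (dilation 1) → BatchNorm → ReLU → 3×3×3 conv (dilation 2) →
   BatchNorm → ReLU, giving a 7×7×7 receptive field without resolution loss.
   BatchNorm runs in the batch-size-1 regime (per-map statistics during
   training, running estimates at inference); this is stable here but is the
   usual caveat of that regime.
5. **Head** — tokens are mean-pooled, then linear (hidden width 4C) → Tanh →
   linear to the raw 12-vector; the final layer is zero-initialised so the
   untrained cascade outputs the identity transform exactly, the standard
   stable start for spatial-transformer training. The optional centre-of-mass
   initialisation is folded into the accumulated matrix.

Stage *i* warps the original moving image by the accumulated transform,
downsamples to level *i*, and predicts a residual transform about the warped
image's centre of mass.

Defaults: `C = 64`, block pairs (1, 2, 2), MLP ratio 4. The `tiny` preset
(`C = 16`, one pair per stage) is used by the desk-scale experiments; it has
~103 k parameters and runs a forward+backward pass on a 64×64×32 pair in a
fraction of a second on one CPU.

## Objective

`L = L_sim + λ·R`, λ = 0.01. `L_sim` is multi-resolution local NCC:
`Σ_i −(1/2^(L−i)) NCC_w(F_i, M_i(φ))` over `L = 3` pyramid levels (finest
weight −1, then −1/2, −1/4; identical pyramids approach −1.75). Local NCC
uses window `w = 7` (odd, standard for registration; `w = 0` selects global
NCC), with per-window statistics computed over the in-bounds voxels only —
border windows are clipped, not zero-padded, which preserves invariance to
local affine intensity changes everywhere — and an ε = 1e-5 variance guard so
flat windows contribute 0 rather than NaN. Note the guard makes the score on
images with large flat regions equal the textured-voxel fraction rather
than 1; this is intentional (flat regions carry no alignment information).

`R` is a dimensionless quadratic identity-deviation,
`Σ t² + Σ (r/π)² + Σ ((s−1)/0.5)² + Σ (h/π)²`, summed over stages; it is zero
iff every stage predicts the identity.

## Training

Adam, learning rate 1e-4, batch 1 (defaults). Training is label-free, so
model selection keeps the checkpoint with the lowest mean validation
*similarity* loss (ties → earliest epoch); early stopping after 30 epochs
without improvement; a divergence guard aborts after 10 consecutive
non-finite losses. Data splitting follows an 80/20 outer train/test split
with five seeded 80/20 train/validation resamples of the outer training set.
A single seed drives weight initialisation, shuffling, splitting and phantom
sampling; runs are bitwise reproducible on one device.

## Evaluation

Per-structure Dice (both-empty pairs count as 1, one-empty as 0), DSC30
(the mean of the lowest ⌈0.3·n⌉ per-structure Dice values — the aggregator
over the worst 30 % is a design choice), and HD95 (95th percentile of the
pooled directed boundary-voxel distances, computed via distance transforms;
voxel units by default, spacing-aware on request — reported magnitudes of a
few voxels suggest voxel units are the natural scale). A structure empty
after warping is reported as missing and excluded from HD95 with a warning.

## Synthetic cohorts

The generator emulates what the method actually exercises: an ellipsoidal
"brain" with a bright cortical shell, interior tissue, a deep core and up to
ten asymmetrically placed ellipsoidal blobs of distinct intensity (asymmetry
makes rotations identifiable); a smooth intensity gradient; Gaussian
smoothing; min–max normalization to [0, 1]. Per-subject anatomical jitter
(structure positions and sizes) is kept sub-voxel in scale, emulating the
homogeneity of a same-strain laboratory rodent cohort — the regime in which
affine registration to a common atlas is meaningful; with large anatomical
variability no affine map can produce high overlap and the overlap metric
would measure the generator, not the registration. What the phantoms do
*not* model: bias fields, EPI distortion, motion, multi-coil noise, real
anatomical topology. Passing the recovery experiment therefore demonstrates
the method's geometric and optimisation machinery, not robustness to scanner
physics.

Misalignments are sampled uniformly inside configurable ranges. Test-range
defaults (rotation ≤ 0.3 rad, translation ≤ 0.15, scale [0.9, 1.1], shear ≤
0.1) are deliberately milder than the hard constraint box so recovery is
well-posed; the full box is available. The moving image is built by warping
the phantom with the *inverse* of the sampled transform (plus optional
Gaussian noise), so the forward sampling transform the network must output
is exactly the sampled one.

## Numerical choices

* Float64 throughout; the autodiff engine's hand-written adjoints
  (convolution, box filter, trilinear sampling, softmax, indexing) are
  verified against central differences in the test-suite.
* Trilinear sampling uses the align-corners convention; out-of-bounds reads
  are zero in both the value and its gradient.
* Euler decomposition of an estimated matrix (QR with positive-diagonal
  upper factor) returns angles on the canonical branch |r_y| ≤ π/2.
* Degenerate inputs: zero-mass images raise for centre-of-mass operations;
  constant volumes normalize to zeros with a warning; empty label sets raise
  for HD95.

## Problem sizes

The recovery experiment defaults to 64×64×32 volumes, 50 training and 10
held-out pairs, 500 optimisation steps with the tiny preset at learning rate
1e-3 — chosen so a full simulate→train→register→evaluate cycle completes in
minutes on a single CPU while leaving the method's behaviour qualitatively
intact. The determinism check uses a reduced chain (6 pairs, 30 steps,
32³) since reproducibility is independent of problem size.

## Known limitations

* Affine only; no deformable refinement.
* Desk-scale amortized training is the method's weak regime, and the recovery
  experiment reports it honestly. The loss landscape itself is sound:
  optimising the 12 parameters directly for a single pair through the same
  warp/NCC path recovers rotations to ~0.002 rad. But a feed-forward
  predictor must read pose out of mean-pooled token embeddings, whose
  variation across misalignments is a small fraction of their magnitude at
  initialisation; with tens of training subjects and a few hundred batch-1
  steps the cascade reliably learns translation and scale corrections (every
  held-out pair improves over its unregistered baseline) while rotation
  regression stays near the cohort mean. Accurate amortized rotation recovery
  needs the cohort sizes and training horizons of a full study, not a
  desk-scale run — the same regime the original architecture class is
  designed for.
* BatchNorm's batch-size-1 regime ties inference statistics to the training
  trajectory.
* The exported world-space matrix assumes NIfTI affines with no shear
  between subject and atlas grids beyond what the headers encode.
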