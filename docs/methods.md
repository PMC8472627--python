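# Methods

## Problem and model

`cascadereg` performs unsupervised deformable registration of 3D scalar
volumes (the target regime is multi-organ abdominal CT resampled to a cubic
grid). Given a fixed image I_f and a moving image I_m on a shared domain,
the goal is a transform φ(x) = x + u(x) such that I_m ∘ φ ≈ I_f, found by a
learned coarse-to-fine cascade rather than per-pair iterative optimization:

1. **Coarse stage.** A convolutional regressor downsamples the
   channel-concatenated pair through stride-2 3³ convolutions to a
   4-voxel side and predicts 12 affine parameters through a fully
   connected layer. The affine map is parameterized by its *deviation*:
   φ_aff(x) = (I + A)x + b, so zero network output is the identity.
2. **Fine stage.** n recursive cascade modules, each a 3D U-net (stride-2
   encoder, transposed-convolution decoder with kernel 4 / stride 2, skip
   concatenation per matching resolution), each predict a residual dense
   displacement field from the previously warped image and the fixed
   image; the moving image is progressively warped module by module.
   An equivalent single field is obtained by resampling composition,
   u_g(x) = u_inner(x) + u_outer(x + u_inner(x)).

The training objective is

    L_total  = L_coarse + L_fine
    L_coarse = L_sim(I_f, I_m∘φ_aff) + λ1·L_ortho(A) + λ2·L_det(A)
    L_fine   = L_sim(I_f, I_m∘φ)     + Σ_k [λ3·L_smooth(u_k) + λ4·L_topo(u_k)]

with L_sim = 1 − CC (global Pearson correlation; appropriate for
mono-modal data), L_ortho = −6 + Σ(μ_i² + μ_i⁻²) over the singular values
of I + A, L_det = (det(I+A) − 1)², L_smooth the mean squared forward
difference of the field, and L_topo the mean over interior voxels of
max(0, −J) where J is the finite-difference Jacobian determinant of φ —
zero exactly when no voxel folds. Defaults: λ1 = λ2 = 10⁻¹,
λ3 = λ4 = 10⁻⁵; batch size 2, 5 epochs, Adam at learning rate 10⁻⁴.
Because every prediction head is zero-initialized, the untrained model is
exactly the identity and every regularizer starts at zero; the initial
total loss is the coarse plus fine similarity of the raw pair (the
similarity term appears once per stage, so it equals 2·L_sim at identity).

The similarity term of the coarse stage is evaluated on the affine-warped
image (before any fine module), and the fine-stage similarity once on the
final warped image with smoothness/folding penalties summed per cascade
field. Per-cascade similarity is a straightforward variant but is not the
default, matching the recursive-cascade convention of training through the
final composite.

## Numerical core

No GPU framework is used: the networks, their gradients and Adam run on a
compact reverse-mode autodiff engine (`cascadereg.autodiff`) written in
numpy. 3D convolutions and transposed convolutions are computed as one
GEMM per kernel tap over regularly-strided slices; trilinear grid sampling
is differentiable in both the sampled image and the displacement field
(so gradients flow through progressive warping into earlier cascades);
the loss terms carry analytic gradients (SVD-based for the orthogonality
term, cofactor-based for the folding term). Every operation's gradient is
verified against central finite differences in the test suite. Everything
is float32 and bit-deterministic given the seed.

Conventions: 0-based voxel indices; displacement fields in voxel units of
the fixed grid, component axis first in memory and last in NIfTI files;
out-of-grid samples return background 0; forward finite differences with a
one-sided difference at the far boundary (exact for affine maps), and
boundary voxels excluded from folding statistics.

## Phantom generator

The synthetic cohort stands in for inter-subject abdominal CT:

* Four contrast-separated soft ellipsoidal organs (a large right-side
  organ, two small posterior organs, a medium left-side organ) at jittered
  anatomically plausible positions, intensities 0.55/0.70/0.78/0.88 on a
  zero background, edges smoothed with a Gaussian of 1 voxel (sd),
  additive Gaussian noise (sd 0.02), clipped to [0, 1]. Overlapping
  placements are re-sampled, then rejected. Default grid 128³ at 3 mm
  isotropic spacing (the full-scale regime); the desk-scale profile uses
  32³.
* Ground-truth deformations: a moderate affine (per-axis scales in
  [0.95, 1.05], rotation ≤ 5°, translation ≤ 3 voxels, about the grid
  centre) composed with Gaussian-smoothed (sd 4 voxels) white noise
  rescaled to a 2-voxel maximum displacement. The composite field is
  verified orientation-preserving — the non-rigid amplitude is halved
  until the minimum interior Jacobian determinant exceeds 0.05 — so a
  fold-free solution always exists and the folding loss of the ground
  truth is exactly 0.
* Cohorts are atlas-paired: one phantom is the shared fixed image and
  each mover is that atlas warped by an independent ground-truth field.

What the phantoms do **not** model: CT noise texture and artifacts,
organ-boundary contact, sliding motion, respiratory deformation, intensity
inhomogeneity between subjects. Passing desk-scale tests therefore
demonstrates the correctness and trainability of the machinery, not
clinical-grade accuracy on real CT.

Because a mover is constructed as moving(x) = fixed(φ_gt(x)), a perfect
registration recovers the *inverse* of the ground-truth map; recovery
experiments compare the prediction against −t for a ground-truth
translation t. A predicted affine can also split a translation between
A·x and b, so the comparable scalar is the effective translation at the
grid centre, A·c + b.

## Desk-scale study protocols

Grids of 32³ with 8 base channels keep every experiment within minutes on
one CPU (sizes chosen as the package's reference desk-scale conditions):

* **Loss decrease** — 10 pairs, 2 cascades, 5 epochs, batch 2, lr 10⁻⁴
  (the default optimization protocol): final-epoch mean total loss falls
  strictly below the first-epoch mean.
* **Translation recovery** — 44 pure-translation pairs (40 train / 4
  held out, offsets ≤ 3 voxels), coarse-only model, 150 epochs at lr
  10⁻³: mean held-out recovery error < 0.5 voxel.
* **Cascade ablation** — shared 10-pair cohort (8 train / 2 test),
  20 epochs at lr 10⁻³, n ∈ {0, 1, 3}: mean test DICE non-decreasing
  in n.
* **Folding control** — same cohort and protocol, 2 cascades, with the
  default λ4 = 10⁻⁵ and with λ4 = 0: fraction of interior voxels with
  negative Jacobian determinant of the composite field < 1% under the
  default. At this scale the unpenalized run also does not fold (the
  ground-truth deformations are smooth and training is short), so the
  paired value is reported alongside rather than contrasted.

The recovery and ablation protocols use a higher learning rate and more
epochs than the 5-epoch default because the coarse regressor and the
cascades need more optimization steps to converge at this cohort size;
these are the package's reference settings for those experiments, fixed
in `cascadereg.experiments`.

## Design choices and degenerate inputs

* The correlation coefficient of a constant input is defined as 0 (loss 1)
  with a warning, avoiding division by zero on empty or fully-masked
  patches; CC is global over the volume, with no window.
* The specificity index is computed as TN/(TN+FP); a literal
  TP/(TN+FP) variant (seen in some write-ups, presumably a typo) is
  available behind `sc_as_printed=True`.
* The contour distance (CMD) is the max-of-directed-max form over boundary
  voxel sets (boundary = foreground voxel with a background face
  neighbour); a directed-mean variant is available via
  `reduction='mean'`. The Hausdorff distance uses full voxel sets. Both
  are in mm via the voxel spacing; empty masks yield NaN ("missing").
* Global SSIM constants: k1 = 0.01, k2 = 0.03, L = 1 for normalized
  volumes; PSNR uses MAXI = 1 and reports +inf at zero MSE.
* "Combining volumes with masks" is interpreted as masking intensities to
  the multi-organ ROI (`mask_to_roi`), with labels carried separately for
  evaluation; multi-channel or label-only registration would be
  alternative readings.
* Resampling to a cube preserves physical extent (spacing is rescaled);
  label maps resample nearest-neighbour only and never gain new labels.
* Channel widths (16 at the top, doubling, capped at 256; 8 in the desk
  profile), LeakyReLU(0.1) activations without normalization layers, and
  transposed-convolution upsampling are conventional choices where the
  architecture family leaves them open; they are configurable.
* Grids smaller than 128³ drop encoder/decoder levels so the coarsest side
  stays ≥ 4; sides must be powers of two ≥ 8.
* The coarse subnetwork trains jointly with the cascades under the single
  total loss; a `freeze_coarse` flag exposes the pre-trained-affine
  variant.

## Known limitations

* CPU-only and desk-scale: a 128³ seven-cascade model is expressible but
  slow to train in this engine; the shipped experiments use 32³.
* No diffeomorphic integration or inverse-field computation; composition
  is resampling-based and zero-extended outside the grid, so field algebra
  identities hold to interpolation tolerance and away from boundaries.
* The folding penalty controls but does not guarantee invertibility.
* Orientation handling on NIfTI read is canonical-axis reordering only;
  full affine-matrix geometry is out of scope.
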