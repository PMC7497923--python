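# Methods

`mindcycle` implements unsupervised deformable registration of multimodal
3D volume pairs (the motivating setting is pelvic CT/MR after rigid
pre-alignment) with two jointly trained fully convolutional networks that
regress dense displacement fields, supervised only by image content:
a modality-independent descriptor loss, a field smoothness penalty, and a
cycle-reconstruction loss. This note records the model, the conventions
chosen where the design was genuinely open, what the synthetic phantoms
do and do not emulate, and the numerical choices that matter.

## Model

Let `I_m` be the moving and `I_f` the fixed volume, both preprocessed to
a common grid and intensities in [-1, 1]. A network `G` maps the
two-channel pair to a displacement field `f = G(I_m, I_f)` in voxel
units; the transformation is `phi(x) = x + f(x)`, applied by trilinear
resampling (`warp`). Two networks are trained jointly, one per
registration direction. For one direction the loss is

    L_dir = l1 * Lcont(warp(I_m, f), I_f)
          + l2 * Lreg(f)
          + l3 * Lcyc(I_m)

with defaults `l1 = 5, l2 = 1, l3 = 1`, and the total objective is the
sum over both directions.

**Content loss.** Per voxel x and search offset r, the MIND response is

    MIND(I, x, r) = (1/n) exp(-D(I, x, r) / V(I, x))

where `D` is the summed squared difference between the image patch at x
and the patch at x + r, and `V` is the mean of `D` over a small
neighborhood of x, floored at a small epsilon. `Lcont` is the mean
absolute difference between the MIND stacks of the warped moving and the
fixed image. Because the descriptor encodes local self-similarity only,
it is comparable between modalities whose intensities are related by an
arbitrary (even non-monotone) tissue mapping.

Conventions:

- Patches and the search region are in-plane by default (5x5 patch,
  7x7 region minus the zero offset, i.e. 48 responses per voxel),
  appropriate for thick-slice acquisitions; cubic 3D mode via
  `MindConfig(mode_2d=False)`.
- The normalization constant `n` is realized per voxel as division by
  the maximum response over the search region, the convention of the
  original MIND literature, so responses lie in (0, 1] with per-voxel
  maximum exactly 1.
- The variance neighborhood is the 4-connected in-plane ring and `V` is
  the *mean* of `D` over it. (The "3 neighborhood" with a 1/3 factor
  sometimes quoted for this estimator is internally inconsistent; the
  mean over a well-defined neighborhood is used instead, and the
  neighborhood is configurable.)
- Variance floor: `epsilon = 1e-6 * (intensity range)^2`, with an
  absolute floor of 1e-12, so flat regions produce uniform (all-one)
  descriptors rather than divisions by zero.
- Boundary handling is edge replication, realized through clipped index
  reads: a patch sample position is clamped to the grid, and the search
  offset is applied to the clamped position and clamped again. The
  brute-force reference implementation in the test suite uses the same
  convention, and the dense (shifted-difference + separable box sum)
  path reproduces it to machine precision.
- `Lcont` divides by the product of voxel count and region size (a
  single mean over the response stack); sequential means would give the
  identical value.

**Regularization.** `regularization_loss` implements the literal squared
displacement magnitude, mean over voxels (`loss(f) = mean_x |f(x)|^2`),
with an optional first-difference (diffusion) penalty
(`penalty="gradient"`). The *training objective* defaults to the
gradient penalty: its purpose is smoothness of the deformation grid, and
at the default weights a magnitude penalty is so strong a zero-field
prior that it suppresses the content term entirely (any displacement of
~1 voxel rms costs about 1.0 while full alignment of a typical phantom
pair gains only ~0.1 of weighted content loss), pinning training at the
identity. `reg_penalty: magnitude` in the training config restores the
zero-displacement prior for experimentation.

**Cycle loss.** The deformed image is fed back through the opposite
network together with the original moving image, and the L1
reconstruction error is taken:

    Lcyc(I_m) = || warp(warp(I_m, G(I_m, I_f)), G'(deformed, I_m)) - I_m ||_1

Reconstruction composes two resampling steps (the second network sees
the *deformed* pair), not an analytic composition of fields. Both
directions contribute one cycle term each.

## Network

Encoder: `n_scales` (default 3) stride-2 3x3x3 convolutions with ReLU;
strides are in-plane only by default because thick-slice volumes have
too few slices to halve repeatedly (`stride_z=2` available). Channels
double per scale from `base_channels` (default 32). Bottleneck:
`n_resnet_blocks` (default 9) residual blocks, each two 3x3x3
convolutions with instance normalization, ReLU, and an identity skip.
Decoder: nearest-neighbor 2x in-plane resize followed by a stride-1
3x3x3 convolution and ReLU per scale (resize-convolution avoids the
checkerboard artifacts of transposed convolutions). Head: 1x1x1
convolution to 3 channels followed by `max_displacement * tanh`
(default 10 voxels), bounding the field. With `final_zero_init` (default)
the head starts at zero, so the initial transform is exactly the
identity — training starts from "do nothing" rather than from a random
deformation.

All tensors are float64 and the forward/backward passes run on a small
tape-based reverse-mode engine written for this package
(`mindcycle.autodiff`); convolutions are im2col matrix products, warping
and shifting are gathers whose adjoints are scatter-adds or pure
slicing. Gradients of every primitive are checked against central
finite differences in the test suite.

Optionally the head can emit the field on a coarser in-plane grid that
is then linearly upsampled (`field_scale`, default 1 = full-resolution
output): each coarse degree of freedom aggregates the loss gradient of
`field_scale²` voxels, which accelerates convergence on smooth
deformations at the cost of fine-grained field detail.

## Training

Joint Adam (default lr 1e-4, betas (0.5, 0.999) — the momentum-light
setting customary for cycle-consistent image translation; the end-to-end
phantom study uses lr 5e-3, see below) over both networks' parameters on
the summed objective, batch size one volume pair, constant learning
rate. The MIND stacks of the two *fixed* (unwarped) images are
precomputed once per pair and cached; only the warped image's descriptor
is differentiated. Masks and landmarks are never visible to training.
Training aborts with the last finite state saved if any loss term goes
non-finite. All randomness (network init order, seed fan-out) derives
from a single seed via named substreams, and runs are bit-reproducible
single-threaded. Two further options default off: `lr_final` enables
exponential learning-rate decay across epochs, and
`content_smooth_sigma` applies a mild differentiable Gaussian blur to
the images inside the content term (a coarse-scale conditioning device;
at the desk-scale settings studied here it flattened the descriptor
signal more than it helped, hence the off default).

At desk scale the amortization is data-limited: with only eight
training pairs the networks reliably learn small corrective fields that
transfer to held-out pairs, while forcing optimization to convergence
produces larger deformations that fit the training pairs' descriptor
loss but do not transfer. The shipped study configuration therefore
stays in the light-training regime; its held-out Dice/TRE improvements
are modest by construction (pre-registration Dice at these settings is
already ~0.85-0.90, and nearest-neighbor mask warping quantizes away
sub-half-voxel corrections).

## Preprocessing

`resample` (trilinear, physical-extent preserving, edge hold outside the
grid) to a target spacing, typically (1, 1, 5) mm; `crop_or_pad` to a
fixed grid, centered on the foreground centroid (threshold at the 5th
intensity percentile, configurable) with minimum-intensity (air)
padding; `normalize_intensity`, a robust rescaling that maps the 1st/99th
percentile window linearly onto [-1, 1] with clipping. The percentile
window realizes the otherwise undefined "standardization" step; both
percentiles are configurable. The percentiles are order statistics
(lower/higher interpolation), which makes the map exactly idempotent on
its own output. Volumes are axis-aligned: voxel index i maps to physical
position `origin + i * spacing`; direction matrices are out of scope.

## Synthetic phantoms

`generate_case` builds a multimodal pair with known ground truth:

1. a shared anatomy defined *analytically* in continuous coordinates —
   smooth soft-tissue gradient, a bladder-like ellipsoid, a rectum-like
   tube, two bright bone shells;
2. a ground-truth displacement field: per-component Gaussian-smoothed
   white noise (scale `deformation_smoothness`, default 8 voxels),
   scaled so the peak magnitude equals `deformation_amplitude` (default
   3 voxels), with the through-plane component damped by the spacing
   ratio so displacements stay commensurate in millimetres; generation
   fails if the field folds (checked via the Jacobian determinant);
3. modality renderings: map A resembles CT (bone brightest, soft
   tissues mid-range); map B rank-permutes the tissue intensities and
   reverses the background gradient, so the pair is non-monotonically
   related and raw per-voxel intensity correlation is weak — intensity
   metrics fail while structure matches;
4. the B volume is rendered at inverse-warped sample positions (the
   displacement field inverted by fixed-point iteration), so warping
   vol_b by `gt_field` recovers the A-side anatomy exactly up to
   interpolation; masks are rendered analytically in each space (no
   resampling error) and landmark pairs satisfy `p_b = p_a + f(p_a)`
   exactly, giving TRE = 0 under the ground-truth field;
5. spatially correlated Gaussian noise (sd 0.02 intensity units,
   correlation scale 1 voxel) is added independently per modality.
   Correlated rather than white noise is used deliberately: white noise
   is destroyed by trilinear resampling while the fixed image's noise
   stays crisp, which systematically raises the descriptor loss of
   correctly warped images — an artifact reconstructed medical images,
   whose noise is correlated over a voxel or two, do not show;
6. both volumes are normalized to [-1, 1].

Default grid 64x64x16 at (1, 1, 5) mm. The end-to-end study in
`scripts/acceptance.py` uses 32x32x8 phantoms (8 training, 2 held-out
pairs) so that full training fits in minutes on one CPU; the network for
that study is correspondingly small (base_channels 12, 2 residual
blocks, 2 scales, max_displacement 6), trained with Adam lr 5e-3 for 60
epochs (480 pair-steps).

What the phantoms do **not** emulate: anatomically realistic pelvic
shapes and tissue textures, CT Hounsfield calibration, MR bias fields
and physics, rigid misalignment (pairs are generated rigidly aligned,
mirroring the rigid pre-registration the method assumes), sliding-organ
discontinuities, and scanner-specific artifacts. Passing the phantom
suite therefore demonstrates the machinery end to end — the losses
drive real alignment, metrics and ground truth are consistent — but
does not certify clinical accuracy on patient data.

## Evaluation

- **Dice** per label, defined as 1 when both sets are empty (logged).
- **ASD**: symmetric mean over both boundaries of each surface voxel's
  nearest Euclidean distance to the other boundary, in mm with
  anisotropic spacing; surface voxels are labeled voxels with a
  face-adjacent background neighbor. Two interchangeable backends — an
  exact all-pairs search and a Euclidean distance transform — agree to
  1e-9 and are cross-checked in the tests.
- **TRE**: the displacement field lives on the fixed grid, so each
  *fixed* landmark is mapped through `x + f(x)` (field interpolated
  trilinearly at the point, converted to mm) and compared with its
  paired moving landmark. Under the zero field this reduces to the raw
  landmark offsets.
- **Folding fraction**: fraction of interior voxels with non-positive
  finite-difference Jacobian determinant of `x + f(x)`; 0 for any
  sensible field, 1 for an orientation reversal.
- Moving-space ROI masks are warped into fixed space with
  nearest-neighbor interpolation (labels are never blended). At coarse
  grids this discretization caps achievable warped-mask Dice well below
  1 even for the ground-truth field (about 0.93 at 32x32x8, above 0.95
  at the 64x64x16 default) — pre/post comparisons use the same path, so
  the comparison stays fair.

## Numerical choices and degenerate inputs

- Constant-intensity volumes normalize to all zeros with a warning
  (zero percentile range).
- NaN/Inf intensities are rejected at load and at save.
- `crop_or_pad` windows falling partly outside the grid fill with the
  volume minimum (air); the physical origin is updated.
- Trilinear warping clamps sample positions to the grid (edge
  replication); gradient contributions are zero where the clamp is
  active.
- The per-voxel descriptor maximum is differentiated through the argmax
  (ties route to the first maximum).
- Fixed-point inversion of the ground-truth field runs 30 iterations,
  ample for the default amplitude/smoothness ratio (contraction factor
  well below 1; the folding check would reject fields outside this
  regime).

## Known limitations

- No GPU path; the autodiff engine is single-threaded numpy and is
  sized for desk-scale problems (tens of thousands of voxels per
  volume). The clinical-scale 200x200x24 configuration is expressible
  but slow to train here.
- The MIND optimum under trilinear interpolation is biased slightly
  below the true deformation magnitude (warping smooths the moving
  image, which perturbs its descriptors), so recovered fields
  under-estimate large displacements; alignment metrics still improve.
- Only axis-aligned volumes; no direction cosines, no DICOM series.
- No diffeomorphic parameterization; plausibility is monitored (not
  enforced) via the folding fraction.
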