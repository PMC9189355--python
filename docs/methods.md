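# Methods

`cbctkit` compares two routes to a treatment-day CT-quality image in pelvic
radiotherapy: deforming the planning CT onto the daily cone-beam CT
(registration → "dpCT") and translating the CBCT into a CT-like image with a
generative model (synthesis → "sCT"). Everything runs on a synthetic pelvic
phantom with exact ground truth, so the comparison that matters clinically —
registration accuracy collapses when the bladder volume differs strongly
between scans, synthesis accuracy does not — can be measured rather than
argued.

## The digital pelvic phantom

The phantom is built from geometric primitives rasterized in Hounsfield
units: an elliptic-cylinder body (soft tissue, 45 HU), an ellipsoidal
bladder (urine, 2 HU), a spinal-cord cylinder (85 HU) inside a bony
vertebral ring, spherical femoral heads (700 HU), and paired iliac
bone-marrow segments (300 HU), plus per-tissue Gaussian jitter (SD 5 HU).
These contrasts follow typical soft-tissue CT values; in particular the
urine/muscle difference of ≈40 HU is what lets a delineator (or a
registration algorithm) follow the bladder wall on a CBCT.

A CT/CBCT pair is produced by warping the CT with a known smooth
displacement field and then corrupting the warped copy additively:

* **Deformation.** Gaussian-perturbed control points (default spacing
  25×40×40 mm) interpolated with cubic splines, tapered to zero in a 10%
  boundary band (the skin outline is reproducible between scans), weighted
  toward the bladder region (inter-fraction pelvic deformation is dominated
  by bladder/rectum filling; the periphery and bony frame are stable), with
  the through-plane component damped by 0.4 (at 5 mm slices, through-plane
  soft-tissue motion is small and barely representable). The dense field is
  rescaled so its maximum vector norm equals `max_displacement_mm`
  (default 12 mm). Keeping that bound under a third of the control spacing
  keeps the map invertible (checked via the discrete Jacobian).
* **Bladder volume mismatch.** A radial expansion field about the bladder
  center realizes a target volume-difference statistic
  Diff = |V_CBCT − V_pCT| / min(V_CBCT, V_pCT) × 100%; the achieved Diff is
  measured on the label maps and the linear scale corrected until it lands
  within 10% (relative) of the target. The expansion displaces the
  surrounding soft tissue smoothly out to 1.8 bladder radii and is composed
  into the ground-truth field.
* **Degradation.** Additive and deliberately simple — an emulation of an
  iteratively reconstructed CBCT, where statistical reconstruction keeps
  noise moderate but residual scatter shading and streaks remain: Gaussian
  noise (SD 18 HU), a smooth bias field (amplitude 60 HU, correlation length
  80 mm), a handful of in-plane streaks (6 lines, ±40 HU), an optional
  cavity-artifact blob and couch slab. No projection/reconstruction physics
  is simulated; the model only needs to exercise the same failure modes the
  algorithms face (cross-scan intensity inconsistency, fake edges, noise).

What the phantom does **not** emulate: bowel/rectal gas reconfiguration,
bladder-content HU changes, truncation, motion blur, or observer variability
in contouring (labels are exact). Reported Dice values are therefore
optimistic relative to clinical numbers and are compared directionally, not
absolutely.

## Preprocessing

Skin mask by thresholding at −300 HU with per-slice morphological closing,
couch rejection (border-touching flat components), largest component and
per-slice hole filling; air fill (−1000 HU) outside the body; trilinear
resampling to the working grid; rigid alignment of the CT to the CBCT
(skin-centroid translation followed by a coarse-to-fine NCC hill climb over
translations and in-plane rotation — only improvements are accepted);
in-plane cropping centered on the skin centroid (floor convention for even
sizes). The registration branch then clips to [−250, 200] HU and maps
linearly onto (−1, 1); the synthesis branch uses tanh(HU/400), whose inverse
is clamped to ±1200 HU (atanh diverges at ±1; the clamp bounds synthetic
intensities to a physically meaningful range).

## Registration (MSnet)

A three-stage coarse-to-fine cascade. Each stage sees the (already warped)
moving image and the fixed image as a two-channel 3D volume and predicts a
residual displacement field through an encoder (two stride-2 convolutions) →
six residual blocks → decoder (two nearest-upsample + convolution) network;
the output convolution is zero-initialized so optimization starts at the
identity. Stage fields are upsampled, scaled to voxel units and composed
(`u_total = u_inner + u_prev(x + u_inner)`); contours propagate by
nearest-neighbor warping.

The objective is unsupervised: a MIND dissimilarity plus a diffusion
smoothness term on the residual field. Design choices that mattered, all
established on phantom experiments during development:

* **Pyramid scales are in-plane only** (1/4, 1/2, 1): 5 mm slices are
  already coarse, and pooling the slice axis made through-plane motion
  unrecoverable.
* **MIND variance floor.** The descriptor divides patch dissimilarities by a
  local variance estimate, which is scale-invariant: with a tiny floor,
  *independent* per-scan noise in homogeneous tissue produces O(1)
  descriptor mismatch that dominates the loss (we observed fitted fields
  scoring *better* than the ground-truth field while moving organs the
  wrong way). The floor defaults to 0.3 of the global mean dissimilarity,
  which suppresses the homogeneous-region mismatch while leaving genuine
  edges (far above the mean) intact. Affine intensity invariance is
  unaffected.
* **Noise prefilter.** Both loss images are smoothed with an in-plane
  Gaussian (σ = 1 voxel) before the descriptor.
* **Optimization schedule.** Adam (lr 2e-3) with global-norm gradient
  clipping at 1.0 — without clipping, a minority of seeds diverge with
  exploding gradients. Iterations are front-loaded to the coarse stage
  (180/100/8 by default, ≤ 300 total): the coarse grid can already express
  smooth anatomical deformation, while the finer stages refine with smaller
  steps (lr × 0.5, × 0.15) under progressively stronger smoothness
  (× 2, × 4). Unconstrained fine stages otherwise "explain" irreducible
  appearance mismatch by deforming anatomy.
* **Instance fitting.** At desk scale the cascade is optimized per image
  pair; the objective is identical to population training, and
  `train_registration` accepts multiple pairs (iterations then cycle
  through them).

Typical desk-scale behavior (grid 16×96×128 at 5×2×2 mm, 8 base channels,
one CPU): a fit takes ≈ 1 minute; with a bladder Diff < 20% the bladder Dice
moves from ≈ 0.78 pre-registration to ≈ 0.85–0.91, mean endpoint error
≈ 1.0–1.5 voxels inside the body; with Diff > 100% the recovered Dice drops
by ≥ 0.10 relative to the small-mismatch condition, reproducing the failure
mode that motivates the synthesis route.

## Synthesis (CycleGAN)

Two 2D generators (CBCT→CT and CT→CBCT) and two patch discriminators train
on axial slices normalized by tanh(HU/400). The generator loss is
`L_adv + λ·L_cycle + μ·L_sc` with λ = μ = 10: a least-squares adversarial
term, L1 cycle reconstructions, and a similarity constraint — the MIND loss
between each synthetic slice and its source slice, which ties synthetic
anatomy to the input image rather than to the training distribution.
Generators are ResNet (15 residual blocks) or U-net (5 levels); both carry a
global input-residual skip by default (the head predicts a correction in
pre-tanh space, so a fresh generator is the identity map) — at desk training
budgets a plain generator spends its entire budget re-learning the image
content before it can begin correcting it. The step size is constant for the
first half of training and decays linearly to zero over the second half
(0.002 at full scale). The discriminator step size is a separate knob
(`disc_rate`; the desk presets use 0.02 so the discriminator learns faster
than the generators); discriminator updates draw on an image-history pool
of 50, and batches may be paired (registered slices) or shuffled.

Desk preset: 96×128 slices, 6 base channels, subsampled epochs (8 batches of
6 slices per epoch). What scale buys and what it costs: the desk runs
demonstrate that training optimizes its objective (cycle and adversarial
losses descend) and that the synthetic image's *geometry* follows the CBCT —
the property the central comparison needs — but a few hundred optimizer
steps cannot reproduce the intensity-restoration quality of full-scale GAN
training (tens of thousands of steps).

## Study design and evaluation

The study generates cases across four bladder volume-difference strata
(<20%, 20–50%, 50–100%, >100%; cases are assigned to strata by the
*measured* Diff), registers each pair, synthesizes an sCT with a generator
trained once per study on a disjoint training split, and scores: Dice of
propagated contours against the CBCT ground-truth labels (registration);
Dice of an HU-band re-segmentation of each organ on the sCT against the same
labels (synthesis — a deterministic stand-in for physician re-delineation:
threshold in the organ's HU band within a dilated neighborhood of the true
mask, keep the largest component); NMI/NCC before and after registration;
and MAE/RMSE/PSNR/SSIM of CBCT and sCT against the clean warped CT.
Evaluation formulas: Dice 2|A∩B|/(|A|+|B|); NMI 2·MI/(H1+H2) from a joint
histogram over a fixed [−1000, 1500] HU range (64 bins; natural logarithm —
NMI is base-invariant); NCC with population standard deviations; PSNR with
MAX taken from the reference image; SSIM with 11×11 in-plane windows
averaged over slices (c1 = (0.01·L)², c2 = (0.03·L)², L the reference
dynamic range).

## Numerical conventions and degenerate inputs

Axis order (z, y, x) everywhere; displacement fields are voxel-unit vectors
on the fixed grid with `out(x) = in(x + u(x))`; out-of-bounds warp reads
return air (images) or background (labels), while the differentiable warp
used inside training clamps at the volume border to keep the objective
smooth. Dice of two empty masks is 1; NMI/NCC reject constant images; PSNR
of identical images reports +inf; resampling uses edge clamping so constants
are preserved exactly. All randomness flows from explicit integer seeds
through `numpy` generators; training, phantom generation and the study are
bitwise reproducible for a fixed seed on a fixed platform.

## Known limitations

* The phantom's failure modes are a subset of clinical ones; absolute Dice
  values are optimistic and only directions/differences are meaningful.
* Desk-scale synthesis demonstrates structure preservation, not
  intensity-restoration quality; image-error metrics for the sCT at desk
  scale reflect a generator a few hundred steps into training.
* The rigid-alignment search covers translations and in-plane rotation
  only, which matches the phantom's geometry but not all clinical setups.
* Instance-fit registration re-optimizes per pair; the full-scale
  population-training path shares the same code but has not been run at
  full scale on CPU.
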