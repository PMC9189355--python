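# cbctkit

Tools for improving cone-beam CT (CBCT) image quality in pelvic
radiotherapy, built around the comparison that decides clinical workflow:

* **dpCT** — deform the planning CT onto the daily CBCT with an
  unsupervised multi-stage 3D registration network and propagate its
  contours, or
* **sCT** — translate the CBCT into a CT-like image with a
  similarity-constrained CycleGAN and contour that.

Registration keeps real CT intensities but inherits the planning-day
anatomy; synthesis follows the treatment-day anatomy but invents
intensities. When the anatomy barely changes between scans the two are
equivalent; when it changes a lot — for pelvic patients, chiefly the degree
of bladder filling — registration accuracy collapses while synthesis
accuracy does not. `cbctkit` reproduces this comparison end to end on a
digital pelvic phantom with exact ground truth, so no patient data is
needed.

## What is inside

| Module | Role |
| --- | --- |
| `cbctkit.core_io` | `ImageVolume` / `LabelMap` data model, NIfTI I/O, run config |
| `cbctkit.phantom` | pelvic CT/CBCT pair generator: anatomy in HU, CBCT-style degradation, known smooth deformations, controllable bladder volume mismatch |
| `cbctkit.preprocess` | skin mask, couch removal, air fill, resampling, rigid alignment, centered crop, intensity normalizations |
| `cbctkit.mind` | modality-independent neighborhood descriptor (MIND) and its L1 loss |
| `cbctkit.registration` | MSnet: 3-stage coarse-to-fine displacement cascade, unsupervised (MIND + smoothness), warping/composition, contour propagation |
| `cbctkit.synthesis` | CycleGAN (ResNet-15 / U-net-5 generators, patch discriminators), `L_G = L_adv + λ·L_cycle + μ·L_sc` with λ = μ = 10 |
| `cbctkit.metrics` | NMI, NCC, DSC, MAE, RMSE, PSNR, SSIM and the volume-difference statistic Diff = \|V₁−V₂\|/min(V₁,V₂)×100% |
| `cbctkit.study` | stratified end-to-end comparison study and report rendering |
| `cbctkit.autodiff` / `cbctkit.nn` | compact numpy reverse-mode autograd and conv layers the networks run on (CPU, deterministic) |

The model math is in `docs/methods.md`.

## Worked example

Register a phantom pair with a known deformation and a 17% bladder volume
difference, then check how well the propagated bladder contour matches the
CBCT ground truth:

```python
import numpy as np
from cbctkit.phantom import PhantomSpec, DegradationSpec, DeformationSpec, make_pair
from cbctkit.preprocess import desk_config, extract_skin_mask, fill_outside_body, normalize_registration
from cbctkit.registration import MSNetConfig, train_registration, propagate_contours
from cbctkit.metrics import dsc
from cbctkit.core_io import extract_mask

spec = PhantomSpec(grid_shape=(16, 96, 128), spacing=(5, 2, 2), seed=1)
fspec = DeformationSpec(max_displacement_mm=16.0, control_spacing_mm=(25, 48, 48), seed=101)
pair = make_pair(spec, DegradationSpec(seed=201), fspec, bladder_diff_target=18.0)

cfg = desk_config()
skin = extract_skin_mask(pair.cbct, cfg)
moving = normalize_registration(fill_outside_body(pair.pct, extract_skin_mask(pair.pct, cfg)), cfg)
fixed = normalize_registration(fill_outside_body(pair.cbct, skin), cfg)

model, result = train_registration([(moving, fixed)], MSNetConfig(seed=1), region=skin)
dmask = propagate_contours(pair.pct_labels, result.field)

truth = extract_mask(pair.cbct_labels, "bladder")
pre = dsc(extract_mask(pair.pct_labels, "bladder"), truth)
post = dsc(extract_mask(dmask, "bladder"), truth)
epe = np.sqrt(((result.field - pair.true_field) ** 2).sum(-1))[pair.cbct_labels.labels > 0].mean()
print(f"bladder DSC {pre:.3f} -> {post:.3f}, mean endpoint error {epe:.2f} voxels")
```

On one CPU core this takes about a minute and prints

```
bladder DSC 0.769 -> 0.910, mean endpoint error 1.24 voxels
```

i.e. the instance-fit cascade recovers most of the known deformation: the
propagated bladder contour overlaps the ground truth at Dice 0.91 and the
estimated field is ≈1.2 voxels from the true one inside the body. Repeating
with `bladder_diff_target=250` (a more-than-doubled bladder) drops the
post-registration Dice to ≈0.72–0.77 — the failure mode that motivates the
synthesis route, whose re-segmented bladder Dice is insensitive to the
volume difference.

The same steps are available from the shell:

```
cbctkit phantom make-pair --seed 1 --bladder-diff 18 --preset desk --out pair/
cbctkit register --moving pair/pct.nii.gz --fixed pair/cbct.nii.gz \
        --labels pair/pct_labels.nii.gz --out reg/
cbctkit metrics --ref pair/cbct_clean.nii.gz --test pair/cbct.nii.gz --out report.json
cbctkit study --seed 0 --cases-per-stratum 1 --out study_out/
```

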