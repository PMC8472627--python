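# cascadereg

Unsupervised coarse-to-fine recursive-cascade registration for 3D
multi-organ volumes, with a synthetic phantom bench and a nine-metric
evaluation suite.

Deformable registration aligns a *moving* volume I_m to a *fixed* volume
I_f through a transform φ(x) = x + u(x). Classical per-pair optimization
is accurate but slow; this package implements the learned alternative: a
**coarse affine subnetwork** (predicting a deviation A and offset b, so the
map is (I+A)x + b and zero output is the identity) followed by **n
recursive cascade modules**, each a 3D U-net that predicts a residual
dense displacement field from the previously warped image, trained
end-to-end *without* ground-truth deformations by minimizing

    L_total  = L_coarse + L_fine
    L_coarse = (1 − CC(I_f, I_m∘φ_aff)) + λ1·L_ortho(A) + λ2·L_det(A)
    L_fine   = (1 − CC(I_f, I_m∘φ))     + Σ_k [λ3·L_smooth(u_k) + λ4·L_topo(u_k)]

where CC is the global correlation coefficient, L_ortho/L_det keep the
affine map near-orthogonal and volume-preserving, L_smooth is the L2
variation of each cascade field, and L_topo penalizes folding — the mean
over voxels of max(0, −J) with J the Jacobian determinant of φ. Defaults
λ1 = λ2 = 0.1, λ3 = λ4 = 1e−5; batch 2, 5 epochs, Adam at 1e−4.

It is aimed at researchers who want a fully inspectable, CPU-deterministic
implementation of this model family: the networks and their gradients run
on a small numpy autodiff core (every gradient is finite-difference
verified in the tests), and a multi-organ phantom generator with known
ground-truth deformations makes the whole pipeline testable at desk scale
without any data download. Volumes, label maps and displacement fields are
NIfTI-1 (fields as 4D, component last, voxel units).

## Worked example

```python
from cascadereg import (PhantomSpec, DeformationSpec, CascadeRegistrator,
                        make_phantom_dataset, evaluate_case)

# 10 atlas-paired 32-cube phantoms (8 train / 2 test) with known fields
ds = make_phantom_dataset(10, PhantomSpec(grid_shape=(32, 32, 32), seed=7),
                          DeformationSpec(seed=100), test_fraction=0.2)

est = CascadeRegistrator(n_cascades=1, grid_side=32, base_channels=8,
                         epochs=20, learning_rate=1e-3, seed=0)
est.fit(ds)
print(f"total loss {est.history_.total.iloc[0]:.3f} -> "
      f"{est.history_.total.iloc[-1]:.3f}")

case = ds.test_cases()[0]
before = evaluate_case(case.fixed, case.moving,
                       case.fixed_labels, case.moving_labels).as_dict()
warped, field, warped_labels = est.register(case.moving, case.fixed,
                                            case.moving_labels)
after = evaluate_case(case.fixed, warped,
                      case.fixed_labels, warped_labels).as_dict()
print(f"DICE {before['DICE']:.3f} -> {after['DICE']:.3f}, "
      f"RMSE {before['RMSE']:.4f} -> {after['RMSE']:.4f}")
```

Output (about a minute on one CPU):

```
total loss 0.708 -> 0.048
DICE 0.298 -> 0.840, RMSE 0.0879 -> 0.0292
```

The first logged step already reflects the untrained identity cascade
(its loss is the coarse plus fine dissimilarity of the raw pair) and the
total drops by an order of magnitude as the model learns; the mean organ
overlap (DICE) of the held-out pair rises from 0.30 to 0.84 and the
intensity error (RMSE) falls to a third of its starting value — the
phantom deformation has been substantially recovered.

The same pipeline is scriptable from the shell:

```bash
cascadereg simulate --out sim/ --seed 3          # phantom pair + GT field
cascadereg train --config train.yaml --out run/  # loss log + test metrics
cascadereg evaluate --fixed sim/fixed.nii.gz --warped sim/moving.nii.gz \
    --fixed-labels sim/fixed_labels.nii.gz \
    --warped-labels sim/moving_labels.nii.gz --out report.csv
cascadereg ablate --n-values 0,1,3 --out ablation/
```

Evaluation reports nine indices per case: RMSE, PSNR, global SSIM over the
intensity volumes; DICE, IOU, sensitivity, specificity, Hausdorff distance
(mm) and contour distance (mm) over the organ masks.

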