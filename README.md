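# perifw — peritumoral free-water patch classification

`perifw` asks whether a brain tumor is a **glioblastoma** or a **brain
metastasis** without looking at the tumor itself. The two entities differ in
the tissue *around* the tumor: metastases are surrounded by vasogenic edema
(mostly acellular fluid), while glioblastomas infiltrate their surroundings
with tumor cells. That difference lives in the extracellular water content,
which single-shell diffusion MRI can quantify through a two-compartment
model:

    S_j = S0 [ (1 − f) exp(−b_j g_jᵀ D_t g_j) + f exp(−b_j · d_water) ]

where `f` is the **free-water volume fraction** (FW-VF) of an isotropic
compartment with fixed diffusivity `d_water = 3.0×10⁻³ mm²/s` and `D_t` is
the tissue tensor. The pipeline:

1. fit the bi-tensor model per voxel (interpolated initialization + anchored
   refinement) to produce an FW-VF map, plus conventional (FA, MD, AX, RAD)
   and free-water-corrected (FW-FA, FW-AX, FW-RAD) scalar maps;
2. sample 16×16 axial patches inside the peritumoral edema —
   `floor(edema voxels / 256)` per subject, zero tumor voxels under any
   footprint, ≤20 % overlap with healthy brain, shift augmentation;
3. classify patches with a compact six-convolution CNN (global average
   pooling + softmax, RMSprop / cross-entropy), or with Gabor / radiomic
   features + PCA(98 %) + random forest as baselines;
4. label each subject by **majority vote** over its patches, evaluate with
   patch-level 5-fold cross-validation and held-out subject testing, and
   compare classifiers by ROC/AUC with the DeLong test.

Real cohorts of this kind are IRB-restricted, so the package ships a
synthetic-phantom module that generates brain/tumor/edema masks, ground-truth
FW-VF fields with class-distinct texture (smooth/high for metastasis,
mottled/lower with a radial gradient for glioblastoma), and simulated DWI
with Rician noise. See `docs/methods.md` for models, parameters, and
limitations.

This is research software for method exploration on synthetic data — not a
clinical tool.

## Worked example

```python
import numpy as np
from perifw import (PhantomParams, make_phantom, simulate_dwi,
                    fit_freewater, patch_budget, sample_patches)
from perifw.experiment import subject_scalar_maps

# one glioblastoma phantom and its simulated acquisition
sub = make_phantom(PhantomParams.for_class("glioblastoma", seed=1))
dwi = simulate_dwi(sub, snr=30, seed=2)
masks = {"brain": sub.brain, "tumor": sub.tumor, "edema": sub.edema}

maps = subject_scalar_maps(dwi, masks, {"FW-VF"})
err = np.abs(maps["FW-VF"].values[sub.edema] - sub.truth_f.values[sub.edema])
print(f"edema voxels: {sub.edema.sum()}")
print(f"FW-VF MAE inside edema: {err.mean():.3f}")
print(f"patch budget: {patch_budget(sub.edema)}")
```

prints

```
edema voxels: 4719
FW-VF MAE inside edema: 0.014
patch budget: 18
```

— the free-water map recovers the ground-truth volume fraction to ~0.014
despite Rician noise at SNR 30, and this subject's edema supports 18
patches (4719 voxels / 256, rounded down).

The full experiment (cohort simulation → map fitting → patches → CNN →
cross-validation → majority-vote testing → report) runs from the command
line, one subcommand per stage:

```bash
perifw run --config exp.yaml --outdir out --seed 1     # everything
perifw simulate --outdir out --seed 1                  # or stage by stage
perifw fitmaps  --outdir out
...
```

Completed stages are skipped unless `--force` is given; every stage writes
a provenance marker (config echo, seeds, output hashes) under
`out/stages/`, and the final report lands in `out/report/report.json` with
per-map/per-classifier metric tables, ROC curves as CSV and PNG, and
per-subject vote breakdowns.

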