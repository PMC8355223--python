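# tsomt — two-stage optimal mass transport of brain MRI volumes to cubes

Volumetric segmentation networks want a dense regular tensor, but a brain
occupies only ~12–20% of an MRI scan cuboid, and cropping or tiling wastes
capacity on air and destroys global context.  `tsomt` transports the whole
brain onto a regular `n³` cube (default 128³) with **local mass
preservation** and **minimal deformation**, and converts cube-space
predictions back to the brain grid — the preprocessing/postprocessing pair
around a 3D U-Net-style segmenter.

The method composes two discrete optimal-mass-transport (OMT) maps.  The
brain, meshed as a tetrahedral complex (M, ρ) normalized to volume 4π/3 and
carrying a grayscale-derived density ρ(v) = exp(φ(v)) ∈ [1, e], is mapped to
the unit ball by minimizing the transport cost

    T_c(f) = Σ_v ‖v − f(v)‖² m_ρ(v),    subject to ρ(τ)|τ| = |f(τ)|,

via a spherical area-preserving boundary solve (alternating hemisphere
relaxations of an area-weighted Laplacian in the stereographic plane)
followed by a homotopy continuation of the interior (mass-weighted
cotangent Laplacian solves along g_t = (1−t)v + t·g, t = k/p).  A
case-independent cube→ball map (constant density δ ≡ 1) is precomputed
once; the composition f*_δ⁻¹ ∘ f*_ρ carries the brain onto the cube.
Because ρ is boosted by histogram equalization where tumor tissue is bright
(FLAIR), tumor voxels claim a proportionally larger share of the cube,
rebalancing the classes a segmenter trains on.

Quality is verified by the transport cost, the total mass-measure
distortion D_M, the per-vertex stretch ratio R_M (1 = perfect local mass
preservation), the bijectivity rate (percentage of unfolded tetrahedra) and
the conversion loss (1 − Dice after a forward/inverse round trip);
segmentation outputs are scored by Dice, sensitivity, specificity and HD95.
See `docs/methods.md` for the full model, solver and mesh-processing
details.

## Worked example

Everything is testable without data downloads via the built-in phantom
generator (a genus-zero brain-like solid, four MRI-style modalities, nested
WT ⊇ TC ⊇ ET tumor labels):

```python
import numpy as np
from tsomt import (PhantomSpec, make_phantom, build_case_map,
                   forward_resample, inverse_labels,
                   transport_cost, total_distortion, stretch_ratio,
                   bijectivity, conversion_loss)
from tsomt.metrics import class_mask

gray, labels = make_phantom(PhantomSpec(seed=0))     # 64³, 4 modalities
case = build_case_map(gray, labels)                  # mesh + both OMT stages

print(f"transport cost  T_c = {transport_cost(case.tmap.stage1):.4f}")
print(f"distortion      D_M = {total_distortion(case.tmap.stage1):.4f}")
comp = case.tmap.composed_image()                    # brain -> cube images
_, mean, sd = stretch_ratio(case.tmap.stage1.mesh, case.density, comp)
folded, rate = bijectivity(case.tmap.stage1.mesh, comp)
print(f"stretch ratio   mean = {mean:.4f}, SD = {sd:.4f}")
print(f"bijectivity     {rate:.2f}% ({folded} folded tets)")

cube = forward_resample(case.phi, case.labels, case.tmap, n=128)
back = inverse_labels(cube.labels, case.tmap, labels.shape, case.mask)
wt_loss = conversion_loss(class_mask(labels, "WT"), class_mask(back, "WT"))
print(f"cube WT share   {100*(cube.labels > 0).mean():.2f}% "
      f"(brain: {100*(labels > 0).sum()/case.mask.sum():.2f}%)")
print(f"WT conversion loss after round trip: {100*wt_loss:.3f}%")
```

Output:

```
transport cost  T_c = 0.1720
distortion      D_M = 0.0234
stretch ratio   mean = 1.0100, SD = 0.0612
bijectivity     99.99% (4 folded tets)
cube WT share   11.62% (brain: 6.95%)
WT conversion loss after round trip: 0.000%
```

The stretch-ratio mean sits at 1 with a small spread — the composed map
preserves local mass — and the histogram-equalized density roughly doubles
the tumor's share of the cube.  At phantom scale every brain voxel receives
many pulled-back cube centres, so the round-trip label loss is zero; on
full-resolution clinical volumes (~1.5 centres per voxel) it is sub-percent.

The same pipeline is scriptable from the shell:

```bash
tsomt phantom --seed 1 --size 64 --out case
tsomt forward --case case_image.nii.gz --labels case_labels.nii.gz \
      --n 128 --out case
tsomt inverse --cube-labels case_cube.npz --map case_map.npz --out back.npz
tsomt metrics --pred back.npz --truth back.npz --report report.json
```

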