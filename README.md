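# microglia3d

Quantifying retinal microglia in 3D from multi-channel confocal z-stacks.

Microglia — the resident immune cells of the retina and CNS — shift from a
ramified, surveillant morphology toward an amoeboid, phagocytic one as they
activate.  This package implements a complete, reproducible pipeline for
measuring that shift from IBA-1 / CD68 dual-labelled wholemount imagery:

1. **Voxel classification** — a three-class random forest
   (microglia / vasculature / background) over a multi-scale filter bank
   (Gaussian smoothing, Laplacian of Gaussian, gradient magnitude,
   difference of Gaussians, structure-tensor and Hessian eigenvalues at
   sigmas 0.3–10), trained from sparse expert annotations.
2. **Instance segmentation** — Gaussian smoothing of the microglia
   probability (σ = 1), Otsu thresholding, exclusion of high-probability
   vessel voxels (vessels fluoresce in the IBA-1 channel), Sobel-elevation
   watershed with distance-transform markers, a physical size filter and an
   optional expert QC pass.
3. **Morphometry** — per cell: volume `V`, convex-hull volume `V_H`,
   solidity `V / V_H`, and on the z-projection: area `A`, perimeter `P`,
   hull area/perimeter `A_H`, `P_H`, solidity `A / A_H`, convexity
   `P_H / P`, circularity `4πA / P²`, and the minor/major axes of the
   moment-equivalent ellipse with axis ratio `b / a`; per stack: count
   densities in count/mm² and count/mm³.
4. **CD68 colocalization** — per-cell lysosomal (CD68) volume, the
   CD68 : IBA-1 volume ratio, CD68± status and the per-stack CD68+
   proportion.
5. **Group statistics** — Shapiro–Wilk-gated Student's *t* vs Mann–Whitney
   *U* (exact by enumeration for small samples), and two-way ANOVA
   (Type-II SS) with Bonferroni-corrected pairwise contrasts for
   group × CD68 designs; mean ± SEM reporting with the usual star
   convention.

A synthetic scene generator (`microglia3d.synthetic`) renders two-channel
stacks of soma-plus-processes cells spanning the ramified↔amoeboid spectrum,
with vessels, PSF blur, Poisson/read noise and **exact voxel-level ground
truth**, so every stage is testable without donor data.  See
`docs/methods.md` for the models, conventions and their limits.

## Worked example

```python
import numpy as np
from microglia3d import (control_params, ad_params, generate_scene,
                         render_stack, annotate_scene, train_classifier)
from microglia3d.segment import segment_stack
from microglia3d.morphometry import measure_labels
from microglia3d.stats import two_sample_test

# a control scene: 30 cells, mean volume 1085 um^3, two vessels, known truth
scene = generate_scene(control_params(), seed=1)
stack, truth = render_stack(scene)

labels = annotate_scene(truth, n_per_class=400, seed=7)   # sparse "expert" strokes
clf = train_classifier(stack.channel(0), labels, seed=0)

pmap = clf.predict_probabilities(stack.channel(0))
seg = segment_stack(pmap)                                  # smooth->Otsu->vessels->watershed->size
records = measure_labels(seg.labels)

vols = np.array([r.volume_um3 for r in records])
print(f"{seg.labels.n_labels} cells detected (true: {truth.n_cells})")
print(f"mean volume {vols.mean():.0f} um^3; "
      f"mean solidity {np.mean([r.solidity_3d for r in records]):.2f}")
```

prints (seed 1):

```
30 cells detected (true: 30)
mean volume 1009 um^3; mean solidity 0.34
```

— the watershed chain recovered all 30 cells, the detected mean volume is
within ~3% of the scene's true voxelized mean (1039 µm³; 1085 µm³ was
requested of the generator), and solidity ≈ 0.34 reflects a mixed
ramified/amoeboid population (1.0 would be a perfectly convex, amoeboid
cell).  Comparing two such groups end-to-end:

```python
ad_stack, ad_truth = render_stack(generate_scene(ad_params(), seed=2))
# ... classify + segment as above, then:
res = two_sample_test(control_volumes, ad_volumes)
print(res.test_name, res.p_value, res.stars)
```

selects the test via the normality gate and reports the branch, p-value and
significance stars.

The same stages are scriptable from the shell via the `microglia3d` CLI
(`simulate`, `train`, `segment`, `measure`, `stats`, `run-all`), each verb
consuming the previous stage's serialized outputs (OME-TIFF stacks, label
TIFFs, tidy CSVs, a JSON run manifest).

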