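# fwtract

Single-shell free-water elimination tractometry of white-matter bundles, and
its association with longitudinal cognitive decline — as a fully synthetic,
fully testable pipeline.

## The problem

Diffusion-tensor measures of white matter (FA, MD, RD, AD) are contaminated
by freely diffusing extracellular water: cerebrospinal fluid at bundle
borders and enlarged interstitial space in the aging brain. A voxel
containing a fraction *f* of free water looks more isotropic and more
diffusive than its tissue really is. Free-water elimination (FWE) fits a
two-compartment bi-tensor model per voxel,

    S(b, g) = S0 · [ (1 − f) · exp(−b gᵀ D g) + f · exp(−b · d_iso) ],

with the free-water diffusivity fixed at d_iso = 3×10⁻³ mm²/s (water at body
temperature), and reports the tissue-compartment scalars FAt, MDt, RDt, ADt
plus the free-water map *f* ∈ [0, 1]. In elderly cohorts these corrected
measures of the cingulum bundle — and the free-water content itself — track
the decline of verbal fluency over years of follow-up.

Real cohort data of this kind are not public. `fwtract` therefore ships a
synthetic-data module that emulates every input with planted ground truth —
single-shell diffusion signals (1–2 b0 + 21 half-sphere directions + 21
antipodes per series at b = 1000 s/mm², Rician noise), bundle/lesion/tissue
masks, longitudinal Isaacs Set Test (IST) trajectories with random
intercepts and slopes, and screening funnels — so every stage of the
analysis is verifiable end to end:

1. **tensor_model** — weighted log-linear single-tensor fit; FA/MD/RD/AD.
2. **free_water_model** — per-voxel bounded nonlinear least squares for
   (f, D); FAt/MDt/RDt/ADt and the FW map.
3. **tract_metrics** — bundle-mask aggregation, percent change
   ((corrected − conventional)/conventional × 100), lesion volumetrics.
4. **longitudinal_slopes** — REML linear mixed model (random intercept +
   slope); per-subject slope = fixed slope + BLUP.
5. **association** — Spearman/Mann-Whitney screens, paired t contrasts,
   standardized-β regressions adjusted for age and bundle volume (optionally
   lesion load; joint FW + MDt model), Benjamini–Hochberg FDR per family.

## Worked example

Simulate one noise-free cingulum-like voxel at the healthy-elderly operating
point (tissue FA 0.567, tissue MD 0.755×10⁻³ mm²/s, free-water fraction
0.141) and fit both models:

```python
import numpy as np
from fwtract import (make_gradient_scheme, tensor_from_scalars, VoxelModel,
                     simulate_bitensor_signal, fit_single_tensor, fit_bitensor)
from fwtract.synthetic import _axially_symmetric_tensor

scheme = make_gradient_scheme(n_dirs_half=21, bvalue=1000.0, n_series=2)
lam = tensor_from_scalars(fa=0.567, md=0.755e-3)
tissue = _axially_symmetric_tensor(lam, axis=np.array([0.0, 1.0, 0.0]))
voxel = VoxelModel(tissue_tensor=tissue, fw_fraction=0.141, s0=1000.0)
signal = simulate_bitensor_signal(voxel, scheme)

conv = fit_single_tensor(signal, scheme)
fwe = fit_bitensor(signal, scheme)
print(f"conventional: FA={conv.fa[0]:.3f}  MD={conv.md[0]*1e3:.3f}e-3 mm^2/s")
print(f"fw-corrected: FAt={fwe.fat[0]:.3f}  MDt={fwe.mdt[0]*1e3:.3f}e-3 mm^2/s  FW={fwe.fw_fraction[0]:.3f}")
```

prints

```
conventional: FA=0.489  MD=0.889e-3 mm^2/s
fw-corrected: FAt=0.567  MDt=0.755e-3 mm^2/s  FW=0.141
```

The conventional tensor sees the water-contaminated voxel as less
anisotropic (0.489 < 0.567) and more diffusive (0.889 > 0.755); the
bi-tensor fit removes the 14.1% free-water compartment and returns the
planted tissue values exactly — noise-free single-shell recovery is exact
for anisotropic tissue.

The full chain runs from one config:

```sh
fwtract run-all --seed 1 --out run1        # or: fwtract simulate / fit-dti /
                                           # fit-fw / tract-metrics / slopes /
                                           # associate for single stages
```

which writes per-subject NIfTI maps, a tract-measure CSV, slope CSV,
paired-contrast and regression results CSVs, and a manifest with every seed
and per-stage wall time.

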