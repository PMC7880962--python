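# radbatch

**CT-radiomics variability screening and batch-effect harmonization, at desk scale.**

Radiomics features extracted from CT scans depend not only on the imaged
tissue but on how the scan was acquired and reconstructed: pixel size, slice
spacing, slice thickness, reconstruction kernel, tube voltage and current all
perturb the 93 standard first-order and texture features. In multicenter
studies these acquisition differences act as *batch effects* that can swamp
the biological signal. `radbatch` implements the complete workflow for
quantifying and removing that variability:

1. **Simulate** a digital tissue-characterization phantom (13 cylindrical
   rods of tissue-equivalent densities, lung through cortical bone) imaged
   under controlled acquisition protocols — z-averaging over the slice
   thickness, grid resampling, kernel point-spread functions, voltage
   contrast scaling, and mAs-dependent noise.
2. **Extract** the standard 93-feature battery from each rod VOI: 18
   first-order statistics plus five 3D texture-matrix families (GLCM 24,
   GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5), after resampling to isotropic
   1 mm voxels (cubic B-spline / nearest neighbor) and fixed-bin-width
   discretization at 50 HU.
3. **Screen** per-feature reproducibility between protocol pairs with the
   intraclass correlation coefficient — two-way random effects, absolute
   agreement, single measurement, ICC(2,1):

   `ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)`

   A feature is *robust* for a pair when ICC > 0.8; an acquisition variable
   becomes a *batch* when any of its pairs leaves < 80% of features robust.
   Robust proportions before/after correction are compared with a
   continuity-corrected two-proportion test, FDR-controlled per factor
   (Benjamini–Hochberg).
4. **Harmonize** feature tables with parametric empirical-Bayes ComBat
   (`Y = α_g + γ_ig + δ_ig·ε`, normal prior on the additive effects γ,
   inverse-gamma on the squared scale effects δ²) or with SVD-based
   correction (remove principal components whose scores associate with
   batch labels at p < 0.001, reconstruct).
5. **Validate** with repeated K-means clustering purity: 1000 random
   restarts, each cluster scored by its majority class, and the highest
   purity attained in more than 20% of the iterations reported.

## Worked example

```python
import numpy as np
import radbatch as rb
from radbatch.synthetic import rasterize_rod_masks
from radbatch.features import FEATURE_NAMES

truth, masks, layout = rb.make_phantom_truth(seed=1)
sharp = rb.AcquisitionProtocol(kernel_id="D", slice_thickness=5.0)
soft = rb.AcquisitionProtocol(kernel_id="A", slice_thickness=5.0)

import pandas as pd
rows = []
for proto in (soft, sharp):
    acq = rb.simulate_acquisition(truth, proto, seed=2)
    for mat, mask in zip(rb.GAMMEX_MATERIALS, rasterize_rod_masks(layout, acq)):
        feats = rb.extract_all(acq, mask, bin_width=50, target=1.0)
        rows.append({"material": mat.material_id, "protocol": proto.kernel_id, **feats})
table = pd.DataFrame(rows)

rep = rb.icc_pairwise(table, "A", "D", list(FEATURE_NAMES),
                      protocol_col="protocol", subject_col="material")
print(f"robust features A vs D: {rep.robust_count}/93 ({rep.robust_fraction:.2f}%)")
```

prints

```
robust features A vs D: 27/93 (29.03%)
```

— i.e. switching between the softest and a sharp reconstruction kernel
leaves only ~29% of the 93 features with ICC > 0.8 across the 13 materials,
well under the 80% rule, so the kernel is flagged as a batch. The same
screening after harmonization shows the recovery; the full study (sweeps
over all six acquisition variables, before/after resampling, ComBat/SVD
correction and purity validation) runs from one config:

```bash
radbatch run --config examples/study.yaml --out runs/exp1 --seed 17
```

## Layout

| module | contents |
|---|---|
| `radbatch.synthetic` | digital phantom, acquisition simulator, clinical-cohort generator |
| `radbatch.image_io` | NRRD/NIfTI I/O, isotropic resampling, HU discretization |
| `radbatch.features` | the 93-feature extractor (first-order + 5 texture families) |
| `radbatch.robustness` | ICC(2,1), the 80% batch rule, proportion tests, BH |
| `radbatch.harmonization` | parametric/nonparametric ComBat, SVD correction |
| `radbatch.evaluation` | clustering purity, frequency rule, PCA diagnostics |
| `radbatch.pipeline` / `radbatch.cli` | config-driven orchestration, `radbatch` CLI |

See `docs/methods.md` for the models, conventions and their rationale.
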