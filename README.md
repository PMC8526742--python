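# ablaquant

Quantification of ethanol-based chemical ablation zones from CT imaging and
stained histology.

Ethanol ablation destroys tissue (e.g. liver tumors) by intratumoral
injection of concentrated ethanol; adding ethyl cellulose (EC), a polymer
that gels on contact with tissue water, localizes the injectate. Because
ethanol attenuates X-rays less than water, CT can both *see* the injectate
and estimate its local concentration. `ablaquant` implements the full
radiologic–pathologic quantification chain:

1. **Calibration** — a two-point map from radiodensity (HU) to estimated
   ethanol fraction,

   *c*(HU) = (HU − HU₀) / (HU₁₀₀ − HU₀),

   where HU₀ and HU₁₀₀ are the radiodensities of the 0% and 100% ethanol
   standards (water or mean pre-ablation tissue, and pure ethanol). The
   module also quantifies the two calibration error components: systematic
   error from residual non-linearity at intermediate concentrations, and
   random error from the radiodensity spread of homogeneous samples.
2. **CT volumetrics** — the cytotoxic *distribution volume* is the tissue
   volume with estimated concentration ≥ 20% (a 10-minute exposure to 20%
   ethanol is cytotoxic); an optional upper cut at 120% removes air-bubble
   artifacts. Shape is summarized by the aspect ratio

   AR = (Σ distance-to-centroid / N) / (3V/4π)^(1/3),

   the mean voxel distance to the centroid over the radius of an
   equal-volume sphere. Note the numerator is the arithmetic mean distance
   (a uniform solid sphere scores 0.75 under this convention, exposed as
   `SPHERE_ASPECT_RATIO`). Cumulative volume histograms and maximum
   concentration projections complete the picture.
3. **Histology** — necrotic area on NADH-diaphorase-stained serial sections
   (viable tissue stains blue; necrosis is unstained): entropy-filter tissue
   segmentation, low-blue necrosis segmentation with minimum-size and
   five-largest-region rules, and serial-section reconstruction
   V = Σ areaᵢ · step.
4. **Correlation** — per-sample necrosis-to-distribution ratios, group
   mean/sd, and between-group fold-changes.

A seeded synthetic-data module generates vial panels, CT injection phantoms
and stained slide series with analytic ground truth, standing in for animal
data.

## Worked example

```python
import numpy as np
from ablaquant import fit_two_point, to_concentration, segment_distribution
from ablaquant.synthetic import (TISSUE_HU, ETHANOL_HU, Inclusion,
                                 InjectionPhantomSpec, make_injection_phantom)

spec = InjectionPhantomSpec(
    inclusions=(Inclusion(center_mm=(16, 16, 16), radii_mm=(2.5, 2, 2),
                          concentration=0.6),))
ct, tissue, truth = make_injection_phantom(spec)

model = fit_two_point(TISSUE_HU, ETHANOL_HU)       # 0% = tissue, 100% = ethanol
conc = to_concentration(ct, model, tissue)
dist = segment_distribution(conc, lower=0.20)
print(f"volume {dist.volume_ul:.1f} µL  (truth {truth.rasterized_volume_ul:.1f})")
print(f"aspect ratio {dist.aspect_ratio:.3f}  components {dist.n_components}")
```

prints

```
volume 43.4 µL  (truth 43.4)
aspect ratio 0.758  components 1
```

The noise-free 60%-ethanol ellipsoid (analytic volume 41.9 µL) is recovered
exactly at the 20% threshold — the 1.5 µL gap to the analytic value is
rasterization at 0.5 mm voxels — and its aspect ratio sits near the solid
sphere reference of 0.75, indicating a compact, localized distribution.

The same stages are available from the shell:

```bash
ablaquant simulate phantom --seed 5 --out ph/
ablaquant quantify-ct --post ph/phantom.nii.gz --tissue-mask ph/tissue_mask.nii.gz \
    --hu-zero 60 --ethanol-standard -340.3 --out results/
ablaquant simulate slides --seed 5 --out sl/
ablaquant quantify-histology --slides sl/ --pixel-size 25 --out results/
```

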