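# ramansizer

Particle sizing of active pharmaceutical ingredients (APIs) inside tablets
from Raman chemical images — for formulation scientists who need to know
whether processing changed the drug's particle size in the finished dosage
form, where powder-based sizing techniques no longer apply.

A Raman map of a tablet cross-section (a spectrum per pixel on a regular
grid) is turned into a particle size estimate in four steps:

1. Savitzky–Golay second-derivative preprocessing of every pixel spectrum
   (31-point window, cubic), removing baseline and enhancing contrast;
2. a univariate band image at a component-specific wavenumber (1,605 cm⁻¹
   for polystyrene size standards, 1,601 cm⁻¹ for ebastine), sign-flipped
   so particle pixels are bright;
3. binarization at the threshold *t* = mean + *k*·σ of the image's
   intensity histogram (*k* = 0.5 validated), pixels ≥ *t* being object;
4. connected-component labelling and equivalent circular diameters
   *d* = 2·√(A/π), pooled across analysis areas with particle-count
   weights.

The calibration workflow validates the threshold with *model tablets*:
tablets manufactured with NIST-traceable polystyrene microspheres
(4.9 / 9.8 / 15.8 µm) in place of the API. Per-standard recovery
(100 × post/pre) and the OLS regression of post- on pre-formulation mean
diameters quantify threshold quality; *k* = 0.5 gives slope ≈ 1.02.

A synthetic phantom generator (`ramansizer.phantom`) emulates the whole
experiment — spherical particles with an isolated Raman band embedded in a
patchy multi-component excipient matrix with baseline drift and noise —
with exact ground truth, so every stage is testable without instrument
data.

## Worked example

Simulate three analysis areas of a model tablet with 9.8 µm spheres and
size them:

```python
import numpy as np
from ramansizer import phantom, size_areas
from ramansizer.phantom import truth_section_summary

maps, truths = [], []
for area in range(3):
    spec = phantom.preset("ps10", seed=100 + area, thin_axis=True)
    hmap, truth = phantom.generate(spec)
    maps.append(hmap)
    truths.append(truth_section_summary(truth).mean_diameter)

pooled = size_areas(maps, band=1605.0, k=0.5)
print(f"pooled mean {pooled.pooled_mean:.2f} um "
      f"({pooled.total_particles} particles, "
      f"area {pooled.pooled_area_percent:.1f}%)")
print(f"truth mean  {np.mean(truths):.2f} um")
```

prints

```
pooled mean 9.70 um (47 particles, area 11.8%)
truth mean  9.80 um
```

— the pipeline recovers the true mean diameter to ~1 % here. The object
area (11.8 %) sits slightly below the true disk coverage (12 %) because a
sphere's Raman response fades toward its rim and the mean + 0.5σ threshold
trims the faintest rim pixels. The same
chain runs from the shell:

```bash
ramansizer simulate --preset ps10 --seed 7 --thin-axis --out map.h5 --truth truth.json
ramansizer size --wavenumber 1605 --k 0.5 --out results/ map.h5
ramansizer sweep --band 1605 --ks 0,0.5,1.0,1.5 \
    --map ps10=map.h5 --pre ps10=9.8 --out sweep/
```

Pooling the published per-area model-tablet results reproduces the printed
pooled means and recoveries exactly:

```python
from ramansizer import pool_areas, recovery
from ramansizer.datasets import model_tablet_summaries

pooled = pool_areas(model_tablet_summaries("ps5"))
print(round(pooled.pooled_mean, 2), round(recovery(6.30, pooled.pooled_mean), 1))
# 6.2 98.4
```

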