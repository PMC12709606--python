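# slscgcnr

Coherence-based ultrasound classification of complicated breast cysts
vs solid masses: short-lag spatial coherence (SLSC) beamforming, gCNR
lesion scoring, and the multi-reader diagnostic-accuracy statistics
that go with them — plus a synthetic RF channel-data and reader-panel
generator, so the whole pipeline runs and is tested without any
clinical data.

## The problem

Complicated cysts (benign, fluid with internal debris) often mimic
hypoechoic solid masses on B-mode ultrasound because acoustic clutter
fills the anechoic interior with speckle-like texture. The result is
unnecessary follow-up and biopsy. Amplitude imaging cannot reliably
separate the two — but *spatial coherence* can: echoes from solid
tissue stay coherent across the receive aperture (the van
Cittert-Zernike triangle `R(m) ≈ 1 − m/N` for diffuse scattering),
while clutter inside a fluid cavity is largely incoherent.

The pipeline implemented here:

1. **SLSC beamforming.** From focused RF channel data, each pixel is
   the short-lag coherence sum `Σ_{m=1..M} R̂(m)` with
   `R̂(m)` the normalized correlation of element pairs at lag `m`
   over a one-pulse-length axial kernel; `M = 7` (10% of the
   64-element aperture), negative values truncated, full linear scale.
   B-mode (delay-and-sum envelope) is formed from the same data.
2. **gCNR scoring.** For a mass ROI and an automatically placed
   equal-area, same-depth tissue ROI, `gCNR = 1 − Σ_b min(p_mass(b),
   p_tissue(b))` over a shared histogram — the overlap of the two
   pixel-value distributions, invariant to any monotone remapping of
   pixel values.
3. **Threshold classification.** A mass is called *fluid* when its
   SLSC gCNR is at or above 0.76 (within the acceptable range
   0.62–0.85), *solid* otherwise.
4. **Reader statistics.** Trapezoidal ROC/AUC (equal to the
   Mann-Whitney statistic), 1000-iteration percentile bootstrap CIs,
   lower-bound AUC `(sens + spec)/2` for single reader operating
   points, DeLong's paired test, and Fleiss' κ with large-sample
   variance, z and P plus the standard interpretation bands
   (fair 0.21–0.40, moderate 0.41–0.60, substantial 0.61–0.80, ...).

See `docs/methods.md` for the models, estimators, default parameters
and limitations.

## Worked example

Simulate, beamform and score one cluttered complicated cyst and one
solid mass (identical geometry, same seed):

```python
from slscgcnr import (LesionSpec, ImagingConfig, image_and_score_mass,
                      classify_mass, ClassifierParams)

cyst = LesionSpec(center=(0.0, 15e-3), radius=1.75e-3, content="fluid",
                  echogenicity=0.0, clutter_level=2.5)
solid = LesionSpec(center=(0.0, 15e-3), radius=1.75e-3, content="solid",
                   echogenicity=0.5, clutter_level=0.0)
params = ClassifierParams(threshold=0.76)
for name, lesion in [("complicated cyst", cyst), ("solid mass", solid)]:
    res = image_and_score_mass(lesion, ImagingConfig(), seed=42)
    call = classify_mass(res.gcnr_slsc, params)
    print(f"{name:16s}  gCNR(B-mode) = {res.gcnr_bmode:.2f}   "
          f"gCNR(SLSC) = {res.gcnr_slsc:.2f}   -> called {call}")
```

prints

```
complicated cyst  gCNR(B-mode) = 0.58   gCNR(SLSC) = 1.00   -> called fluid
solid mass        gCNR(B-mode) = 0.41   gCNR(SLSC) = 0.30   -> called solid
```

On B-mode the two lesions are nearly indistinguishable (clutter fills
the cyst to solid-like contrast); on the coherence image the cyst's
interior is incoherent and separates cleanly, so the 0.76 threshold
classifies both correctly.

The full study pipeline — cohort simulation, eligibility filtering
(175 → 145 eligible → 112 analysis masses), per-reader scoring, ROC,
bootstrap, DeLong, κ tables and the threshold-tradeoff report — runs
from one config:

```bash
slscgcnr run --seed 1 --out results/study
```

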