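# Methods

This note documents the models, estimators and design choices behind
`slscgcnr`, and what its synthetic experiments can and cannot show
about clinical data.

## The classification problem

Complicated breast cysts (fluid with internal debris) and hypoechoic
solid masses can look alike on conventional B-mode ultrasound because
acoustic clutter fills the anechoic cyst interior with speckle-like
texture. Amplitude imaging therefore separates the two classes poorly.
Spatial coherence separates them well: echoes from solid tissue are
spatially coherent across the receive aperture, while the clutter that
fills a fluid cavity is largely incoherent. The package implements the
full decision pipeline: short-lag spatial coherence (SLSC) beamforming,
gCNR scoring of a mass ROI against a same-depth tissue ROI, a fixed
gCNR threshold for the fluid/solid call, and the multi-reader
statistics used to compare that objective call against subjective
readings.

## RF channel-data model

The simulator is a single-scattering, attenuation-free point-scatterer
model with a per-line fixed transmit focus:

- **Transmit.** The beam for the line at lateral position `x_l` is an
  idealized diffraction-limited focused beam: arrival time at a
  scatterer `(x, z)` is `z / c` (planar phase along the beam axis), and
  the lateral field amplitude is `sinc(D (x - x_l) / (lambda z))` with
  `D` the aperture width — the far-field pattern of a uniform aperture,
  evaluated at every depth (constant f-number). The profile is
  truncated beyond 4 sinc lobes, which keeps >95% of the beam energy
  and makes the per-line cost proportional to a narrow scatterer strip.
- **Receive.** Element `i` records a Gaussian-windowed tone at the
  centre frequency (envelope FWHM = `pulse_cycles` periods, default 2),
  delayed by `(z + sqrt((x - e_i)^2 + z^2)) / c` and weighted by
  spherical spreading `1/r`. Delays are geometrically exact, so dynamic
  receive focusing aligns echoes exactly and the spatial-coherence
  behaviour of the aperture is physical rather than prescribed: for
  diffuse scattering the simulated coherence follows the van
  Cittert-Zernike triangle `1 - m/N` (verified to within 0.1 absolute
  in the tests, lags 1-10).
- **Clutter.** Each lesion may inject band-limited Gaussian noise into
  the channel signals, gated to the time samples whose round-trip depth
  lies inside the lesion on lines whose beam crosses it. The noise is a
  variance mixture of an element-shared component and element-independent
  components (`correlated_fraction`, default 0.5). Purely independent
  noise would be removed almost perfectly by coherence imaging; the
  shared component is what lets clutter partially survive, as it does
  in vivo. Clutter amplitude is expressed relative to the RMS of the
  clean background channel signals. No clinical characterization of
  complicated-cyst clutter statistics exists, so the correlated
  fraction is this package's construct.

Default geometry: 64 active elements, 0.3 mm pitch, 8 MHz centre
frequency, 40 MHz RF sampling, 1540 m/s, 20 mm transmit focus —
plausible for the high-frequency linear probes used in breast imaging.
All values are configurable.

### Speckle statistics

Fully developed Rayleigh speckle requires many scatterers per
resolution cell. With this geometry the two-way resolution cell is
roughly 0.2 x 0.2 mm, so the speckle-statistics tests use 1500
scatterers/mm^2, at which the envelope SNR reaches the Rayleigh value
1.91 and a Kolmogorov-Smirnov test on 10^4 thinned, depth-normalized
pixels accepts the Rayleigh hypothesis at alpha = 0.01. The per-mass
imaging pipeline uses 200/mm^2 for tractability; its speckle is
slightly under-developed (envelope SNR ~1.7), which broadens gCNR
estimates a little but does not affect the contrast ordering the
pipeline measures.

## Beamforming

Both images are formed from the same dynamically focused aperture
signals, one lateral column per scan line, axial sampling at the RF
rate divided by the decimation factor (4 by default, 2 in the per-mass
pipeline for more ROI pixels):

- **B-mode**: envelope (magnitude of the axial analytic signal) of the
  uniformly apodized across-element sum; log-compressed only for
  display.
- **SLSC**: pixel value `sum_{m=1..M} R_hat(m)` where `R_hat(m)` is
  the average normalized correlation of element pairs at lag `m`,
  estimated over an axial kernel of one pulse length (10 RF samples at
  the default 40 MHz / 8 MHz). `M = 7` (10% of the 64-element
  aperture). Negative values are truncated after the lag sum and the
  image kept on the full linear scale; per-lag truncation is available
  as an option but not default. Element pairs with zero energy in the
  kernel are excluded from the average rather than contributing zero.

## gCNR and threshold classification

gCNR = 1 − OVL, with OVL the overlap of the two ROI histograms on a
shared grid spanning the pooled min-max range (256 bins by default).
It is invariant to any strictly increasing remapping of pixel values
up to discretization, which is what makes scores comparable between
amplitude and coherence images; the tests verify linear-vs-log
agreement within 0.02 at 256 bins on large speckle ROIs.

Estimation caveat: with finitely many pixels the empirical OVL is
biased low (gCNR biased high), increasingly so as bins approach the
pixel count. The per-mass pipeline therefore uses 32 bins for its
~300-pixel ROIs; identical distributions then score a gCNR noise floor
of roughly 0.1-0.2 rather than 0.

The tissue ROI is placed automatically: the mass ROI translated
laterally (to the side with more room) by its width plus a margin, so
the pair is equal-area, same-depth and disjoint by construction. A
mass is called **fluid** when its gCNR is at or above the threshold
(0.76 by default, within the acceptable range 0.62-0.85) and **solid**
otherwise; an exact tie is called fluid, a choice the printed examples
do not constrain (the one near-threshold example, 0.75 vs 0.76, is
strictly below).

## Cohort model

The synthetic cohort mirrors the composition of the emulated study:
175 potentially eligible masses, 30 excluded for itemized reasons
(hyperechoic content 2, unknown content 16, incomplete follow-up 2, no
screenshots 2, superficial 4, not in field of view 4), 145 eligible
(16 complicated cysts, 11 simple cysts, 22 mixed, 71 benign + 25
malignant solid). The statistical subgroup removes mixed masses (they
contain both classes) and simple cysts (confidently classified from
B-mode features alone), leaving 112 masses with 16 fluid positives and
96 solid negatives. Exclusion reasons are generator-assigned record
attributes; the filters implement the accounting, not the image-based
diagnosis of the reasons.

Two generative routes produce gCNR scores:

1. **Statistics-only**: per-category truncated-normal distributions per
   imaging arm (defaults encode high fluid / low solid scores on SLSC
   and compressed separation on B-mode). Used for fast statistical
   tests and for calibration checks against the closed-form binormal
   AUC `Phi(dmu / sqrt(s1^2 + s2^2))`.
2. **Imaging**: every mass is independently simulated, beamformed and
   scored. Per-category lesion models: complicated cysts are anechoic
   with clutter level uniform in [1, 4] (their clinical hallmark is
   exactly this variability), simple cysts anechoic with clutter in
   [0, 0.5], solid masses have echogenicity uniform in [0.3, 0.7] with
   clutter in [0, 0.1] (their own backscatter dominates).

Reader behaviour is modelled twice: categorical content ratings
(solid/fluid/mixed/uncertain) from a truth-conditioned multinomial
with a shared-latent coupling parameter that tunes inter-reader
agreement, and per-reader gCNR scores as the mass's latent score plus
N(0, 0.05) ROI-variability noise, clipped to [0, 1].

## Statistics

- **ROC/AUC**: empirical curve over the observed score values plus
  {0, 1}, call rule score >= threshold, trapezoidal integration. The
  AUC equals the Mann-Whitney statistic with ties counted 1/2
  (verified exhaustively at small n), and an O(n log n) rank
  implementation of the same quantity drives the bootstraps.
- **Bootstrap CIs**: percentile intervals from 1000 joint resamples of
  (score, label) pairs; single-class resamples are redrawn. Coverage
  calibration: at ~48 events per class the intervals cover a known
  binormal AUC in ~95/100 cohorts; with only 16 positives (the study
  subgroup size) percentile intervals under-cover slightly (~89%), a
  known small-sample property of the percentile method.
- **Lower-bound AUC**: `(sens + spec) / 2`, the area of the two-segment
  ROC through a single operating point; reader panels are summarized by
  the mean lower-bound AUC with a reader-resampling bootstrap.
- **DeLong's test**: paired placement-value (structural component)
  variance estimate, two-sided normal P. Binary reader calls enter as
  two-valued scores — how the emulated comparison paired a binary
  reading with a continuous score is not otherwise specified, so this
  documented convention is used. Degenerate zero-variance cases with a
  nonzero AUC difference are reported as P < 1e-16 with a flag.
- **Fleiss' kappa**: `(P_bar - P_e) / (1 - P_e)` over the four content
  categories (or two categories for thresholded gCNR calls), with the
  large-sample null variance for testing kappa = 0. Two published
  variance formulas are implemented: the Fleiss-Nee-Landis form
  (default) and the original large-sample form; both are available
  because the emulated analysis does not say which it used.
  Interpretation bands: poor (<0), slight (0-0.20), fair (0.21-0.40),
  moderate (0.41-0.60), substantial (0.61-0.80), perfect (>0.80); the
  published band list leaves (0.80, 0.81] unassigned and it is mapped
  to "perfect" here so the bands partition the range. If every rating
  falls in one category, kappa is undefined (P_e = 1) and reported as
  1 with a degenerate flag.
- **Kappa differences**: z on the difference with independently added
  variances. The null model provides no covariance for paired panels,
  so this is an independence approximation, flagged in the report.
  Near the null it matches a mass-resampling bootstrap z within 5%.
- Two-sided tests at alpha = 0.05 throughout; no multiple-testing
  correction is applied, matching the emulated analysis.

## Study orchestration and reproducibility

`run_study` derives every stage seed by hashing the master seed with
the stage name, records all of them in `manifest.json`, and writes
CSV/JSON reports; re-running with the same config is byte-identical.
Any stage failure removes partial outputs and raises with the stage
name. The `slscgcnr` CLI exposes the simulation, beamforming, scoring,
filtering and full-pipeline entry points.

## Problem sizes

Sizes were chosen so the whole suite runs comfortably on one CPU: the
per-mass imaging field of view is 24 lines x 5.5 mm framing a 1.75 mm
radius lesion at 12-18 mm depth with lateral room for the translated
tissue ROI; a full beamformed cohort (112 masses) takes well under a
minute, and the multi-seed comparisons use 10 (tests) or 4
(acceptance script) independent cohorts. Speckle-statistics phantoms
use 10 realizations of a 29-line field at 1500 scatterers/mm^2.

## Known limitations

- The transmit beam is idealized (no defocus away from the focal
  depth, no element directivity, no attenuation or aberration); real
  clutter also includes reverberation and off-axis anatomy that the
  band-limited noise model only approximates statistically.
- gCNR estimates from small ROIs carry an upward bias (histogram
  sparsity) that clinical ROIs, typically larger, suffer less from.
- The synthetic reader model draws conditionally independent ratings
  given a shared latent; real readers share training and systematic
  biases, so synthetic kappa values are calibration knobs, not
  predictions.
- Passing tests demonstrate internal consistency and the direction and
  rough magnitude of the coherence-vs-amplitude separation under the
  stated generative conditions; they do not certify performance on
  clinical images, which are not distributed with this package.
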