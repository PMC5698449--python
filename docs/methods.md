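# Methods

## Problem and model

`seednir` discriminates two seed populations — a wild-type rice acceptor
line and a CRISPR/Cas9 *TGW6*-knockout mutant — from near-infrared
hyperspectral images. The working assumptions, taken from how such data
behave in practice, are:

* each seed's reflectance spectrum is a smooth curve with conserved
  landmarks (a peak near 1122.81 nm; valleys near 1200.19 and 1483.46 nm,
  the C-H second-overtone and N-H first-overtone absorptions of the husk);
* the mutant class differs by a small *multiplicative* offset applied
  across the spectrum (composition changes scale reflectance rather than
  moving band positions);
* per-seed variation is dominated by multiplicative scatter (illumination
  geometry, husk surface), with additive sensor noise on top, worse at the
  spectral edges — hence the analysis window of 975–1646 nm.

The classification model is not parametric: an RBF-SVM or ELM is fitted to
per-seed mean spectra, with wavelength selection in between. The package is
organised around `SeedDiscrimination` (model over a labelled spectral
dataset) and `DiscriminationResults` (split, selected bands, classifier,
accuracies, `summary()`), with the imaging stages as library modules
underneath (`cube`, `morphology`, `spectra`, `partition`, `pca`, `bands`,
`classify`, `mapping`, `synthetic`, `workflow`).

## Synthetic scene generator

The generator (`seednir.synthetic`) emulates a push-broom acquisition of a
seed tray. What it reproduces:

* 256 uniform bands over 874.41–1733.91 nm. The emulated instrument's true
  grid is not recoverable from its nominal constants (the landmark
  wavelengths do not lie on any single uniform 256-point grid over those
  endpoints, and a nominal 5 nm resolution is inconsistent with an
  859.5 nm span over 256 channels); a uniform grid is the simplest
  self-consistent choice, and nothing downstream depends on grid details
  beyond nearest-band lookup.
* Seeds as filled, rotated ellipses with major/minor axes drawn from
  truncated normals (±3 SD, 1 px floor) using per-class mean ± SD shape
  statistics typical of such material (WT ≈ 11.20 × 5.65 px; mutant longer and
  larger in area/perimeter, width unchanged). Rotation is uniform on
  [0, π), making axis ground truth analytic.
* Raw digital numbers `dark + (white − dark) · (R + noise)` with
  `R = base(λ) · class_offset · scatter`; scatter is log-normal
  (`exp N(0, σ)`, default σ = 0.02), noise is N(0, 0.01) per pixel/band,
  inflated 4× outside 975–1646 nm to mimic detector roll-off. Reference
  frames are single noiseless lines `(cols, bands)`, as frame-averaged
  references would be.
* Placement is a jittered grid by default: cells sized for the largest
  3-SD seed plus a guaranteed 1-px gap, so hundreds of seeds pack into a
  ~500 px image deterministically with no overlap (a rejection-sampling
  `placement="random"` mode with bounded retries also exists). 660-seed
  scenes are what the accuracy studies use.

What it does **not** emulate: optics (smile/keystone, point-spread mixing
at seed boundaries), touching or overlapping seeds, within-seed spectral
texture (germ vs endosperm), wavelength-dependent class differences beyond
an optional band-restricted offset, or radiometric drift. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behaviour under the planted model — not field performance on real seed
images, where segmentation errors and subtler class structure dominate.

### Calibrated class separation

With log-normal scatter σ in both classes and log-mean separation
`ln(offset)`, the optimal single-seed rule has accuracy
`Φ(ln(offset)/2σ)`. `offset_for_bayes_accuracy(p, σ) = exp(2 Φ⁻¹(p) σ)`
inverts this; the accuracy studies use `p = 0.95`, σ = 0.02 → offset
≈ 1.068. The default `SceneSpec.class_offset` is the subtler 1.02 (a
realistic effect size for a composition-level change; deliberately below
the comfortable operating point, as real mutant/wild-type contrasts are).
A simulation test verifies the closed form.

## Numerical and design choices

* **Calibration**: references broadcast along the scan axis; denominator
  entries below `1e-6 ×` median white level become NaN with a warning
  (configurable to a hard error). Computed in float64.
* **Segmentation**: Otsu threshold on the band nearest 1139.26 nm
  (nearest-band ties go to the lower wavelength), 8-connected components,
  `min_area = 10 px`. Border-touching seeds are kept but flagged. Touching
  seeds merge — a documented failure mode with a regression test; no
  watershed splitting.
* **Morphometry**: perimeter counts object pixels 4-adjacent to background
  or the border (whether the original contour rule was 4- or 8-adjacent is
  unstated anywhere authoritative; 4-adjacency is declared here as the
  package's convention). Area includes contour pixels. Axis lengths are
  full axes of the second-central-moment equivalent ellipse with a 1/12
  per-pixel variance term (pixels as unit squares), keeping a 1-px-wide
  object's width positive; this differs from `skimage.regionprops` by far
  less than the ≤ 2 px discretisation tolerance used in tests.
* **Denoising**: Daubechies-8, level 3, symmetric extension, soft universal
  threshold `σ√(2 ln n)` with σ from the finest detail coefficients
  (MAD/0.6745) — the standard wavelet-shrinkage default, since only the
  wavelet and level are prescribed by the protocol being followed. Spectra
  must have ≥ 120 points for a level-3 db8 transform.
* **Kennard–Stone**: Euclidean distance on preprocessed spectra, ties to
  the lowest index, calibration size `round(n·r/(r+1))` half-up (660 at
  2:1 → 440). Selection order is preserved so prefixes are nested.
* **PCA**: mean-centring only (no autoscaling, per reflectance convention);
  deterministic sign convention (largest-magnitude loading element
  positive) so loading-peak picking is reproducible.
* **SPA**: chains from *every* start band; subset size ≤ 15 by default
  (covering the 8–12 bands such studies typically retain); the MLR uses an
  intercept and labels {1, 2} as numeric targets; rank-deficient designs
  fall back to a 1e-8 ridge (logged). The RMSEV validation set is an inner
  Kennard–Stone 2:1 sub-split of the calibration set — the outer
  prediction set is never touched by any tuning decision, by construction.
* **Classifiers**: SVM grid c ∈ 2^[−2,10], g ∈ 2^[−6,6], stratified 5-fold
  CV, ties to smaller (c, g). ELM: inputs min–max scaled to [0,1] on
  calibration ranges, uniform[−1,1] hidden weights drawn once for an
  80-node bank (so node counts nest), logistic activations plus an
  output-bias column, least-squares one-hot output weights; node count
  tuned on an inner KS sub-split, ties to fewer nodes. All randomness (CV
  folds, ELM weights) flows from the single `seed` passed to `fit`.
* **Mapping**: object-wise — one prediction per seed's mean spectrum,
  painted over its pixels (a per-pixel diagnostic mode exists). The fitted
  results object records the preprocessing (crop, denoise) its training
  data received, including preprocessing applied upstream of `fit`, and
  replays it on new cubes. Rendering is a pure function; identical inputs
  give byte-identical PNGs.

## Study sizes used in tests and the acceptance script

Accuracy studies run the full imaging chain at 330 seeds/class (the
per-variety scale of the design being emulated, 660 seeds → 440/220);
band-recovery studies plant the class offset on ±3-band windows around
1122.81, 1314.72, 1402.42 and 1581.51 nm and use the generator's direct
spectral-dataset mode, counting a planted feature as recovered when an SPA
pick lands in its window. Replication is 10 seeds in the test suite and 5
in the acceptance script; Monte-Carlo checks elsewhere use 100–200
replicates. Each full-scene run takes ~15 s on one CPU.

## Known limitations

* Two classes per variety only; no multi-variety joint model.
* No scatter correction (SNV/MSC) or derivative preprocessing.
* Kennard–Stone is O(n²) in memory (distance matrix) — fine to a few
  thousand seeds, not for pixel-level sets.
* The PCA-loadings selector is sensitive to its prominence parameter on
  noisy loading curves and, consistent with the protocol it follows,
  generally underperforms SPA.
* The ELM's reported accuracy depends on the drawn hidden weights; fix the
  seed for reproducibility rather than averaging over draws.
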