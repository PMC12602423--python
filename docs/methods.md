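# Methods

## Problem setting

A rice field is observed at several dates during the vegetative stage
(nominally 34, 41 and 47 days after sowing) with a five-band multispectral
sensor (R, G, B, red-edge, NIR) at centimetre-scale ground sampling
(default pixel size 0.00913 m). Each pixel at each date belongs to one of
three ground covers — paddy (0), exposed/flooded soil (1), broadleaved
weed (2) — and the analysis questions are (i) how accurately the cover can
be classified from the 5-band spectrum alone, (ii) how cover transitions
between dates quantify weed spread, and (iii) how much blanket herbicide
volume targeted spraying of the weed-covered fraction would save.

Classification is strictly per-pixel: the classifier sees a single 5-vector
of reflectance and no spatial or temporal context. Change detection is
post-classification comparison — each date is classified independently with
the *same* trained weights and the *same* standardization, and labels are
compared pixel-by-pixel — so no reflectance-differencing threshold is ever
chosen.

## Synthetic scenes

Real multi-date UAV orthomosaics are not bundled with the package; the
`scene` module generates scenes with the statistical structure the analysis
assumes, and everything downstream treats them exactly as it would real
co-registered rasters.

**Spatial layout.** Class maps come from quantile-thresholded
Gaussian-smoothed white noise: one field carves weed patches covering the
requested weed fraction, a second splits the remainder between paddy and
soil. Smoothing scale (`patchiness`, default 8 px at 256², 6 px in the
128² demo) sets the characteristic patch radius. Quantile thresholding
pins realized class fractions to the request up to patch-boundary
granularity (tested to ±3 percentage points). This produces contiguous
patches — the regime in which sieve/majority post-processing and change
maps are meaningful — rather than i.i.d. pixel labels. The patchiness
default is chosen for testability; the spatial autocorrelation of real
infestations is not calibrated to field data.

**Spectra.** Each class has a per-band Gaussian signature; draws are
clipped to the physical reflectance range [0, 1]. Defaults: paddy
(0.04, 0.08, 0.03, 0.35, 0.55), soil (0.12, 0.10, 0.08, 0.15, 0.10), weed
(0.05, 0.11, 0.04, 0.47, 0.47), with band s.d. 0.010–0.030. Soil is dark
in the NIR; paddy and weed are both vigorous vegetation and differ mainly
in the RE/NIR ratio, the intended hard pair. Every class pair is ≥2 pooled
s.d. apart in at least one band, and a nearest-centroid rule scores >95%
in a fixed-seed Monte-Carlo check — so classifier benchmarks measure the
pipeline, not an impossible task.

**Dynamics.** Between dates the class map advances by synchronous
4-connected sweeps: a non-weed pixel adjacent to weed becomes weed with
probability `weed_expansion_prob` (default 0.25 per step, 3 steps between
dates in the demo); a soil pixel adjacent to paddy becomes paddy with
`paddy_closure_prob` (default 0.10, canopy closure during tillering); a
weed pixel adjacent to paddy reverts with `suppression_prob` (default 0 —
the untreated regime). Rule precedence per pixel is expansion, closure,
suppression, at most one change per sweep. With suppression 0 the weed
count is non-decreasing, mirroring untreated-plot behaviour; the treated
regime is emulated by a weed-free initial map with expansion 0. Defaults
give weed growing from ~10% to ~14% of the field over the three dates,
the order of magnitude of untreated-plot observations.

**Nodata.** Masks are authoritative: the class-map sentinel is 255,
reflectance carries NaN, and masked pixels never enter prediction,
post-processing, transition matrices or area totals (the "excluded"
policy). The generator masks a configurable fraction (demo 2%) via another
smoothed field.

**What the generator does not emulate.** Radiometric drift between
flights, registration error, mixed pixels at class boundaries, water-depth
effects on reflectance, within-class spatial correlation of noise, and
spectrally distinct weed species. Passing tests therefore demonstrate that
the pipeline's machinery is correct and self-consistent under its stated
assumptions, not that the accuracy figures transfer to arbitrary field
imagery.

## Sampling and standardization

Labeled pixels are drawn without replacement per (date, class) from valid
pixels, shuffled, and split 60/20/20 by simple random (unstratified)
shuffling — class balance is the sampling design's job, not the split's.
Partition sizes are round(f·n) for validation and test with the rounding
remainder assigned to training (so n = 54,467 splits 32,681/10,893/10,893).
Per-band standardization (x − μ)/σ uses the sample mean and n−1 s.d. of
the **training partition only**; the same scaler is stored with the model
and applied to every partition and every date at inference, keeping all
inputs on one scale. Constant bands are rejected by name.

## Classifier

Architecture: input(5) → Dense(20, ReLU, He-normal) → Dropout(0.2) →
Dense(15, ReLU, He-normal) → Dropout(0.2) → Dense(k, softmax,
Glorot-uniform), k = 3 for the infested regime, k = 2 for the weed-free
regime (483 and 467 parameters). Loss is categorical cross-entropy plus an
L2 penalty λΣw² on layer weights, λ = 10⁻⁶. Optimization is Adam with
learning rate 0.005, β₁ = 0.9, β₂ = 0.999, batch 32, up to 100 epochs with
early stopping (patience 10) on validation loss and best-weight
restoration. The network is implemented directly on numpy — at this size a
framework buys nothing, and a single integer seed makes initialization,
batch order and dropout masks bit-reproducible. Dropout is inverted and
training-only; inference is deterministic. Argmax ties break to the lowest
class code.

Numerical choices: probabilities are floored at 10⁻¹² inside logs;
softmax is computed with max-subtraction; Adam uses ε = 10⁻⁸ and the
standard bias-corrected step. MSE is computed on probability vectors
against one-hot targets (the natural reading when reported alongside
cross-entropy); κ is reported as a fraction in [−1, 1]. A loud warning
fires if a training table at n ≥ 1000 has any band mean beyond ±0.5 —
the signature of un-standardized input.

## Raster inference and post-processing

Valid pixels are classified in batches (default 65,536); batching cannot
change results because inference is per-pixel. The maximum class
probability is kept as a confidence map. Two speckle filters follow, both
4-connected to match the scene dynamics, with tie-breaks pinned so a
brute-force oracle reproduces them bit-exactly:

- **Sieve** (default minimum 5 px): each same-class component smaller
  than the threshold is reassigned to the majority class among its valid
  boundary *pixels* (ties to the lowest code), all components judged
  against the pass's input map; passes repeat while the number of
  undersized components strictly decreases. The strict-decrease rule makes
  termination unconditional; an undersized component completely surrounded
  by nodata has no voters and is left unchanged, the one case where an
  undersized component can survive.
- **Majority filter** (default 3×3, 1 pass): each valid pixel takes the
  modal class of the valid pixels in its window; a tie keeps the center's
  class if tied, otherwise the lowest tied code wins.

Majority (not median) filtering is implemented; on an ordinal encoding a
median variant would be a one-line change. All parameters are recorded in
the output sidecar. Rasters are written as plain TIFF (5-band float32
reflectance, uint8 class maps) with a JSON sidecar for pixel size, band
order, class palette and nodata policy.

## Change detection

A pixel enters change products only if valid at **both** dates (the joint
mask — otherwise "total valid pixels" is ill-defined across dates). The
nine categories are the ordered pairs (class at t₁, class at t₂), coded
3a + b; counting them gives the 3×3 transition matrix, whose row sums are
the t₁ class counts and column sums the t₂ class counts — asserted on
every pipeline run. Weed-free (2-class) maps flow through the same
machinery with an empty weed row/column. "Pixels that became weed" is the
paddy→weed plus soil→weed cells; class-change percentages divide each cell
(and each per-destination aggregate) by the joint-valid total. Areas are
pixel count × pixel area, 1 ha = 10,000 m², rounded only at presentation.

## Herbicide budgeting

With weed density d (% of valid pixels in the chosen denominator mask —
whole field or treatment plots, exposed as an argument since both readings
are defensible), blanket volume V (a field-survey input; the worked
examples use 280 ml, the unique volume consistent with the published
(estimate, reduction) pairs to within 0.013%):

    estimated = d·V/100,   reduction = 100·(V − estimated)/V = 100 − d.

The identity on the right is asserted wherever both are computed. The
reduction-vs-coverage relationship is an ordinary least squares fit; R² is
invariant under affine rescaling of the coverage axis, so hectares and
percent give identical fit quality. This is a first-order model: it
assumes herbicide need scales linearly with weed-covered area and ignores
dose–response, species composition and growth stage.

## Pipeline reproducibility

One global seed is hashed with each stage name (CRC32-based, kept below
2³¹) into independent per-stage seeds, so identical configs give
byte-identical CSV/JSON artifacts and identical rasters, and a stage can
be re-run alone. The run manifest records seeds, parameters and files;
`validate_outputs` re-checks matrix conservation, density sums, the
budgeting identity and mask respect from the artifacts alone.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run on 128×128 scenes with
1,000–1,500 samples per class per date (the published sampling design of
~4,750–6,500 per cell is exercised once, on 256×256 scenes, to verify the
pooled totals of 28,557 and 54,467 rows). These sizes are the package's
chosen benchmark conditions: the classifier's job — separating three
Gaussian spectral classes — does not get harder with more identically
distributed samples, and the oracle-equivalence suites (100 random 64×64
instances per operation) bound the post-processing and differencing code
exactly at any size.

## Known limitations

- Synthetic-regime accuracies (~0.99–1.0) sit above those reported for
  real imagery (~0.98): real scenes contain mixed pixels, radiometric
  drift and within-class texture the generator does not model.
- The contact-process dynamics are a minimal defensible model of patch
  growth, not a calibrated ecological model of *Monochoria vaginalis*.
- The sieve's "no undersized components remain" goal is unreachable for
  components enclosed by nodata (documented above).
- Herbicide budgeting is the linear first-order model; no efficacy or
  dose–response modelling.
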