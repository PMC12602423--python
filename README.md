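# paddycd

Temporal change detection of broadleaved weed infestation in rice (paddy)
fields from multispectral imagery, for agronomists and remote-sensing
practitioners working on site-specific weed management (SSWM).

Blanket herbicide spraying treats the whole field regardless of where weeds
actually grow. If a per-pixel classifier can map paddy, exposed soil and
weed from five-band (R, G, B, red-edge, NIR) reflectance at several dates,
then differencing the maps shows where and how fast the infestation
spreads, and the weed-covered fraction directly bounds how much of the
blanket spray volume targeted application would save.

`paddycd` implements that whole chain as a tested Python library:

- **`paddycd.scene`** — a synthetic-scene generator producing co-registered
  multi-date 5-band reflectance rasters with known paddy/soil/weed ground
  truth: clustered patches from thresholded smoothed random fields,
  per-class Gaussian band noise, and a 4-connected contact process for weed
  expansion and canopy closure between dates.
- **`paddycd.samples`** — labeled pixel tables, 60/20/20 random
  train/validation/test splits, and per-band standardization fit on the
  training partition only and reused for every date.
- **`paddycd.dfnn`** — the classifier: a fully connected network
  input(5) → Dense(20, ReLU) → Dropout(0.2) → Dense(15, ReLU) →
  Dropout(0.2) → Dense(k, softmax), trained with Adam (lr 0.005, batch 32,
  ≤100 epochs, early stopping with patience 10) minimising categorical
  cross-entropy + L2 (λ = 10⁻⁶); plus the full confusion-matrix metric
  suite (overall accuracy, Cohen's κ, cross-entropy, MSE, one-vs-all
  precision/recall/F1).
- **`paddycd.raster`** — batched whole-raster inference with nodata
  masking and confidence maps; sieve and majority-filter post-processing
  with pinned-down tie-breaks.
- **`paddycd.change`** — post-classification differencing: nine-category
  change maps, 3×3 transition matrices T with T[a,b] = #{pixels: class a at
  t₁ ∧ class b at t₂}, class-change percentages and per-date area
  summaries.
- **`paddycd.herbicide`** — weed density d (% of valid pixels), coverage
  area d·A/100, estimated targeted-spray volume d·V/100 for a blanket
  volume V, expected reduction 100·(V − estimated)/V ≡ 100 − d, and the
  OLS fit of reduction against weed coverage.
- **`paddycd.pipeline` / CLI `paddycd`** — end-to-end orchestration with
  one global seed fanned out per stage, a manifest, and an output validator
  that re-checks every conservation invariant from the files on disk.

## Worked example

`examples/` contains one narrative script per capability. Training the
classifier on a simulated infested field (`examples/02_train_classifier.py`)
prints:

```
samples: 5400 train / 1800 validation / 1800 test
network parameters: 483
stopped after 24 epochs (early stopping on validation loss)

test overall accuracy: 99.94%
test kappa:            0.9992
cross-entropy loss:    0.0013
mean squared error:    0.0003
```

483 is the full parameter count of the 5-20-15-3 network; accuracy and κ
near 1 mean the three covers are nearly perfectly separable from their
5-band spectra. Differencing the three classified dates
(`examples/03_change_detection.py`) yields transition matrices whose
paddy→weed and soil→weed cells grow from 215 pixels (1.31% of the field)
over 7 days to 506 pixels (3.09%) over 14 days, and the herbicide planner
(`examples/04_herbicide_planning.py`) turns the published three-date weed
coverage series (0.05, 0.054, 0.07 ha against reductions 40.95, 39.36,
37.06%) into

```
slope -180.00 %/ha, intercept 49.56 %, R^2 = 0.9487
```

— the expected herbicide saving falls by ~180 percentage points per extra
hectare of weed, so earlier intervention preserves a larger saving.

The same chain is available from the shell:

```bash
paddycd run --seed 1 --outdir runs/demo
paddycd validate runs/demo
```

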