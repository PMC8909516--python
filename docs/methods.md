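# Methods

## Problem and pipeline

Stable (heavy-metal-type) stress affects rice through its entire growth
cycle: the stressed canopy follows the normal phenological trajectory but at
persistently lower vigor, with the strongest depression of red-edge indices
in June–August. The pipeline classifies each pixel from the temporal shape
of eight spectral indices:

reflectance time stack → spectral indices → slope + cloud masking →
gap-filled per-pixel sequences → stratified split → GRU training →
per-pixel classification → confusion-matrix / kappa assessment.

## Spectral indices

The eight features, computed per pixel per date from bands
B1, B3, B4, B5, B6, B7, B8:

| Index | Formula |
|---|---|
| REP | 700 + 40·(((B7−B4)/2 − B5)/(B6−B5)) |
| CIred_edge | B7/B5 − 1 |
| MSR | (B6−B1)/(B5−B1) |
| MCARI | ((B5−B4) − 0.2·(B5−B3))·(B5/B4) |
| NDVI | (B8−B4)/(B8+B4) |
| RDVI | (B7−B4)/(B7+B4) |
| NDRE1 | (B6−B5)/(B6+B5) |
| NDRE2 | (B7−B5)/(B7+B5) |

Two definitions deviate from the forms usually published under these names
and are kept deliberately, because this exact feature set is the package's
contract: RDVI is here a plain normalized difference (the canonical
*renormalized* difference index divides by √(B7+B4)), and MSR involves the
coastal-aerosol band B1 rather than the usual red/NIR simple-ratio form.
Cells with a vanishing denominator or a cloud QA flag carry an explicit
invalid flag and NaN — never a sentinel zero — so downstream gap handling is
unambiguous.

## Masking

Slope is computed from the DEM by Horn's eight-neighbor finite-difference
method (the GIS de-facto standard; edges use replicated borders, which
halves the gradient seen at a border pixel of an inclined plane — slope
claims in the tests therefore address interior pixels). Pixels with slope
strictly greater than 8° are removed: rice is not grown on such terrain,
and the strict reading ("greater than") retains a pixel at exactly 8°.
Cloud masking invalidates all eight indices at flagged (pixel, date) cells
and is idempotent.

## Sequence building

The classifier requires fixed-length sequences on a shared date grid, but
cloud masking leaves ragged gaps. Among the defensible policies (dropping
cloudy dates, padding with a mask token, interpolation) we interpolate
linearly in time per index, with nearest-valid extrapolation at the ends:
it is the simplest order-preserving choice and never alters an originally
valid cell. A pixel with zero valid observations for some index cannot be
reconstructed; it is dropped and counted, keeping the known cost of
QA-based cloud removal (loss of persistently cloudy pixels) observable in
every run report.

Splitting is stratified by class (the class totals are strongly imbalanced,
roughly 2:1 stressed to unstressed among rice pixels) at a default 80/20
train/test ratio, seeded. Each index channel is standardized to mean 0 /
sd 1 using training-set statistics only (sd 0 falls back to scale 1);
standardization is an optimization aid, not part of the scientific model,
and is fitted train-only to avoid leakage.

## GRU classifier

The cell equations are implemented exactly as stated in the package README;
the final combination H_t = Z_t⊙H_{t−1} + (1−Z_t)⊙H̃_t is the standard GRU
convention and is unit-tested (it makes H_t a convex combination, so the
hidden state stays in [−1, 1] once it enters that range). The architecture
is one GRU layer plus a two-layer dense head (tanh on the inner layer,
softmax output); the inner width defaults to hidden_size/2, a free choice
recorded in the config. Depth beyond one recurrent layer is not implemented.

Defaults follow the published operating point: input_size 8 (the feature
order is the index order above and is frozen), hidden_size 256, batch_size
8, learning_rate 1e-4. The optimizer, initialization and stopping rule are
not dictated by the model and are package choices, fully logged: Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), small-uniform initialization in
[−0.1, 0.1] with zero biases, early stopping on test loss with configurable
patience, returning the epoch-best model. All randomness flows from a
single integer seed; two runs with identical config and seed are
bit-identical.

The backward pass is hand-written backpropagation through time. It is
verified against central finite differences with step 1e-5 on random small
instances (d = 3, h = 4, T = 5); relative error is measured as
|g_fd − g_an| / max(|g_fd|, |g_an|, 1e-6), where the 1e-6 floor reflects
the resolution limit of double-precision central differences (absolute
noise ≈ 1e-10, so entries below ~1e-6 cannot be resolved to 1e-4 relative).
Observed worst-case error is ~1e-5, an order of magnitude inside the 1e-4
pass bound.

Training can run 3-class (nonrice/unstressed/stressed, the default) or
2-class on rice pixels only (`rice_only`), since published workflows are
ambiguous about whether nonrice pixels enter the classifier; the map
product uses 255 as the no-data code for masked pixels either way.

## Evaluation

Confusion matrices are stored classified-rows × reference-columns. The
per-class metrics are accuracy (TP+TN)/n, precision TP/(TP+FP) (= user's
accuracy), recall TP/(TP+FN) (= producer's accuracy) and the harmonic-mean
F1. One erratum is corrected: the source formula list repeats the recall
expression for F1, which contradicts its own reported metric triples
(e.g. precision 90.43 %, recall 90.66 %, F1 90.54 % — exactly the harmonic
mean); the harmonic mean is implemented. Cohen's kappa uses expected
agreement from the marginals; the degenerate all-one-class matrix with
perfect agreement returns κ = 1. Ratios of the form 0/0 (empty predicted or
reference class) are reported as NaN and excluded from macro averages,
never coerced to 0.

## Synthetic scene generator

The generator emulates the statistical structure the analysis assumes, not
radiative physics:

* **Phenology**: latent vigor v(t) on a double-logistic green-up/senescence
  curve (green-up midpoint DOY 140, senescence DOY 280), sampled at 33
  dates evenly spaced over April–October.
* **Stress signature**: stressed pixels use
  v′(t) = s · v(t) · (1 − a·exp(−(t − c)²/2w²)) with persistent depression
  s = 0.85 and a Gaussian mid-season trough (center DOY 196, width 25 d,
  depth 0.25) — a curve that is lower at every date with its largest gap in
  June–August.
* **Bands**: fixed affine mixing reflectance = intercept + slope·vigor, with
  NIR (B7, B8) strongly increasing in vigor, red (B4) decreasing, red-edge
  (B5, B6) intermediate; the signs guarantee every red-edge index increases
  with vigor, hence the stressed-below-unstressed ordering downstream tests
  assert. Nonrice pixels get a constant soil-like spectrum.
* **Heterogeneity and noise**: per-pixel multiplicative vigor scale uniform
  in [0.9, 1], additive Gaussian reflectance noise (sd 0.01), clipping to
  [0, 1.2].
* **Clouds**: independent per (pixel, date) with probability 0.05;
  contaminated cells get a bright flat spectrum (0.9) and an invalid QA
  flag.
* **Classes**: per-pixel assignment with fractions (0.30 nonrice, 0.24
  unstressed, 0.46 stressed); the rice-internal ratio matches the ~2:1
  stressed:unstressed imbalance of the motivating study area.
* **DEM**: a sum of six low-frequency random cosines, amplitude-scaled so
  ~10 % of pixels exceed 8° slope, guaranteeing the terrain mask is
  exercised.

What the generator does **not** emulate: atmospheric and illumination
effects, sensor noise correlation, spatially correlated cloud fields
(independent contamination is the default; real clouds are blobs), mixed
pixels at field boundaries, other stressors with similar signatures, and
any calibrated magnitude of the stress-induced index gap — the depression
parameters are plausible, not fitted to field data. Passing tests therefore
demonstrate that the pipeline recovers a planted separable signal under
realistic masking/noise plumbing, not that the classifier attains any
particular accuracy on real imagery.

## Problem sizes and numerical choices

The synthetic-recovery check uses a 56×56 scene (≥ 500 samples in each rice
class after slope masking), hidden size 32 with inner dense width 16, and
12 training epochs — the task converges to ceiling within ~3 epochs, so
this configuration exercises the full training loop while keeping a
single-CPU run in seconds. Index and metric computations are required to
match scalar oracles to 1e-12 (pure double arithmetic, no tolerance for
algorithmic drift). Softmax is computed with max-subtraction; the sigmoid
uses the numerically stable two-branch form. Argmax ties break toward the
lowest class index.

## Known limitations

* Gap filling by linear interpolation cannot represent uncertainty from
  long cloud runs; heavily gapped sequences enter training at full weight
  (the gap fraction is recorded per sample but not used for weighting).
* One recurrent layer only; no bidirectional or stacked variants.
* The rasters are plain TIFFs with the affine transform carried in the
  manifest sidecar, not embedded GeoTIFF tags; georeferencing survives the
  package's own round-trip but is not visible to external GIS tools.
* Training is plain numpy on one CPU; the published hidden size (256) on
  scene-scale data is feasible but slow — the reduced demo configuration
  exists for that reason.
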