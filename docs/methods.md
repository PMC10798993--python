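# Methods

`lufor` re-implements, at desk scale and on synthetic data, a pipeline for
mapping *land use following deforestation*: which human land use occupies a
pixel after tree-cover loss. The real-world analogue consumes ~5 m 4-band
satellite mosaics over tropical Africa, a forest-loss mask with per-pixel
loss year (2001–2020), and imperfect reference polygons for 15 land-use
classes. Every stage of that analysis is reproduced here against a seeded
synthetic-scene generator, so the statistical machinery is testable without
any download.

## Synthetic scenes

A scene is a height×width stack of four reflectance bands (blue, green,
red, nir) in [0, 1], a clean 15-class truth mask, a forest-loss mask with
loss years, and a north-up lon/lat geotransform. Classes combine a spectral
signature (4-band mean + Gaussian noise, default sd 0.02 per band) with a
geometry kind: rectangular fields (croplands, plantations, tea), blobs
(pasture, coffee, cacao, other-land-with-tree-cover), compound clusters
(settlement, mining), a meandering river (water), random-walk roads
(2–3 px wide at 5 m resolution), and row-ripple textures over tree-crop
lattices (oil palm, rubber, cashew).

Design properties, both enforced by tests:

* **Separability.** The 15 signatures keep a minimum pairwise L2 distance
  of ~0.19, several noise standard deviations, so a nearest-centroid
  classifier on the raw bands recovers the truth exactly as noise → 0. The
  learning problem is solvable by construction; a model that fails is
  failing for model reasons.
* **Determinism.** Every output is a pure function of config + seed
  (numpy Generator throughout).

The forest-loss mask is a thresholded smooth random field over non-water
pixels (default 50% coverage) and the loss year is i.i.d. uniform on
2001–2020: the trend analytics only require a defined lustrum partition,
not a realistic disturbance process.

**Label corruption.** Real reference polygons suffer delineation error,
mixed-class polygons, and missing labels. These are abstracted into four
seeded, parameterized corruptions applied to the clean truth in order:
per-class boundary dilation (`boundary_shift_px`), whole-component
relabeling (`polygon_mix_fraction`), exact-rate random mislabeling
(`mislabel_fraction`; the realized differing-pixel rate equals the
parameter by construction), and dropping labels to the unlabeled code −1
(`drop_fraction`). No quantitative error rates exist for the real archive;
the bundled benchmark uses 30% mislabel + 30% drop, which is severe enough
to visibly depress initial accuracy while leaving the task learnable.

What the generator does **not** emulate: atmospheric effects, clouds/haze,
cross-sensor mosaic seams, phenology, spatially correlated noise, and
geographic label bias. Passing benchmarks therefore demonstrate that the
pipeline's machinery is correct and that the active-learning mechanism
works as designed — not that any particular accuracy is attainable on real
imagery.

## Preprocessing

The model consumes a fixed 7-channel stack: the four bands plus
ndvi = (nir−red)/(nir+red), savi = (nir−red)/(nir+red+0.5)·1.5, and
ndmi = (green−nir)/(green+nir). ndmi is deliberately green-based (4-band
imagery has no SWIR); it is retained in this unconventional form for
fidelity to the mapping methodology being reproduced. Zero-denominator
pixels map to 0. Band normalization defaults to clip-to-[0,1]
("fixed" — the generator already emits that range), with per-scene min-max
available; which variant the original analysis used is not documented, so
both are provided.

Loss components smaller than 3.8 ha (1520 pixels at 5 m) can be removed
before inference. Connectivity is 8 by default — the less aggressive
filter — with 4 available; whether the area criterion applies per
component or per image is ambiguous in the source design, so it is
implemented per component.

## Segmentation model

An attention U-Net: encoder blocks of (3×3 same-padded conv → BatchNorm →
ReLU)×2 with dropout 0.1, 2×2 max pooling, a bottleneck, and a decoder of
nearest-neighbour ×2 upsampling with **additive attention gates** on the
skip connections (α = σ(ψ(ReLU(W_g·g + W_x·x))), x′ = x⊙α, all 1×1
convolutions; the gate variant is not pinned down in the source design, so
the common additive form is used). A 1×1 softmax head emits K=15 class
probabilities; classes are mutually exclusive.

The network is implemented in a small NumPy layer framework written for
this package (im2col convolutions on BLAS, analytically derived backward
passes, Adam). It is float32, single-threaded-deterministic, and fully
driven by explicit seeds; its gradients are validated against central
differences in the test suite.

**Focal loss.** Per non-ignored pixel with true class t,
FL = −w_t·α_t·(1−p_t)^γ·log p_t, averaged over scored pixels. γ defaults
to 2 (the canonical setting; the source recipe states only that γ, α and
class weights exist), α ≡ 1, and class weights default to
inverse-pixel-frequency normalized to mean 1 over the classes present —
imbalance is handled in the loss rather than by resampling. Unlabeled
(−1) pixels contribute exactly zero loss and gradient: corrupted
annotations must not teach the model a fake class. p_t is clipped at 1e−7
in the gradient path (1e−12 in the reported value) to keep logs finite.

**Training.** Reference recipe: Adam, lr 1e−4, batch 64, 200 epochs. Desk
scale (used by every bundled experiment, chosen for single-CPU runtimes of
minutes): depth 3, 12 base filters, 32×32 patches, batch 8, Adam 2e−3
decayed exponentially to 2e−4 across the run, 15–30 epochs. The
clean-recovery benchmark tiles scenes with stride 16 (overlapping patches,
4× the samples per scene — an augmentation that notably stabilizes the
thin road/cluster classes); the active-learning benchmark keeps
non-overlapping tiling because it trains nine models in sequence.
Tie-breaks in `argmax_map` go to the lowest class id; with a loss mask,
non-loss pixels receive the no-data code 255 (inference is only meaningful
where forest loss occurred, and 255 fits an 8-bit raster with K ≤ 15).

## Active learning

Pool-based loop over three disjoint pools (annotated / unannotated /
independent test; test membership never changes). Each cycle: train from
scratch on the annotated pool (retraining from scratch matches the
"repeat the process" design; warm start is available), score every
unannotated scene by prediction entropy H(Y) = −Σ p_i log p_i, select
scenes with aggregated entropy strictly above a threshold, reveal their
*clean* labels via the simulated annotator (the oracle), and evaluate on
the fixed test pool.

Aggregation over pixels is unspecified in the source design; the default
is the mean per-pixel entropy, restricted to forest-loss pixels when a
mask is available (max and fraction-above-τ are provided). The threshold
0.6 is ambiguous in scale: the library default treats it as normalized
entropy (H/ln K ∈ [0,1]), while the bundled benchmark applies the rule in
its literal published form — 0.6 nats — which for K = 15 (max ln 15 ≈ 2.71)
is a permissive filter: an undertrained model exceeds it everywhere, a
converged one nowhere. Selection uses strict inequality; a threshold of
1.0 on the normalized scale therefore legally selects nothing.

**Benchmark.** 24 scenes of 128², 8 initially annotated with 30%
mislabel + 30% drop corruption, 12 unannotated, 4 test, 2 AL cycles,
3 seeds. The published macro-F1 trajectory (43% → 54% → 84%) depended on
the real archive and is not reproducible; the property that is
reproducible, and is asserted by the tests, is the direction and size of
the improvement: the final cycle's macro F1 exceeds the initial one by at
least 0.05 on average, with non-decreasing trajectories in most seeds.

## Accuracy metrics

Confusion matrices use rows = map (predicted), columns = reference
(truth); pixels whose reference is −1 are excluded. F1 = 2PR/(P+R) per
class; macro F1 is the unweighted class mean, micro F1 pools counts (and
equals overall accuracy for single-label pixels). User's/producer's
accuracy are per-class precision/recall. All zero-denominator cases score
0 rather than NaN so macro aggregation stays stable when a rare class is
absent from a small test batch. Per-class scores are pixel-wise.

## Stratified assessment

Good-practices stratified estimation (after Olofsson et al. 2014) with
map classes as strata: W_i = mapped-area share; p̂_ij = W_i·n_ij/n_i·;
overall accuracy = Σ p̂_jj; UA_i = p̂_ii/p̂_i·; PA_j = p̂_jj/p̂_·j;
error-adjusted area of class j = A_total·p̂_·j, with the stratified
standard errors of those quantities (strata with a single sample report
zero variance rather than dividing by n−1 = 0). Sample allocation is
proportional with largest-remainder rounding raised to a per-stratum
minimum (the source design does not print its allocation rule; total
sample size and minimum are config parameters, defaults 400 and 5 at desk
scale). The estimators are validated against a census oracle: sampling
every pixel reproduces the exhaustive confusion-matrix values to machine
precision, and repeated-sampling standard errors shrink as 1/√n.
Assessment is run independently per lustrum (2001–2005, 2006–2010,
2011–2015, 2016–2020) by binning pixels on loss year; empty bins are
reported as missing, not errors. Reference labels come from the
generator's truth (a perfect interpreter) with an optional
interpreter-error rate for sensitivity tests.

## Hotspots and trends

Per-class pixels become points at their centers (optional stride
subsampling for large rasters), are binned onto a regular 0.1°×0.1°
lon/lat grid, and smoothed with a Gaussian kernel of bandwidth 0.1° (the
kernel family is not named in the source design; Gaussian is the default,
a box kernel is available). Densities are per square degree and conserve
mass — density × cell area integrates to the point count within well
under 1% because the grid extent pads the point bounding box by four
bandwidths. Degree cells are treated as planar; metric distortion with
latitude is ignored, which is acceptable at the 0.1° display scale and is
the main known limitation of the hotspot module.

Trend tables aggregate classified loss pixels into (region, class,
lustrum) areas (pixel count × pixel area) and within-(region, lustrum)
proportions that sum to 1; the log10 display transform is left to
presentation. Country proportions are per-country class percentages over
classified pixels, summing to 100.

## Orchestration

One YAML file (pydantic-validated, unknown keys rejected) drives the
`lufor` CLI (`simulate`, `train`, `al-run`, `predict`, `assess`,
`hotspots`, `trend`, `all`). A single global seed fans out to per-stage
seeds via SHA-256 of `"{seed}:{stage}"`, so stages are individually
reproducible and never share streams. Every run writes the resolved
config and its hash next to its artifacts. Rasters are written as plain
TIFF with a JSON sidecar for the geotransform and ids; region/country
partitions are integer rasters.

## Known limitations

* The NumPy network is deliberately small; it is not a performance or
  architecture-fidelity substitute for a GPU training stack, and the
  reference recipe (200 epochs, batch 64) is impractical under it.
* Scene realism is stylized (see the generator section); absolute accuracy
  numbers on synthetic scenes say nothing about accuracy on real mosaics.
* The 0.6-nats selection rule is coarse for K = 15: in the bundled
  benchmark it selects the entire unannotated pool after the corrupted
  initial training. The normalized scale with the same numeric threshold
  is the more discriminating default for library users.
* Geographic computations assume an equatorial degree scale; no map
  projections are supported.
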