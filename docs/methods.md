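# Methods

`nichecast` reimplements a three-part invasion-risk analysis — environmental
niche overlap, ensemble climatic-suitability modelling, and standardized
suitability change under future climate and protection regimes — and
exercises it end-to-end on synthetic virtual-species worlds whose niches are
known exactly, so every step can be validated by parameter recovery.

## The synthetic world

The study area is a rectangular grid (default 80×80 cells of 10 km) with
five environmental layers: BIO5 (maximum temperature of the warmest month,
°C), BIO6 (minimum temperature of the coldest month, °C), BIO12 (annual
precipitation, mm), altitude (m) and slope (degrees). Each layer is
Gaussian-kernel-filtered white noise rescaled to a realistic range
(BIO5 ∈ [15, 45], BIO6 ∈ [−15, 15], BIO12 ∈ [100, 2000], ALT ∈ [0, 3000],
SLOPE ∈ [0, 30]); BIO5 ≥ BIO6 is enforced cellwise afterwards. The
default autocorrelation length is 20 km (kernel sd of 2 cells). That value
is deliberately short relative to the region size: the analysis design
assumes the invader's native (western 40% of columns) and invaded (eastern
40%) regions sample essentially the same climate space — the situation of a
Mediterranean invader moving between climatically similar shores — and
short-range autocorrelation is what makes two disjoint regions of one
realisation environmentally exchangeable. The layers are mutually
independent by construction, unlike real bioclimatic variables, which are
strongly collinear; the first two principal components therefore carry a
smaller share of total variance here (~45%) than is typical of real climate
data, and tests should not be read as calibrating that share.

A virtual species is a product of Gaussian responses,
s(x) = prevalence · Π_v exp(−(x_v − μ_v)² / 2σ_v²) ∈ [0, 1],
with optima μ and breadths σ in the variable's own units. Default species
respond to the three climate variables only, with breadths (≈4.5–6 °C,
320–500 mm) wide enough to occupy a realistic fraction of the landscape.
Relief layers exist so the niche-space PCA has the full five-variable
environment, but they do not drive any default species — which also means
the suitability a model must recover is a pure climate signal.

Two occurrence designs are emulated. *Presence-only*: n cells drawn without
replacement with probability proportional to suitability (used for the
invader's native range). *Atlas*: n cells surveyed uniformly at random,
each recorded present with probability equal to its suitability, so
explicit absences exist (used in the invaded region). One grid cell is one
atlas record; there is no sub-cell geometry. Ecoregion-like strata are a
K-seed nearest-centre partition of the grid (default K = 6). The
protected-area mask partitions the grid into compact patches (~1% of cells
each) and accretes random patches until ≈20% of cells are protected, with
a subset of protected patches (≈5% of all cells) flagged as explicitly
targeted for one or two named native species — mirroring a protected-area
network in which only some sites list a given species as a conservation
object.

Future scenarios are additive shifts of the climate layers. Defaults:
a mild scenario (BIO5/BIO6 +1.5 °C, BIO12 −50 mm) and a severe one
(+4.5 °C, −200 mm), plausible end-of-century deltas for the western
Mediterranean. Each scenario is realised as six "GCM" variants — the base
delta plus a small smoothed jitter field (sd 0.3 °C / 30 mm) — and the
variants are averaged cellwise into one layer per predictor, reproducing
the multi-model mean used to damp GCM uncertainty. Precipitation driven
below zero is clamped at zero with a logged warning (expected under the
severe scenario in the driest cells).

What the generator does **not** emulate: real coastline/terrain structure,
collinear climate variables, spatial sampling bias, observer error in atlas
absences, dispersal limitation within a region. Passing tests show the
method recovers known niches under clean sampling; they do not certify
performance under the biases of real occurrence data.

## Niche overlap

The environmental space is the correlation PCA (each variable centred and
scaled; sample sd, n−1) of all study-area cells — a background-calibrated
space shared by every species, which is what makes hull intersections
comparable. The PCA is computed by SVD of the standardized matrix; loadings
are orthonormal, components ordered by explained variance, and signs fixed
so each component's largest-magnitude loading is positive. Occurrences are
projected with the calibration means/sds (never their own), and each
species' environmental space is the convex hull of its projected
occurrences in the first two components. Overlap is the polygon
intersection area, reported as a fraction of *each* hull so both readings
("x% of species A's space", "y% of B's") are available. Niche conservatism
is diagnosed by the count of invaded-range occurrences strictly outside the
native-range hull; boundary points count as inside.

## Ensemble suitability models

Predictors are the three climate variables; projecting relief to a future
date is meaningless, so relief enters only the PCA (a `predictor_names`
flag can add static relief covariates). For each species, R = 10
replicates each draw a fresh absence sample: stratified pseudo-absences of
equal size to the presences for presence-only data (allocation across
strata proportional to stratum background size by the largest-remainder
rule, uniform sampling within stratum, presence cells excluded), or an
equally sized stratified subsample of the recorded absences for atlas
data. Each replicate is split 70/30 stratified by label; five families are
fitted on the 70%:

- **GLM** — logistic regression with quadratic polynomial features (the
  quadratic logit is exactly the log of a Gaussian response);
- **GAM** — logistic regression on a cubic spline basis with a ridge
  penalty;
- **MARS** — hand-written forward selection of reflected hinge pairs by
  residual sum of squares, backward pruning by generalized cross-
  validation, and a ridge-logistic calibration of the selected basis;
- **GBM** — gradient-boosted shallow trees (150 trees, depth 3, shrinkage
  0.05);
- **FDA** — linear discriminant analysis on the spline basis.

Hyperparameters are fixed constants (reproducibility over tuning). Test
AUC is the normalized Mann–Whitney rank statistic (ties contribute ½).
Members with test AUC strictly greater than 0.7 are retained, across all
replicates and families, and combined as a single weighted mean with raw
AUC values as weights (normalized to sum to one). Transferability of the
invader's native-range ensemble is the AUC of its projection against the
invaded-range presences plus an equal-size stratified pseudo-absence
sample from the invaded background.

## Standardized change

Raw consensus scores live on species-specific scales, so all maps are
converted to standard scores using the mean and sample sd of the *current*
prediction over the projection region (the invaded region, where all
sensitive species live); the per-cell change Δz = z_future − z_current then
counts reference standard deviations gained or lost and is comparable
across species. Change is evaluated over two cell sets: the invader's
current invaded occurrences, and the "potential range" of a long-distance
dispersal scenario — the union of all native species' occurrence cells.
Native species are circumscribed to their own occurrence cells intersected
with each range. Within each species × scenario × range, cells are
partitioned by protection regime — outside / protected / protected-and-
targeted-for-this-species (targeted cells are excluded from the plain
protected group) — and summarized as 5/25/50/75/95 percentiles with linear
interpolation (the box-plot convention). Scenario contrasts on identical
cell sets use paired t-tests; contrasts between different cell sets
(inside vs outside protection) use Welch's unequal-variance t-test, since
pairing is only defined with a matching key. p-values are uncorrected; the
number of comparisons is logged.

## Numerical and design choices

- Sample (n−1) standard deviation everywhere (PCA scaling,
  standardization, eval-table spreads).
- AUC threshold is strict (> 0.7); a member at exactly 0.7 is dropped.
- Largest-remainder ties break toward the larger stratum, then the lower
  stratum id.
- Degenerate inputs raise typed errors rather than returning NaN:
  zero-variance PCA variable (named in the message), collinear hulls,
  single-class AUC, zero-spread standardization reference, zero-variance
  paired differences, empty change masks.
- Replicates re-draw their pseudo-absence sample (not merely re-split);
  re-drawing propagates background-sampling uncertainty into the AUC
  spread.
- All randomness flows through named per-stage seeds derived from one
  master seed; reruns of a config are byte-identical, and the run manifest
  records SHA-256 digests of every output.

## Problem sizes

Defaults run the full study (80×80 grid, 4 species, 10 replicates × 5
families, two scenarios × six GCM variants) in ~10 s on one core. The
validation suite uses 100×100 grids with 500 presence records for niche
recovery, 80×80 twin-region worlds with 300 records for transferability,
and 60×60 worlds for scenario-direction checks — sizes at which the
sampling noise of the checked statistics is well below the asserted
margins.

## Known limitations

- Real-data mode reads plain-text (ESRI ASCII dialect) grids and CSVs
  only; CRS handling and GeoTIFF are out of scope.
- The atlas design treats survey effort as exhaustive within a surveyed
  cell; detection probability is not modelled.
- Convex hulls are sensitive to outlying occurrences by construction
  (that is the "maximum convex polygon" definition); no kernel-density
  alternative is provided.
- The potential-range rule (union of native localities) encodes the
  long-distance dispersal assumption literally; it is a scenario, not a
  dispersal model.
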