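# Methods and design notes

This note records the models implemented, the choices made where the
methodology was genuinely open, and what the synthetic ground truth does
and does not demonstrate.

## Raster model

A `RasterGrid` is a single layer on an axis-aligned, unprojected
longitude/latitude grid: row 0 is the northernmost row, cell (0, 0) the
north-west corner, and cell centres carry coordinates. Missing data are a
boolean mask. On-disk format is the ESRI ASCII grid (`.asc`), written
with 9 significant digits so float32 values round-trip bit-exactly and
repeated runs are byte-identical. All percentiles anywhere in the package
use linear interpolation between order statistics.

## Synthetic landscape

Each of the nine predictor layers is

    value(row, col, month) = base + gradient·row + amplitude·cos(2π(month−7)/12) + noise

with the cosine peaking in July and the noise a Gaussian random field
(white noise blurred one cell, rescaled to the target sd) seeded per
layer, so zero-amplitude layers (elevation, forest cover, human
influence) are static across months. Spatially autocorrelated noise
matters: white noise would make cell-level prediction unrealistically
idiosyncratic. Default units and magnitudes are chosen to look like a
temperate continental gradient (e.g. temperature 10 °C base, +0.2 °C per
row southward, ±8 °C annual cycle, 0.5 °C field noise).

True suitability is a Gaussian thermal niche,
`exp(−(T − opt_m)² / 2τ²)` with breadth τ = 1 °C, whose monthly optimum
`opt_m` is chosen so the suitable band sits ~80 % of the way south in
January and ~17 % from the north edge in July, moving smoothly between —
a north–south seasonal migrant. A corridor polyline (default: a
three-cell-wide north–south band through the map centre) receives an
additive suitability boost (default 0.3, capped at 1).

**The corridor is an environmental feature, not only a label.** The
generator imprints it into the predictors as a vegetated low valley
(NDVI +0.2, elevation −300 m). This is deliberate: suitability models
see only the environment, so a corridor present in true suitability but
invisible in every predictor would be unrecoverable *in principle* by
any SDM. Planting the signature makes corridor recovery a fair test of
the method chain rather than an impossibility.

Presence sampling draws cells with probability ∝ suitability × effort,
where effort is a logistic gradient rising toward the east edge — the
kind of institutional spatial bias aggregated occurrence archives carry —
then jitters points uniformly within their cell. Defaults: 300 presences
per month on a 60×60-cell (15°×15°) grid at 0.25°.

What the generator does **not** emulate: taxonomic misidentification,
coordinate uncertainty radii, temporal trends in effort, spatial
autocorrelation of detection conditional on suitability, or real
topography. Passing recovery tests shows the pipeline is internally
sound, not that real archives carry enough signal for any particular
species.

## Occurrence preparation

Filtering keeps records with in-range, non-missing, non-(0, 0)
coordinates, an allowed record type (preserved specimen, human
observation, material sample), and `ref_year − 50 < year ≤ ref_year`;
exact duplicates on (species, lon, lat, year, month, day) collapse, so
revisits on different days survive. Thinning keeps the first record in
input order per 1° cell (grid anchored at integer degrees, floor
assignment) and is idempotent. The analysis thins **within each month**,
since the models are monthly; the aggregated winter/summer endpoint sets
are thinned once more before path analysis.

Seasons: Dec–Feb winter, Mar–May spring, Jun–Jul summer, Aug–Oct fall;
November belongs to no season and is labelled `unassigned`.

Cross-validation uses a random k = 5 fold partition (sizes differing by
at most one); one fold is held out for testing, giving the conventional
80 % training / 20 % testing split. Monthly sample-size guards: warn
below 25 thinned records, refuse below 13 unless explicitly overridden.

Pseudo-absences (default 1,000 per month) are distinct valid cell
centres drawn uniformly without replacement from the full grid,
excluding cells holding presences.

## Predictor screening

Pearson r is computed per pair over cells valid in both layers (in the
analysis, pooled over all 12 monthly stacks). Pairs with |r| > 0.8 —
absolute value, strict inequality — are processed in descending |r|; the
variable ranked lower in a configurable preference order is dropped and
takes no further part. The default preference ranks average temperature
first, standing in for expert judgement of biological relevance.

## Suitability models

* **BIOCLIM**: per predictor, `p = fraction of training presence values ≤ x`
  (weak inequality), tail score `2·min(p, 1−p)`, overall score the
  minimum across predictors, clipped to [0, 1]. A constant predictor
  collapses to a point envelope (1 at the constant, 0 elsewhere).
  Rank-based, hence invariant to monotone transforms of any predictor.
* **GLM**: logistic regression of presence vs. background on
  standardized predictors plus per-predictor squares (lightly penalized,
  C = 10⁴), so unimodal niche responses are representable and perfect
  separation cannot blow up the fit.
* **MaxEnt-style**: the maximum-entropy presence-background model in its
  penalized-logistic form — L1-regularized logistic regression (default
  regularization weight 1.0) on linear + quadratic + pairwise-product
  features of the standardized predictors. The reported score is the
  logistic probability, which is already in [0, 1] and monotone in the
  exponential model's linear predictor; hinge/threshold features are out
  of scope.
* **RF**: 500-tree classification forest, square-root feature sampling,
  scored by presence-vote fraction.

All four are deterministic given their seed. Models serialize to a
versioned JSON archive (the forest as an embedded joblib payload).

## Evaluation and ensembling

AUC is rank-based (Mann–Whitney, ties 0.5). TSS is maximized over
candidate thresholds — midpoints of consecutive sorted unique scores
plus sentinels — with `score ≥ threshold` as predicted presence and ties
broken toward the lower threshold. Variable importance is permutation
importance (drop in AUC when one column is shuffled, averaged over
repetitions; rank 1 = most important), one procedure for all four
algorithms rather than four package-specific ones.

Ensemble weights are `max(metric, 0)` normalized to sum to one — a
worse-than-chance model contributes nothing rather than subtracting
signal — and the ensemble is the cell-wise weighted mean, masked where
any input is masked. Ensemble rasters are then winsorized at the 99th
percentile and min–max rescaled to [0, 1]; winsorizing is the
"outlier-removal" rule because it is reversible by configuration and
keeps every cell defined.

## Corridor inference

Seasonal conductance is the cell-wise mean of the season's three monthly
ensembles (spring: Mar–May; fall: Aug–Oct), floored at ε = 10⁻⁶ so the
graph stays connected. Optional monotone transforms (sqrt, log, natural
log, cube root) are exposed but off by default.

The graph is 8-connected; for an edge of length L (1 rook, √2 diagonal,
cell units) between cells with conductances c₁, c₂: edge conductance
`mean(c₁, c₂)/L`, traversal cost `L·mean(1/c₁, 1/c₂)`. The symmetric
construction lets the least-cost and circuit layers share one graph.

Least-cost paths use Dijkstra; tie-breaks are deterministic (path
reconstruction walks tight edges choosing the smallest node index, with
a 10⁻⁹ relative tolerance for float equality). One path per (winter,
summer) endpoint pair; density counts each traversed cell once per path.
Straight-line and along-path distances are haversine great-circle
kilometres (R = 6371 km) between cell centres.

The circuit solve fixes grounds at potential 0, splits the injected
current equally across sources (all-to-one mode, mirroring a single
source-set/ground-set per season and direction; spring runs winter →
summer, fall the reverse), solves the reduced Kirchhoff system with a
sparse direct solver, and reports node current as half the sum of
absolute incident edge currents. Disconnected source–ground
configurations are rejected rather than regularized.

The percentile mask flags cells at or above the 95th percentile of valid
values. For the consensus, density and current are binarized at their own
95th percentiles — one consistent rule, configurable — and consensus
counts the agreeing methods (0–3); cells at 3 are the candidate corridor.

## Spatial statistics

Weights are binary queen contiguity, not row-standardized, which keeps
the checkerboard closed forms (I = −1, C = 2(N−1)/N on rook weights)
exact and is the common raster default. Moran's I and Geary's C use the
standard global formulas over valid cells; the statistics are computed on
the LCP density raster *including zero cells*, because the question is
whether path concentration stands out against the background. Inference
is a one-sided permutation test (default 99 permutations, +1 estimator,
"more clustered" = higher I or lower C), which is distribution-free and
whose p-value floor of 0.01 matches the granularity the design targets.
The distance test is a one-sided paired t of mean(path − straight) > 0;
an all-zero difference vector is reported as the p = 0.5 boundary case
and a zero-variance positive mean as t = ∞, both flagged.

## Pipeline and reproducibility

`run_pipeline` executes prep → screen → monthly fits → evaluation →
ensemble → seasonal conductance → three corridor methods → consensus →
statistics, writing every artifact plus a manifest of SHA-256 content
hashes. A single master seed derives per-stage seeds by fixed offsets;
two runs with equal config and seed produce byte-identical numeric
artifacts (the manifest's wall-time field is the one excluded quantity).
Configuration validates before any compute (unknown algorithm names,
out-of-range thresholds).

## Problem sizes

The default study runs 12 months × 4 algorithms on a 60×60 grid with
300 presences and 1,000 pseudo-absences per month (~8,000 endpoint pairs
per season), which keeps a full run around a minute on one CPU while
leaving the suitable band ~10 cells wide — narrow enough for sharp
recovery tests. The determinism check uses a 20×20 grid; the exact path
and circuit oracles run on grids up to 4×4, where exhaustive simple-path
enumeration is feasible.

## Known limitations

* The monthly SDM test scores are optimistic only with respect to random
  folds; no spatial block cross-validation is implemented.
* The circuit node-current convention (half the absolute incident edge
  currents) undercounts at sources and grounds, where external current
  enters; corridor thresholds are percentile-based, so this has no
  practical effect away from endpoints.
* With few endpoint cells, LCP density is dominated by trunk routes near
  endpoints; the consensus with the current map and the suitability mask
  is what suppresses those artefacts.
* The synthetic bias field is monotone east–west; real archival bias is
  patchier, and 1° thinning removes only its within-cell component.
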