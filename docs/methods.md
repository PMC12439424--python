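# Methods

This note documents the models, defaults and numerical choices behind
`sdmrisk`, and what the synthetic experiments do and do not demonstrate.

## Geometry

All geometry is planar in an equal-area km frame. Grids are south-up with
cell centres at `origin + (index + 0.5) * cell_km`; points falling exactly
on a cell edge belong to the cell with the larger index (floor rule).
Longitude/latitude inputs are expected to be projected before use; the
package does no geodesic arithmetic, which is a deliberate restriction —
at the tens-of-km extent of a narrow-range endemic the planar error is
negligible relative to occurrence-data uncertainty.

`align_resample` uses cell-centre registration: a target cell takes the
value interpolated (nearest or bilinear) at its centre's fractional
position in the source grid. Target centres outside the source coverage,
or whose interpolation touches nodata, become nodata; the stack mask is
the intersection over layers.

## The synthetic landscape

`generate_env_stack` builds each layer as a Gaussian random field —
white noise convolved with a Gaussian kernel (default length 6 cells) and
re-standardized — then rescales it affinely to a plausible range for its
registry units (temperatures to 5–30 °C, precipitation to 0–400 mm, and
so on). Smoothness is the only spatial property the downstream analysis
relies on, so convolution was preferred to spectral synthesis.

Layers come in groups of three sharing a latent field: the second and
third members mix the latent at weight 0.92 (pairwise |r| ≈ 0.85, above
the 0.75 filter threshold), while the first member is an independent
field. This gives the collinearity filter genuine work (about a third of
the layers are redundant proxies) while keeping a set of identifiable
candidate driver layers. Driver identifiability is the reason the first
members are fully independent rather than weakly loaded on the latent:
when a driver shares variance with nuisance proxies, permutation
importance is known to split credit among them, and "which layer drives
the species" stops being a well-posed recovery target.

The nodata mask removes a `mask_fraction` of cells contiguously by
thresholding a further smooth field, mimicking a study-area boundary
rather than salt-and-pepper gaps.

### The virtual species

`truth_suitability` is a logistic model on standardized layers:
`expit(intercept + Σ terms + N(0, noise_sd))`. Terms are linear
(increasing/decreasing) or quadratic with negative curvature (unimodal).
The default species uses three drivers — increasing (coefficient 4.0),
decreasing (3.5) and unimodal (1.0, −4.5) — from three distinct
correlation groups, with intercept −5. Two properties motivated these
values, chosen once as the package's reference conditions:

* **Narrow range.** Mean suitability ≈ 0.14 and roughly 10–15% of cells
  exceed 0.5, matching the few-percent range fraction typical of a
  narrow-range endemic rather than a widespread generalist.
* **Comparable driver signal.** The three terms have per-landscape
  contribution dispersions of the same order, so each driver is genuinely
  informative at occupied sites; a token third driver would make the
  stated recovery target (all three drivers in the importance top 3)
  meaningless.

Occurrences are drawn without replacement, cell by cell, with probability
proportional to suitability, and placed at cell centres. This emulates
presence records collected roughly in proportion to habitat quality; it
does **not** emulate roadside/accessibility bias, detection failure,
georeferencing error or taxonomic misidentification, so passing recovery
tests say nothing about robustness to those real-data pathologies.

### Future stacks

`make_future_stack` applies per-layer `value * factor + shift`, averaged
over `n_gcm_members` realizations that can each add an independent smooth
perturbation (`perturbation_sd`, in units of the layer's SD, default 0).
The default of 0 keeps the arithmetic identities exact (identity deltas
reproduce the input bitwise); the pipeline's default config uses 0.05 to
emulate mild inter-GCM spread. The default scenario set crosses two
pathways with two periods — temperature layers shifted by +1.5/+2.0 °C
(low pathway) or +2.5/+4.0 °C (high pathway) and precipitation layers
scaled by 0.95/0.92 or 0.88/0.80 — magnitudes in line with mid/late-century
projections for arid subtropical mountains.

## Predictor screening

VIF is computed by regressing each standardized column on all others with
an intercept; exact collinearity reports +inf. The filter has two phases:
first the maximum-|r| pair (ties broken by sorted name order) loses its
higher-VIF member (equal VIFs: the lexicographically later name) until no
pair reaches 0.75, then the maximum-VIF variable is dropped until all
VIFs are ≤ 5. Both drops are recorded with their triggering value, and
the filter is idempotent on its own output.

Permutation importance permutes *evaluation rows* (not raster cells) of
one variable at a time, computes `1 − cor(intact, permuted)` predictions,
averages over `n_perm = 5` seeded permutations, floors at zero and
normalizes to percentages. Row permutation was chosen because importance
is a property of the fitted response surface at the sampled environments,
not of spatial arrangement.

## Learners and evaluation

GLM is unpenalized logistic regression on linear terms behind a
standardizing scaler (no polynomial terms — the response shape flexibility
lives in the tree ensembles); RF uses 500 trees; BRT 200 trees at
learning rate 0.05 with 0.75 subsampling; SVM is an RBF SVC behind a
scaler with Platt calibration (5-fold, non-shuffled, hence deterministic).
Replication is by subsampling: each replicate independently splits
presences and backgrounds 70/30 (test size = round-half-up of 0.3·n per
class). Background size defaults to 1,000 uniform cells excluding
presence cells.

The decision rule is `score ≥ threshold → presence`, making threshold 0
the all-presence boundary. The MTSS threshold scans the unique observed
scores and takes the smallest maximizer; a dense-grid scan can differ by
at most one inter-score gap, which a test asserts. Undefined metric
ratios (an absent class) are NaN, never silently zero. Replicate tables
report mean ± sample (n−1) SD per algorithm plus an Average column that
averages the algorithm means (pooling replicates across algorithms is the
alternative; averaging means weighs algorithms equally regardless of
failed fits).

## Ensembling and change accounting

Ensemble weights floor negative TSS at zero; a model with TSS ≤ 0 has no
influence, and an all-non-positive weight set is an error rather than an
unweighted fallback. Suitability classes are low [0, 0.3), moderate
[0.3, 0.5], high (0.5, 1] — both bounds inside "moderate" so the classes
partition [0, 1] totally.

Change maps code `current + 2 × future`. The summary derives current =
loss + stable and future = gain + stable (asserted as invariants), with
loss% = 100·loss/current and gain% = 100·gain/(current + gain) — the
latter denominator equals future + loss and is the convention consistent
with published change tables of this shape. Report percentages round
half-even to one decimal; raw values are retained alongside.

## Red List engine

EOO is the shapely convex-hull area (collinear sets give 0); AOO counts
distinct 2×2 km cells, with an origin-sensitivity helper because AOO
depends on grid anchoring. In `assess`, EOO is floored to AOO before B1,
per standard guidance. Criterion B needs the size threshold plus ≥ 2 of
conditions (a) fragmentation or few locations (≤ 1/5/10 for CR/EN/VU),
(b) continuing decline, (c) extreme fluctuation; the criteria string is
rendered compactly, e.g. `B1ab(i,iv,v)+2ab(i,iv,v)`. Location counts are
user inputs: locations are threat-defined and judgment-laden, so no
automatic clustering is attempted.

Projected AOO under full dispersal counts all future-suitable cells;
limited dispersal intersects with the current range, so full-dispersal
loss never exceeds limited-dispersal loss (a tested invariant). A3(c)
maps loss < 15% to LC; the bands above that follow the standard A3
thresholds (30 VU, 50 EN, 80 CR), with [15, 30) reported as NT — an
explicit extension, flagged here because the <15%→LC rule alone leaves
the interval undefined. The final category is the most threatened among
triggered current-status criteria; proposed future categories are carried
per scenario in the assessment basis.

## Problem sizes and determinism

The reference experiments use a 100×100 km grid with 12 candidate layers
(3 drivers + 9 nuisance), 300 presences and 1,000 background points; the
recovery experiment repeats 20 seeded runs with one replicate each and a
single 5-replicate run for the held-out ensemble AUC. These sizes keep
the full suite and the acceptance script in the minutes range while
leaving the statistical conclusions unchanged at larger grids.

Every random draw flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning; nothing reads the clock. Identical
configs produce byte-identical CSV reports, which a test asserts.

## Known limitations

* Presence-only sampling bias, detection error and coordinate noise are
  not modelled; recovery results are best-case.
* Raster I/O writes plain TIFF plus a JSON geometry manifest, not
  CRS-tagged GeoTIFF; consumers needing GIS metadata must carry the
  manifest.
* The GLM is linear-in-predictors; strongly unimodal responses are
  captured by the tree ensembles and the SVM, not the GLM.
* Areas are planar cell counts; geodesic cell-size variation is ignored.
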