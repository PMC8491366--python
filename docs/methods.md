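# Methods

This note documents the models implemented in `jackalkit`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Kernel home ranges

The utilization distribution (UD) is a fixed bivariate Gaussian kernel
density evaluated at the centers of a regular square-cell grid and normalized
to total mass 1. The grid spans the data bounding box expanded by 3h on every
side (so that no appreciable kernel mass is clipped; `kde_ud` rejects grids
violating this) at 256 × 256 cells by default. Halving the cell size changes
the 95% area by well under 5% for smooth point sets of n ≥ 100, which is the
resolution-stability bar the test suite enforces.

**Bandwidth.** The reference bandwidth is Worton's plug-in rule for
bivariate-normal data, h_ref = σ̂·n^(−1/6) with σ̂ = √((s_x² + s_y²)/2) using
n−1 sample variances. Used alone it over-smooths multimodal ranges, so the
working bandwidth is 0.8 × h_ref — unless the *ad hoc* bandwidth is larger,
in which case the larger one is used (`BandwidthSpec.h_used = max(0.8·h_ref,
h_adhoc)`). The ad hoc estimate scans multipliers 1.00, 0.95, …, 0.05 of
h_ref and returns the smallest bandwidth whose 95% isopleth is still a single
8-connected cell component without interior holes (holes are background
components of the mask that do not touch the grid border). If the isopleth is
fragmented even at h_ref the scan returns h_ref with a warning rather than
failing. The 0.05 step and floor are conventional; the scan is procedural and
any step refinement only tightens the returned multiplier.

**Isopleths.** The p-isopleth is the smallest set of highest-mass cells whose
cumulative mass first reaches p, with cells ranked by (mass descending, flat
index ascending). Accumulation stops at the first crossing, so a uniform UD
over 100 equal cells yields exactly 95 cells at p = 0.95. The area is the
counted cell area (convergent under grid refinement; no contour
interpolation); the polygon outline is the coverage union of the selected
cell squares.

**MCP.** The percent-MCP peels ⌊(1−p)·n⌋ points farthest (Euclidean) from the
arithmetic mean of *all* points — the centroid is not recomputed between
removals — then takes the convex hull. Hull areas are cross-checked in the
tests against an independent hull implementation.

**UDOI.** For two UDs on the same grid,
UDOI = A_overlap × Σ_c UD₁(c)·UD₂(c) / cell_area, with A_overlap the
intersection area of the two 95% level sets. Inside `udoi` the level sets are
*tie-inclusive* (every cell whose mass ties the crossing mass is included):
for continuous UDs ties have measure zero and this coincides with the
isopleth rule, while for exactly-uniform UDs it makes the identity
UDOI(identical uniform) = 1 hold exactly instead of 0.95 — the defining
property of the index. Values above 1 indicate concentrated shared use.

**Filters and summaries.** Monthly ranges require ≥ 28 locations spanning
≥ 14 days within the month, each month getting its own bandwidth and grid.
Known extraterritorial forays are removed only via an explicit exclusion
list; the automatic screen (fixes ≥ 12 km by default from the animal's median
location) only *flags* candidates for review, never deletes. Mean home-range
size is reported with SE = sample SD (n−1) / √n; group-count density is
groups × mean adults per group / area.

## Resource selection

The used–available design labels relocations 1 and availability points 0,
with availability sampled uniformly within each animal's 100% MCP at a 10:1
ratio by default (an arbitrary availability frame can be supplied instead,
e.g. a pooled domain or a model-matched sample). Covariates are Euclidean
distances (m) to the nearest feature of each landscape layer, transformed
log(d + 1) — the +1 keeps points lying on a feature finite — then centered
and scaled by the pooled design mean/SD. Pairs with |Pearson r| ≥ 0.7 on the
log scale are reported and one member dropped, chosen by a configurable
priority list (by convention the coarser land-cover layer, e.g. the
deciduous-dipterocarp background, yields to dense forest).

The model is a weighted Bernoulli logistic regression: available points carry
weight W = 1,000 so that the fit approximates the underlying
inhomogeneous-point-process likelihood; slope estimates are invariant to
rescaling all weights and stabilize as W grows (the suite checks < 1% change
from W = 1,000 to 10,000). The mixed version adds a per-animal random
intercept whose variance is *fixed* at 10⁶ — the intercept absorbs each
animal's used:available ratio and must not be shrunk — plus random slopes
with estimated variances. Estimation maximizes the Laplace-approximated
marginal likelihood: an inner Newton solve (with backtracking) finds each
animal's random-effect mode, and L-BFGS-B runs over the fixed effects and log
variances. The outer finite-difference step (1e-6) is deliberately larger
than the inner-solve tolerance so numerical gradients stay clean; on a
reference design the fit agrees with an independent TMB-based implementation
to four decimals in both coefficients and variance components (this
cross-check is part of the test suite). Wald machinery throughout:
CI = β ± 1.96·SE, z = β/SE. The fixed-effects mode (plain IRLS) is the
default whenever between-animal heterogeneity is negligible, and the two
agree within one SE in that limit. SEs come from the weighted likelihood and
do not account for Monte-Carlo noise in a small availability sample; with a
10:1 ratio this leaves per-coefficient 2·SE coverage a point or two below
nominal, and coverage checks in the suite therefore use a 30:1 sample.

Prediction is the relative selection score exp(x·β̂) (fixed effects only,
no intercept — scores are relative, so a point at the covariate means scores
1). Validation is blocked by individual: each fold withholds one animal,
trains on the rest, and scores the withheld animal's available points. The
ten score deciles of those available points define equal-available-area bins;
the area-adjusted frequency is the withheld presence share per bin divided by
1/10, and Spearman's rho against bin rank 1..10 summarizes ranking skill
(per-fold, mean, and pooled over all folds' bin pairs). "Equal-area bins" is
operationalized as available-score deciles — an assumption, since finer
constructions exist, but it fixes each bin at 10% of available points by
definition.

## Diet from scats

Items visually estimated at ≤ 2% of a scat (threshold configurable,
inclusive) are excluded as trace before composition. Scat dry weight is
allocated to items by volume share — the only allocation consistent with
measuring one dry weight per scat and per-item volume percents — and volume
not assigned to an identified item contributes nothing. Correction factors
(CF, g fresh biomass per g dry remains, from canid feeding trials) convert
each item's dry remains to biomass consumed; percent biomass is the CF-mass
share over all taxa and is invariant to uniform rescaling of dry weights.
Percent volume defaults to the arithmetic mean of per-scat volume percents
over all scats (zeros included); a dry-mass-weighted aggregate variant is
provided since published tables rarely state which was used. Frequency of
occurrence counts scats containing a taxon; category-level occurrence counts
a scat once if any member taxon occurs. Seasons are assigned by collection
month (Nov–Feb cool-dry, Mar–May hot-dry, Jun–Oct rainy; no year effects) and
the seasonal contrast is a Pearson chi-square on season × category occurrence
counts (error on zero expected cells, logged warning below 5).

Niche metrics operate on proportion vectors (renormalized silently only
within 1e-6 of summing to 1; `as_proportions` converts percent columns
explicitly). Levins B = 1/Σp² is computed over the finest identified item
rows, not category roll-ups — that granularity is what reproduces the
published 5.43/5.59/4.95 values. Horn's R₀ uses natural logs with the
2·ln 2 normalization (base-invariant). Availability shares are
density × adult-female-mass shares; Jacobs D = (r−p)/(r+p−2rp) compares a
consumed share r against an availability share p. For ungulate electivity, r
is each species' biomass percent over the *whole ungulate category* total
(unidentified ungulate remains dilute all species equally); this is the
normalization that reproduces the published electivities from the printed
composition table, and `category_total` exposes the alternative.

## Synthetic generators

The generators emulate the *statistical structure* the analyses assume, not
the field reality: landscapes are random-walk polylines (roads, streams) and
buffered random patches (dense forest, DDF) in a projected plane; they
support distance queries and nothing else. Movement is independent
habitat-biased draws — a bivariate-normal availability proposal (center σ
defaults 3.5 km, matching ~40–50 km² ranges) thinned by exp(x·β_true) on
standardized log-distance covariates — deliberately *not* an autocorrelated
process, matching the location-independence assumption of 6-h fix schedules
and making coefficient recovery well-defined. The standardization is frozen
against the proposal distribution itself (a seeded 4,096-point reference
sample), so β_true lives on a fixed scale shared by `gen_movement` and
`gen_availability`. For recovery experiments the availability sample should
come from `gen_availability` (the model's true availability); the MCP-uniform
sampler is the field protocol and mismatches the generative model slightly.

Scats: per scat an item count is drawn from the configured distribution over
1–5 items (defaults 14.4/38.4/27.4/17.1/2.7%, the observed mix), an item
*set* by weighted sampling without replacement, within-scat volume shares
from a Dirichlet whose mean is proportional to per-taxon volume weights, and
dry weight lognormal (log-mean ln 10 g, log-sd 0.5 — unspecified in the
source study; biomass percents are scale-invariant so only plausibility
matters). Raw inverse-CF weights (truth/CF) are *biased* under
without-replacement set sampling, because inclusion probabilities saturate
for dominant taxa — a naive construction overshoots the dominant taxon by
double-digit biomass points. Both weight vectors are therefore calibrated by
a seeded Monte-Carlo fixed point (8 iterations × 30,000 simulated scats at
config construction) until the expected volume share of every taxon matches
truth/CF; the expected CF-reconstructed biomass then equals the configured
truth with ≈ 0.1-point residual bias, and the pipeline recovers the truth
within ±2 points per taxon at 10,000 scats. Items co-occur independently (no
taxon interactions), matching nothing deeper than the reported item-count
mix.

What passing these tests shows: the estimators are correct on data satisfying
their own assumptions. What they do not show: robustness to autocorrelated
movement, GPS error, unbalanced monitoring, scat decay/detection bias, or
prey whose remains violate the CF feeding-trial conditions — all properties
of real field data that the generators deliberately omit.

## Numerical details and degenerate inputs

- KDE evaluation is exact (chunked dense Gaussian sums), not binned or
  FFT-approximated; memory is bounded by chunking points.
- `href` requires ≥ 5 distinct points; identical points are an error.
- `mcp` requires ≥ 3 surviving points; removal count is a floor.
- Proportion vectors off by more than 1e-6 from sum 1 are rejected, not
  silently fixed.
- Logistic IRLS failures and mixed-model non-convergence raise with
  diagnostics rather than returning partial fits; complete separation
  surfaces as non-convergence.
- Chi-square requires strictly positive expected counts; expected cells
  below 5 log a warning.
- All randomness flows through `numpy.random.Generator` seeded from
  config/CLI seeds; identical seeds give byte-identical CSV/GeoJSON outputs.
  CSV headers carry the package version, seed, and a config hash; JSON
  carries the same under `_meta`; the ESRI ASCII grid format admits no
  comments, so `.asc` files are bare.

## Problem sizes used in the validation suite

Diet-truth recovery uses 10,000 scats; RSF recovery uses 100 replicates of 5
animals × 500 fixes with a 10:1 availability ratio (and 30:1 for the SE
coverage check, see above); blocked CV uses the 5-animal strong-selection
design; KDE/UDOI geometry checks use 1,000-point clouds on 256² grids and
single-kernel Gaussians on 400² grids. These sizes make every Monte-Carlo
tolerance in the suite comfortable for the seeds used while keeping the full
run around two minutes.

## Known limitations

- No autocorrelation-aware estimators (aKDE, dBBMM) and no CRS handling
  beyond requiring projected planar meters.
- The ad hoc bandwidth scan's contiguity check is grid-resolution dependent
  near the fragmentation threshold.
- Mixed-model SEs are Wald SEs from the Laplace profile over fixed effects;
  variance-component uncertainty is not propagated.
- The chi-square category scheme and the overlap category scheme for
  cross-predator comparisons are user choices; published values computed on
  unstated schemes cannot be targeted exactly.
- Dietary overlap with other predators requires their composition tables as
  input; none ship with the package.
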