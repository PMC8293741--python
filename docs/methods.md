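# Methods

## The analysis grid

All computation happens on one regular planar grid (default cell size
5 km) in a projected equal-area CRS, cell-center registered, row-major from
the north-west corner. Working on a planar grid rather than in geographic
degrees makes distances and areas exact and testable; the cost is that
users must supply inputs in (or resample them to) that CRS. Missing cells
are explicit (`NaN`); any arithmetic with missing yields missing, with one
documented exception in the index sum (below).

`resample_to_grid(..., method="area_weighted_mean")` computes, for each
target cell, the overlap-area-weighted mean of intersecting non-missing
source cells. Because cells are axis-aligned rectangles in a shared planar
CRS, overlap areas factor into row-interval × column-interval overlaps and
the operation is exact (it preserves the global mean of gap-free,
fully-overlapping grids to machine precision). Nodata at coastlines simply
propagates: a target cell with no overlapping valid source area is missing.

Buffers (`buffer_mask`) are computed on cell centers, not polygon edges: a
cell joins the buffer iff its center lies within the given Euclidean
distance (inclusive) of the center of any source cell. This is the natural
raster-pipeline convention; users accustomed to vector buffers should note
that a "5-km buffer" on a 5-km grid adds exactly the orthogonal-neighbour
ring. Distances use an exact Euclidean distance transform, so the
inclusive boundary is honoured without floating-point surprises.

Polygon membership (`rasterize`, protected areas, provinces) is by
cell-center containment with boundary cells counted as covered; overlaps
resolve last-listed-wins and are logged.

## Occurrence preparation

Three filters, in order:

1. **Deduplication** on (collector, collection number): later records with
   both fields equal to an earlier record's are dropped. Records missing
   either field carry no duplicate evidence and are never merged.
2. **Uncertainty gate**: records with stated positional uncertainty
   ≥ 5,000 m are removed (the bound is strict: 4,999 m survives). Records
   without the metadata are kept and counted in a warning — discarding them
   would throw away most herbarium data.
3. **Spatial thinning** to one record per grid cell, reducing collection
   bias toward roads and towns. Within a cell the record nearest the cell
   center wins, ties broken by input order; this tie rule is arbitrary but
   deterministic, which reproducibility requires. Thinning is idempotent
   and the retained count always equals the number of occupied cells.

## Predictor screening

The bioclim pre-screen keeps the `k = 3` most important
temperature-related and `k = 3` precipitation-related candidate variables
(importance from permutation importance averaged over a configurable
number of exploratory model runs), with ties broken in canonical BIO1–BIO19
name order; soil, radiation and terrain variables pass through unscreened.

VIF for a column is 1/(1 − R²) from the least-squares regression of that
column on all others with intercept (+∞ on perfect collinearity).
`vif_select` repeatedly removes the max-VIF variable — name-order
tie-break, so the outcome is invariant to column order — until all
remaining VIFs fall below the threshold (default 10). The sample over
which VIF is computed is the combined presence + pseudo-absence table, i.e.
the data the models actually see.

## Ensemble SDM

**Pseudo-absences.** Three independent sets, each a uniform random draw
without replacement of one third of the eligible background cells
(non-missing, not containing a presence). No exclusion buffer is applied
around presences.

**Runs.** For every learner × pseudo-absence set × replicate: a stratified
70/30 train/test split of the pooled presence/absence cells; class weights
on the training side equalise total presence and absence weight ("equal
weighting" by weights, not resampling, so no data are duplicated or
discarded); the fitted model is scored on the held-out 30% and predicts
suitability for every valid cell. All randomness descends from one master
seed through per-run seed sequences recorded on the run, so reruns are
bit-identical. A learner exception is recorded as a failed run and
excluded downstream, never silently dropped.

**Learners.** The orchestration is learner-agnostic behind a small adapter
contract (fit with sample weights → predict a [0, 1] suitability,
deterministic given a seed). Shipped adapters wrap a standardized
logistic regression (GLM role), gradient-boosted trees (GBM role) and
random forest (RF role); any classifier meeting the contract plugs in.

**Evaluation.** AUC is the rank-based Mann–Whitney form, exact under ties.
TSS is evaluated at the threshold maximising it over the midpoints of
consecutive unique scores (ties resolve to the lowest threshold; a single
unique score degenerates to TSS 0). Maximising TSS on evaluation data is
the conventional default when no operational threshold is prescribed; the
chosen threshold is logged per run. Permutation importance is the mean
over `n_perm` (default 10) permutations of 1 − Pearson r between
predictions on the original and the variable-shuffled training features,
clipped to [0, 1]; constant predictions are treated as "unchanged"
(importance 0, warned).

**Ensemble.** Runs with AUC ≥ 0.7 (inclusive) enter an unweighted
per-cell mean. The ensemble's own AUC/TSS are computed by reading the mean
map at each member's held-out cells, pooled across members — the pool is
the natural evaluation set when replicates each hold out different cells;
cells appearing in several members' test sets count once per appearance.

**Binarization.** The suitability threshold is the 10th percentile —
linear interpolation between order statistics, stated explicitly because
percentile dialects differ — of ensemble suitability at the presence
cells, so ≥ 90% of training presences (up to ties) fall inside the
predicted range.

## Threat index

Eight factors, each scored 0–10 per cell, summed (0–80), urban cells
masked to missing afterwards, then classified into fixed-width bands. The
printed breakpoints (20/40/60) are fixed equal-width bins of the 0–80
range, not data quantiles. Boundary convention: Low [0, 20), Moderate
[20, 40), High [40, 60], Very high (60, 80] — the value 60 belongs to
High, so both the "40–60" and "> 60" labels are honoured.

| factor | reference | highest threat | lowest threat |
|---|---|---|---|
| population saturation (persons/km²) | 1000 | 800 | 1200 |
| cropland cutoff (fraction) | 0.20 | 0.15 | 0.25 |
| road buffer (km) | 20 | 25 | 15 |
| overexploitation margin | 0 | −10% | +10% |
| tree-loss cutoff (fraction) | 0.20 | 0.15 | 0.25 |
| burn-trend buffer (km) | 5 | 10 | 0 |
| temperature saturation (°C) | 2.0 | 1.5 | 2.5 |
| precipitation saturation (mm) | 200 | 150 | 250 |

The population score is `min(10, 10/log10(sat+1) × log10(density+1))`.
The coefficient is derived from the saturation rather than hard-coded, so
each scenario saturates at exactly 10 (for the reference saturation the
coefficient is 10/log10(1001) ≈ 3.333). Climate scores are
`min(10, |Δ|/sat × 10)` with Δ the multi-model-mean future minus current
layer; both warming/wetting and cooling/drying count as pressure via the
absolute value. Threshold factors score 10 at or above the cutoff
(inclusive); overexploitation is strict (licensed > adequate × (1 +
margin)), so a province exactly at its adequate volume is not flagged.
Every scenario parameter is monotone in threat, so highest ≥ reference ≥
lowest holds cellwise for every factor score — asserted in the tests.

A factor layer missing in a cell contributes 0 to the sum there (the index
is a sum over the factors with coverage); each such gap is logged loudly
per layer. Sensitivity percentages (% changed / increased / decreased
class) are computed over cells non-missing in both maps, i.e. the
non-urban land area, and satisfy changed = increased + decreased exactly.

## Exposure overlays

Areas are cell counts × cell area (25 km² at the default resolution), so
they are exact integer multiples. A suitable cell whose threat class is
missing (urban-masked) is kept in the species' total area but reported
under an explicit `unclassified` bucket, so class areas always partition
the total. Protected-area membership is by cell-center containment,
consistent with all other polygon handling.

## Synthetic study system

The generator emulates the structure — not the geography or values — of
the real inputs: standardized Gaussian-smoothed random fields for
predictors (moving-average range in cells; lag-1 autocorrelation grows
with it); a virtual species with logistic Gaussian-niche response whose
intercept is calibrated by bisection to a target prevalence (default 0.15)
so the landscape contains both suitable and unsuitable habitat; presences
(default 150 on a 100 × 100 grid, two true niche variables with breadth
0.7 — a strong but not degenerate signal) sampled ∝ true probability; an
optional road-biased sampling mode (off by default) for studying
collection bias. Threat inputs: exponential-decay population kernels at
random towns (peaks up to 1,500 persons/km² so scores span the full 0–10
scale), random cross-grid road polylines, min-max-normalised fractional
cropland/tree-loss fields, an upper-tail blob mask for the burn trend,
nearest-seed (Voronoi-on-the-grid) provinces with harvest volumes drawn so
only some provinces breach the overexploitation rule under any scenario
margin, climate-model layers sharing one broad change pattern (scaled so
the multi-model mean reaches the saturating amplitude somewhere) plus
small per-model disagreement, and one-cell urban blobs at the larger
towns.

What passing tests on this system do show: the orchestration recovers a
known niche (ensemble suitability vs truth Spearman ρ > 0.8; the true
variables top the importance ranking in ≥ 80% of seeds), the scoring
algebra is exact, and all bookkeeping identities hold. What they do not
show: performance under real-world complications absent from the generator
— interacting niches, strong spatial sampling bias, label noise from
misidentification, non-stationary threat processes, or coastline/nodata
geometry.

## Numerical and scaling choices

- Tests and the pipeline default examples run replicate counts of 1–5 and
  grids of 40–100 cells per side; the replicate count is a parameter
  (`n_replicates`, production default 100) that changes variance, not
  logic — the run-count bookkeeping (learners × 3 sets × replicates) is
  asserted symbolically at full scale.
- Percentile, tie-break and boundary conventions are fixed and documented
  above precisely because dialect differences across GIS/stats platforms
  are the main source of irreproducibility in this kind of pipeline.
- Degenerate inputs error early and loudly (empty classes for AUC, fewer
  than the minimum presences, non-binary masks, out-of-range scores, ≠ 8
  index layers) rather than producing silently wrong maps.

## Known limitations

- No geodesy: inputs must share one projected equal-area CRS; no
  reprojection is performed.
- MaxEnt- and MARS-style learners are not shipped; the adapter contract
  accepts any such implementation but the package does not re-implement
  them.
- No spatial block cross-validation; evaluation splits are random
  stratified, which can be optimistic under spatial autocorrelation.
- The burned-area trend is consumed as a ready binary layer; trend
  estimation is out of scope.
- Binary GeoTIFF I/O is not provided; rasters are text ASCII grids, which
  are larger on disk but diff-able and dependency-free.
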