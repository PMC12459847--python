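# Methods

This note documents the models implemented in `esfringe`, their parameters
(units, defaults, rationale), what the synthetic landscape generator does and
does not emulate, the numerical choices made, and the known limitations.
Every quantitative claim here is computed by the test suite or the
acceptance script; nothing is asserted from external data.

## 1. Grids and units

Two nested planar grids share one origin (top-left corner, metres):

- the **coarse grid** (default 32 × 32 cells of 1000 m) carries the
  zonation features, zone maps and transition typology;
- the **fine grid** refines every coarse cell by an integer
  `refine_factor` (default 33, i.e. ~30.3 m subcells) and carries the land
  use, climate and ES layers.

1000 m is not an integer multiple of 30 m, so an exact 30 m subcell nested
in a 1 km cell is impossible; 33 × 33 subcells per cell is the closest
integer refinement and keeps every aggregation exact (block means, `np.kron`
broadcasts). Rasters are stored as ESRI ASCII grids (plain text) with NaN
mapped to a −9999 sentinel; villages and POIs are GeoJSON; tables are CSV.

## 2. Synthetic landscape generator

The generator (`esfringe.synthetic`) produces a deterministic two-date
landscape from one seed via `numpy.random.SeedSequence` spawning, so every
stage has ground truth.

What it emulates:

- a **monocentric-to-polycentric urban gradient**: intensity surfaces
  (population, GDP, nighttime lights) decay exponentially with distance to
  urban cores, `50 + 8000·exp(−d/λ)` for population, with multiplicative
  log-normal noise (`noise_sd`, default 0.1);
- **zone truth** from distance thresholds: urban within `urban_radius_cells`
  (default 4) of a core, fringe within `fringe_radius_cells` (default 8),
  rural beyond. At the second date both radii grow
  (`fringe × (1 + e)`, `urban × (1 + 0.25·e)` with expansion factor
  `e = 0.5`), so fringe expansion outpaces urban expansion, and the decay
  length grows with it — the study condition the pipeline analyses;
- **land use** (7 classes) from the distance score plus smoothed noise
  fields, so built-up land concentrates near cores and natural land in the
  hinterland; contiguous water patches are grown by randomised BFS to a
  target `water_fraction` (default 0.08);
- **villages** as a Voronoi tessellation of the coarse grid around random
  sites (default 90), the aggregation units for all village-scale analysis;
- **POIs** (default 800) placed with probability proportional to urban
  intensity, with five categories;
- **planted ES bundle archetypes**: seven named mean profiles in [0,1]⁸
  with Gaussian within-archetype noise (`within_sd`, default 0.05) and a
  contrast-scaling `clip(0.5 + separation·(m − 0.5), 0, 1)`, used to
  validate bundle recovery against known truth.

What it does **not** emulate: real census/economic magnitudes, seasonality
or weather sequences (climate layers are smooth spatial gradients), road
networks, policy constraints, multi-date land-use path dependence beyond the
two snapshots, and any specific real region. Generator defaults are the
study conditions; they are never adjusted to make tests pass.

## 3. Zonation

Six features per 1-km cell, computed from the fine layers:

| feature | definition | notes |
|---|---|---|
| population density | block mean of the fine layer | persons/km² (synthetic scale) |
| GDP density | block mean | currency/km² (synthetic scale) |
| PLAND | % of valid fine cells that are construction land | 0–100 |
| nighttime lights | block mean | dimensionless intensity |
| fragmentation `W` | Shannon entropy `−Σ Xₙ ln Xₙ` of land-type shares | nats; 0 for a single type, ln n at a uniform n-type mixture |
| POI function score | category-weighted Gaussian kernel density (bandwidth 1000 m), min-max rescaled to [0,100] | category weights default to equal (no defensible prior); configurable |

Large water bodies are masked first: 4-connected water components with area
strictly greater than `min_water_km2` (default 1 km²; the comparison uses a
1 + 1e−9 relative guard so float accumulation cannot drop an exactly-1 km²
component). Cells more than half covered by masked water are excluded.

The classifier is a scikit-learn `MLPClassifier`, hidden layers (128, 64),
ReLU, Adam with learning rate 0.001, batch 32, stratified 80/20 train/test
split on the labeled sample points (default 1000 points). scikit-learn has
no dropout layers; regularisation is realised as an L2 penalty
(`alpha = 1e-4`) plus early stopping instead — an architectural substitution,
documented, not tuned. Features are standardised with training-set moments.

Transitions between the two zone maps are typed into five classes
(urban/fringe maintenance, urban expansion = fringe→urban, fringe expansion
= rural→fringe, rural retention); backward moves are excluded. A direct
rural→urban jump is not one of the five named types: it counts as urban
expansion by default (`rural_to_urban="excluded"` switches it off). The
3 × 3 zone transfer matrix is row-normalised over cells valid at both dates;
absolute areas in km² are reported alongside.

## 4. Ecosystem-service models

All on the fine grid; negative outputs are clamped to 0 (counted and
logged), masked cells become NaN.

- **Food production (FP)**: Thornthwaite-Memorial standard production
  potential, `W_T = 30000/(1 + e^{1.315 − 0.119T})`,
  `W_R = 30000·(1 − e^{−0.000664R})`,
  `W_V = 30000·(1 − e^{−0.0009695(V − 20)})` with
  `L = 300 + 25T + 0.05T³`, `V = 1.05R/√(1 + (1.05R/L)²)`,
  `W = min(W_T, W_R, W_V)`; T in °C, R in mm/yr, W in kg DM/(km²·yr)
  scale. The multiplicative forms keep `W` bounded by the 30000 ceiling and
  increasing in T and R (both verified by property tests); an alternative
  division form of `W_R`/`W_V` is available behind `printed_form=True` but
  is unbounded and decreasing, so it is not the default. FP = `W · Kᵢ` with
  a land-use coefficient table (cropland 0.85 … bare 0.01).
- **Carbon storage (CS)**: per-class sum of four pools (above, below, soil,
  dead; Mg C/ha), lookup per fine cell.
- **Water yield (WY)**: `max(P − AET, 0)` in mm/yr; AET is a land-use
  fraction of potential ET.
- **Soil conservation (SC)**: `R·K·LS·(1 − C·P)` (retention form of RUSLE);
  zero when `C·P = 1`, linear in erosivity.
- **Nutrient export (TN, TP)**: source strength (HSS) × pollution delivery
  factor, per nutrient. These are *disservices*: more export is worse.
- **Habitat quality (HQ)**: threats (built-up weight 0.7, range 3000 m;
  cropland 0.3, 1000 m) decay linearly with distance to give degradation
  `D ∈ [0,1]`; `Q = H·(1 − D²/(D² + k²))` with half-saturation `k = 0.5`
  and per-class suitability `H`. `Q(D = k) = H/2` exactly.
- **Landscape aesthetics (LA)**: generator-provided [0,1] proximity score
  (urban-amenity oriented), passed through.

## 5. Village-scale interactions

ES layers are averaged over village cells (NaN-aware; villages that end up
empty after masking are dropped with a log message). Indicators are min-max
normalised **pooling both dates**, so temporal change survives normalisation
(a per-date option exists). Spearman matrices are computed for per-date
levels, for temporal changes (t1 − t0), and for changes stratified by
transition type; strata with fewer than 5 villages are rejected,
zero-variance indicators give NaN with a warning. The implementation is
`scipy.stats.spearmanr` and is verified to 1e-12 against an independent
rank-then-Pearson oracle.

## 6. Coupling coordination degree

For the CCDM the two disservices are inverted (`1 − u`) so that "more" is
always "better"; raw orientation is kept for the correlation analyses.

- Coupling `C`: the geometric-to-arithmetic mean ratio of the eight
  normalised indicators, which satisfies the model's stated contract —
  `C = 1` exactly when all indicators are equal and `C = 0` when any is
  zero (both asserted in tests). A nested-product variant is available
  behind `coupling_variant="printed_product"`, but it violates the equal-
  indicators contract (it cannot reach 1), so it is not the default.
- Composite `T`: weighted sum with weights 0.12 for seven indicators and
  0.16 for habitat quality (sums to exactly 1.00).
- Coordination `D = C·T` (a `sqrt_product` variant √(C·T) is available).
- Six levels on half-open intervals: [0, 0.2] F extreme incoordination,
  (0.2, 0.4] E moderate incoordination, (0.4, 0.5] D mild incoordination,
  (0.5, 0.6] C low coordination, (0.6, 0.8] B good coordination,
  (0.8, 1] A high-quality coordination.

Level changes between dates form a 6 × 6 row-stochastic transfer matrix.
The standard deviational ellipse (weighted mean + covariance
eigendecomposition; semi-axes are the standard deviations along the
principal directions, orientation in [0°, 180°)) summarises villages with
`D ≤ 0.5` per date, falling back to uniform weights when none qualify.

## 7. ES bundles

Village vectors (eight indicators, nutrient exports inverted to
purification scores TNp/TPp) are clustered with a bespoke online
self-organizing map: square lattice sized by the ⌈√(5√n)⌉² heuristic,
sample-based initialisation with small jitter, Gaussian neighbourhood, and
linear decay of learning rate (0.5 → 0.01) and radius (max(dim)/2 → 0.5)
over 500 epochs. For each candidate count k in 2–15 the *occupied* codebook
nodes are Ward-agglomerated (dead interpolating nodes carry no villages and
would distort the merge structure); villages inherit their best-matching
node's group, and the Davies–Bouldin index of the induced village partition
— implemented from the definition and verified against both a brute-force
oracle and `sklearn.metrics.davies_bouldin_score` to 1e-9 — selects k (ties
toward the smaller k).

Clusters are named from their mean profiles by a rule cascade over seven
bundle classes (thresholds: high ≥ 0.6, low ≤ 0.3), with a
nearest-archetype fallback that records its rule trace. Bundle changes
between dates are 7 × 7 row-stochastic transfer matrices, overall and per
transition type.

On planted archetypes (separation 3, within-archetype sd 0.05, 20 villages
per archetype, 10 seeds) the selection recovers the planted count of 7 as
the modal k with mean adjusted Rand index ≥ 0.9; on individual seeds the
Davies–Bouldin index itself can marginally prefer a 6-cluster merge, which
is a property of the index, not an implementation error.

## 8. Determinism and numerical choices

- One global seed drives every stochastic stage through
  `SeedSequence`-derived sub-seeds (all < 2³¹).
- Rerunning a pipeline from its manifest reproduces every output file
  byte-for-byte (SHA-256 hashes asserted in tests).
- Rasters are written with `%.17g` so float round-trips are exact.
- Entropy uses natural logarithms with `0·ln 0 := 0`.
- Classifier prediction ties resolve to the lower class code; cluster
  labels are renumbered 1..k by first appearance.

## 9. Limitations

- Everything is synthetic: magnitudes (yields, carbon densities, nutrient
  loads) are on plausible but arbitrary scales, and no claim transfers to a
  real region without recalibration on real rasters.
- The ES models are the closed-form reduced forms above, not full InVEST
  runs (no flow routing, no seasonal water balance, no valuation).
- Dropout is approximated by L2 + early stopping (scikit-learn constraint).
- Village polygons are unions of 1-km cells, so boundaries are blocky.
- The SOM is an online implementation; training cost grows with
  villages × nodes × epochs, which is fine at the default scale (≤ a few
  hundred villages) but not tuned for very large inputs.
- The coupling degree compresses eight indicators into one number; the
  default GM/AM form was chosen for its boundary contract, not derived
  from first principles.
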