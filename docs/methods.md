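# Methods

## The maximum-entropy model

Given presences and a background sample drawn from the landscape, the model
is the Gibbs density `q(x) = exp(λ·f(x)) / Z` over background cells whose
L1-penalized presence log-likelihood

```
ℓ(λ) = mean_p[λ·f] − log Σ_bg exp(λ·f) − Σ_j β_j |λ_j|
```

is maximal.  The problem is convex; we solve it by the standard split
`λ = λ⁺ − λ⁻` with non-negativity bounds, which turns the L1 term into a
smooth linear one, and run L-BFGS-B to a subgradient-optimality residual of
1e-6 (max 500 iterations).  A fit that terminates abnormally with a
residual above 1e-2 raises a convergence error carrying that residual.
Optimization is deterministic given the input tables.

**Features.**  Covariates are min–max scaled to [0, 1] over the background
and clamped to that range at prediction time (projection onto novel
climates therefore never extrapolates features).  Classes: L (scaled
covariate), Q (square), P (pairwise products), H (forward hinge
`max(0, x−t)/(1−t)` at knots t = 0, 1/m, …, and reverse hinge at the
mirrored knots), T (step indicators at m evenly spaced thresholds).  The
default knot count is 20 per covariate — about half of what the classical
Java implementation uses — as a complexity/speed compromise; it is a
parameter.  Zero-range covariates produce constant features that are
flagged and receive no weight.

**Penalties.**  `β_j = RM · β_class(n_presence) · sd_bg(f_j) / √n`, with
per-class base penalties interpolated over presence count in a simplified
form of the published defaults (L/Q/P: 1.0 → 0.2 → 0.05 at n = 10/30/100;
H: 0.5 throughout; T: 2.0 → 1.0 at n = 10/100).  The exact historical
lookup tables are deliberately not replicated: the regularization
multiplier RM is tuned anyway, which absorbs the difference.  A floor of
1e-6 keeps every penalty strictly positive.

**Output transforms.**  raw is the fitted density over the training
background (sums to 1 there).  With H the entropy of that density,
`logistic = e^H·raw / (1 + e^H·raw)` and `cloglog = 1 − exp(−e^H·raw)`;
both are monotone in raw and map a background cell of average density to
0.5 and 1 − 1/e respectively.  Cloglog is the default for all
classification and area accounting (the modern convention); logistic is a
flag.

**Background.**  By convention the training background includes the
presence cells (the pipeline concatenates them); the standalone fitting
function takes the tables as given, so either convention is available.

## Model selection and evaluation

Candidates are the cross of RM values {0.5, …, 4.0 step 0.5} and FC
strings {L, LQ, LQH, LQHP, LQHPT} — 40 models.  Each is scored by AICc
with the likelihood of the raw density renormalized over the background
sample (the background stands in for the full landscape grid; at the
simulator's scale the background effectively *is* the grid, which is the
one place this implementation knowingly diverges from tools that normalize
over every landscape cell).  k counts coefficients with |λ| > 1e-8; AICc
is undefined and the candidate disqualified when n ≤ k + 1.  The minimum
AICc wins; exact ties break by fewer parameters, then lower RM, then grid
order — a single winner is required for pipeline determinism, where other
tools would report all tied candidates.

Cross-validation partitions presences into k random folds (default 10;
spatial-block partitioning is out of scope), draws a fresh background of
up to 10,000 valid cells per fold, fits on the k−1 training folds and
scores the held-out fold by rank-based (Mann–Whitney) AUC against that
background.  The final map is the mean of the k fold models' transformed
predictions.  AUC uses midranks for ties and is invariant under any
monotone transform of the scores.

## Occurrences, predictors, rasters

Cleaning removes out-of-range coordinates, the (0, 0) artefact, exact
duplicates (coordinates rounded to 6 decimals), off-grid points and points
on nodata cells, each with a logged reason code.  Thinning keeps the first
record per grid cell (a seeded random choice is available) and is
idempotent.  Cell ownership is half-open — an edge point belongs to the
cell to its lower-right in index space — so the tiling is unambiguous.

Collinearity screening computes pairwise Pearson correlations over a
seeded sample of up to 10,000 valid cells and prunes greedily in the order
of an explicit priority list: a variable is kept iff |r| < 0.8 (inclusive
cutoff at the threshold) against every variable already kept.  Variables
in `always_keep` (default elevation and slope, which carry terrain
information macroclimate does not) bypass the filter; `always_drop`
(default aspect) never enters.  Formalizing the survivor choice as a
priority list replaces the subjective "ecological relevance" judgement
with a reproducible rule.

Rasters are ESRI ASCII grids on a north-up geographic grid with square
cells; values are float64 in memory and round-trip the ASCII format
losslessly.  Cell areas use the spherical band formula
`A = R²·Δλ·(sin φ_top − sin φ_bottom)` with R = 6371 km — a sphere rather
than an ellipsoid, chosen for a closed, testable form; the error against
WGS84 areas is well under the rounding of the reported 10⁴ km² tables.
Slope and aspect come from Horn's 3×3 kernel with metric, latitude-scaled
horizontal distances; aspect is the downslope compass bearing in [0°,
360°), flat cells (|∇z| < 1e-8) are flagged, and border or nodata-adjacent
cells are nodata.

## Range analytics

Classes at p = 0.2 / 0.4 / 0.6 are left-closed (p = 0.2 is "low",
p = 0.6 is "extreme"); the binary range uses the same inclusive p ≥ 0.2
bound, so binary suitability coincides exactly with class ≥ low.  Percent
change is computed from full-precision areas and rounded only for display,
with an undefined marker (never ±∞) when the baseline class is empty.
Centroids are cell-area-weighted mean centers in geographic coordinates
(a suitability-weighted variant is a flag); shift distances are haversine
on the R = 6371 km sphere.  Mean-center tools operating in a projected
CRS will differ from the geographic computation by a few parts per
thousand at sub-continental extents — no attempt is made to match any
particular projection.  Two-species overlap is the intersection area as a
percentage of the **union** of the two ranges, `100·I/(A + B − I)`.

## The virtual-species simulator

Each predictor layer is a mixture of a smooth latitudinal/longitudinal
gradient and moving-average-smoothed white noise (window 9 cells); the
standardized fields are QR-orthonormalized and re-mixed through the
Cholesky factor of the requested correlation matrix, so realized pairwise
correlations match the request essentially exactly (an infeasible,
non-PSD request is rejected).  The first layer is temperature-like: it
decreases toward the poleward edge, so a uniform warm shift moves the
optimal band poleward — the property the centroid-shift tests rely on.
Layers are scaled to climate-plausible spans (°C-scale temperatures,
mm-scale precipitation, m-scale elevation).

True suitability is the product of per-layer Gaussian responses,
normalized to a maximum of 1.  Presences are cells drawn without
replacement with probability proportional to truth (optionally times a
bias surface), jittered uniformly within the cell.  Future stacks apply
`layer × scale + shift` per layer.

What the simulator does *not* emulate: real spatial sampling bias,
observation error in coordinates, non-Gaussian or interacting responses,
dispersal limitation, and real climate fields' cross-scale structure.
Passing the recovery tests therefore shows the estimator chain is
self-consistent and unbiased under its own assumptions, not that any
particular real-world prediction is right.

## Default problem sizes and seeds

The default synthetic grid is 100 × 100 cells at 0.05° (10,000 cells) with
5 layers and 200 presences; the end-to-end recovery checks tune over the
reduced grid {1.0, 1.5} × {L, LQ, LQH}.  These sizes keep a full
simulate–tune–fit–project–report cycle in the tens of seconds on one core
while leaving the 10,000-point background convention meaningful (the
background is then an exhaustive sample of the valid cells).  All
randomness flows from a single root seed through `numpy.random
.SeedSequence` spawns, so every stage is independently reproducible.

## Known limitations

- Only the ESRI ASCII raster dialect is supported; no reprojection.
- No categorical features, sampling-bias grids, or spatial-block CV.
- AICc normalizes over the background sample rather than every landscape
  cell (see above); with a background that covers the grid the two agree.
- The β sample-size schedule is a documented simplification of the
  historical defaults; RM tuning compensates.
- Percent agreement with range tables computed in projected coordinates
  is bounded by the geographic-vs-projected centroid difference (~0.3%
  at the extents tested).
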