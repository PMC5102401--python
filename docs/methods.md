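# Methods

This note documents the models and procedures implemented in `reefprior`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not represent.

## Synthetic reefscape generator

The generator emulates the statistical structure of hierarchically
classified geomorphic reef maps on a raster of square cells (default
0.2 km side, so a 1 km² planning unit is a 5×5 cell block and a 25 km²
unit a 25×25 block).

**Reef geometry.** `n_patches` contiguous reef patches are grown by
seeded stochastic 4-connected accretion until a target fraction of cells
is reef (patches may merge on crowded grids; each grown patch is
4-connected). Cells interior to a patch carry reef fraction 1; boundary
cells draw a fraction from U(0.3, 1), so planning units clipped to reef
edges have continuous areas.

**Hierarchical classes.** Class labels are assigned by recursive spatial
subdivision: the reef is split into the level-1 classes, each level-1
region into its level-2 children, and so on, with child counts allocated
to parents roughly proportionally to parent area. Each split is a
weighted Voronoi partition with Pareto-distributed seed weights
(`rarity_skew`, default 1.2), producing blocky, spatially coherent
regions whose extents are left-skewed — many restricted classes, few
extensive ones. One class is a union of up to `class_patchiness`
(default 3) disjoint chunks inside its parent region: real geomorphic
classes recur across a reefscape (every atoll has a rim), and this
recurrence is what gives a cost-aware solver genuine spatial choice even
at fine thematic levels. Levels 1–3 and 5 are strictly hierarchical; at
level 4 a fraction `level4_sharing` (default 0.25) of branches reuses a
label from a branch under a different level-3 parent, so the level-4
layer is deliberately not uniquely hierarchical within level 3 (the
distinct level-4 label count may fall below the branch count). Level-5
classes always nest inside a single (level-3, level-4) branch.

**Cost layers.** The uniform layer is reef area itself. The variable
layer is a proxy for fishing opportunity cost: cell cost is
`Σ_centres pop · max(1e-6, 1 − d/decay_radius_km)` with `d` the
Euclidean distance to a fisher population centre in km — cost is maximal
beside large populations and declines linearly, floored so it never
reaches zero. This linear decay is a declared stand-in for
census-derived distance surfaces; its functional form is a module
parameter and alternatives can be swapped in. Per planning unit the cell
surface is aggregated as an area-weighted sum by default (a constant
surface then reduces exactly to cost ∝ area); `mean` and `centroid`
aggregations are provided because the field does not agree on a single
summary.

**What the generator does not emulate.** Satellite-image classification
noise, vector coastlines, bathymetry, anisotropic fishing behaviour, and
the absolute scale of real planning regions (tens of thousands of km²).
Passing tests on synthetic data therefore demonstrate the correctness
and internal logic of the pipeline and the direction of the factorial
effects, not the magnitudes any particular real region would produce.

## Reserve-selection solver

The minimum-set objective is `Σ_{i∈S} c_i + Σ_f spf_f · s_f/T_f` with
`T_f = prop · total_f` (default `prop = 0.30`) and `s_f` the shortfall.
Normalising shortfalls by targets replaces Marxan's internal
cost-to-represent penalty estimate with a scale-free equivalent;
calibration makes the two operationally interchangeable, since both are
tuned until targets are met. The boundary-length modifier is fixed at
zero (solution compactness is not part of this experiment).

**Annealing.** Initial selection includes each unit with probability
0.5; each iteration proposes flipping one uniformly random unit,
accepting improvements always and deteriorations with probability
`exp(−Δ/T)`; temperature decays geometrically from `t_initial` to
`t_final`. The kernel remembers the best state visited during the walk:
the walk's endpoint is a sample from the final-temperature distribution
frozen in an arbitrary basin, whereas the best visited state is
systematically closer to the optimum, and the subsequent strict-descent
sweeps (random unit order, first improving flip taken, repeated until a
sweep changes nothing or `improvement_passes` is reached) start from it.
Problem-scaled default temperatures run from 2× down to 0.05× the mean
unit cost: warm enough initially to accept typical single-unit cost
increases, cold enough finally that only near-neutral moves pass. The
library default schedule is 10⁵ iterations; the factorial experiment
uses 10⁴, which suffices at its problem sizes (≤ ~400 units). On random
≤ 18-unit instances the solver reproduces the exhaustive optimum.

**Calibration.** Species penalty factors start at the mean unit cost;
after each round of `R_cal` replicates, any class whose minimum achieved
proportion of target is ≤ 0.999 has its spf doubled, capped at 20
rounds (then the offending classes are named in the error). The
scenario runner calibrates with `R_cal = R` on the scenario's own
replicate seeds and reports the final round's solutions, so the
calibration guarantee — every class above 99.9 % of target in every
reported solution — holds by construction. Observed calibration depth on
the default experiment is 8–15 rounds.

**Seeding.** Scenario seeds are derived as
`sha256(experiment_seed:code) mod 2^30`, replicate *r* uses
`scenario_seed + r`, and the annealing kernel consumes a single seeded
stream — any individual solution is reproducible in isolation.

## The factorial experiment

Default study conditions: a 100×100-cell reefscape (20×20 km, 16
large-unit slots), reef fraction 0.6 in 5 patches, class counts
(2, 4, 8, 12, 20) across the five levels, 3 fisher population centres
with log-uniform sizes in [5, 200] and a 10 km decay radius, R = 100
replicates per scenario, 10⁴-iteration schedules. These sizes keep a
full 20-scenario run around half a minute on one CPU while leaving the
large-unit grid non-degenerate (nestedness and trend analyses need more
than a handful of large units). Scenario codes follow
size letter + level digit + cost letter (S1U … L5V).

Reported per solution: reserve extent (km²) and cost as a proportion of
the maximum possible cost, i.e. the summed cost of every planning unit
of that size under that layer — this normalisation makes uniform- and
variable-cost scenarios directly comparable.

## Multivariate comparison

Solutions are rasterised to small-unit resolution (a large unit
broadcasts its value — binary selection or selection frequency — to its
nested small units, 25 at most), stacked into a solutions × units
matrix, and Hellinger-transformed (`√(x/rowsum)`), which bounds
Euclidean distances between presence/absence rows by √2 and makes the
zero-inflated matrix usable with Euclidean-based ordination. Distances
feed UPGMA clustering (scipy's average linkage; merge heights are
monotone). The RDA centres the matrix by columns, regresses it on the
reference-coded design factors (intercept plus dummies), and
eigen-decomposes the fitted values; eigenvalues and variances are on the
covariance scale (SS/(n−1)), and the share of constrained variance on
the first two axes is reported over constrained — not total — variance.

The permutation test decomposes the constrained variance sequentially
(type I) in the fixed order cost variability, planning-unit size,
thematic resolution — degrees of freedom 1, 1, 4 — with
`F = (SS_term/df) / (SS_resid/df_resid)` and p-values
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` from freely permuting the rows
of the response (not residuals under a reduced model; rows-of-Y
permutation is exact under the null of full exchangeability tested
here). The decomposition order is a parameter. The implementation is
verified against R vegan's `rda`/`anova(by = "terms")` on a frozen
fixture and calibrated under the null (type-I error at α = 0.05 inside
the binomial confidence band over 200 simulations).

## Nestedness and incidental representation

High-priority sets take all small units with selection frequency at or
above an inclusive threshold (50 and 75 of 100 by default, scaled
proportionally for other R; large-unit frequencies are broadcast first).
Nestedness of a fine "test" scenario inside a coarse large-unit scenario
is `100 · |test ∩ coarse| / |test|` — directional, the denominator is
always the test set, and an empty test set is an error distinct from a
true 0 %. The default comparison grid crosses the 10 large-unit
scenarios with the two finest small-unit scenarios (S5U, S5V) at both
thresholds.

Expected incidental representation converts large-unit selection
frequencies to probabilities `P = freq/R` and accumulates `P ·
class area` per level-5 class; rarity is `(1 − class extent / total
planning extent) · 100` with the total taken over reef (the planning
region is clipped to reef). All arithmetic is done in full precision;
the 3-decimal rounding of exports uses round-half-away-from-zero, because
IEEE doubles make naive rounding of values like 0.17775 fall to 0.177.

## Numerical and degenerate-input conventions

Grids must be exact multiples of the 25-cell large-unit span (no ragged
tiling). Zero-reef planning units are dropped before the solver runs; an
entirely reef-free raster yields an empty grid with a warning. Brute
force enumeration refuses more than 20 units; its ties are broken toward
fewer units, then the lexicographically smallest id set. Iterative
improvement requires a strict decrease (> 1e-12) to accept a flip.
Hellinger rejects all-zero rows; the RDA rejects rank-deficient designs
naming the aliased terms.

## Known limitations

- Variable cost is a single isotropic distance proxy; no travel-cost
  surfaces or market effects.
- The annealing schedule is fixed-length geometric, not Marxan's
  adaptive schedule; equivalence is empirical (oracle tests), not
  structural.
- Class chunk placement is Voronoi-based and ignores depth zonation, so
  within-parent class adjacency patterns are simpler than real
  geomorphology.
- The permutation test treats rows as freely exchangeable; replicates
  within a scenario share a calibrated spf vector, which real data
  analyses might prefer to handle with restricted permutations.
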