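# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The stem-age rate estimator

The per-family diversification rate is r = ln(N)/t with N the extant
species richness and t the stem age (Myr). It assumes a pure-birth history
(extinction fraction ε = 0) from the stem lineage's origin and is known to
be biased — in particular it cannot distinguish a rate slowdown from a
constantly low rate, and it compresses toward zero for monospecific
families (ln 1 = 0 regardless of age). It is used here deliberately: it
needs nothing but a count and a stem age, so it works on family-level
trees with unresolved or imputed terminal structure, and the downstream
analysis only consumes broad rate *quantiles*, not precise rate values.
Crown-age or extinction-corrected estimators are out of scope.

Stem ages are summarised across the tree set by the per-family **median**
(the default), because node-age distributions across posterior trees are
strongly right-skewed; the mean is available via `use_median=False`.
An even-length median is the mean of the two central values.

## Quantile binning

Families are sorted ascending by (rate, family name) — the name being a
deterministic tie-break, relevant because monospecific families tie at
exactly 0 — and cut into k = 5 equal-count rank bins. When n mod k = m ≠ 0
the extra members go to the lowest-index bins (sizes ⌈n/k⌉ for bins 1..m).
Rank bins rather than interpolated quantile breakpoints are used because
the permutation null needs fixed per-bin membership counts. Binning is
invariant to input order.

## MPD and the permutation null

MPD of a tip set is the mean patristic distance over its unordered pairs;
distances are computed by a single post-order sweep (O(n + m²) for m
tracked tips), validated against dendropy's implementation and a
brute-force path-sum oracle. The null reassigns all families to bins of
the observed sizes uniformly at random; size preservation is what isolates
phylogenetic placement from bin size. With 1000 replicates the 95%
envelope is the symmetric nearest-rank interval — the 25th and 976th order
statistics — giving exact two-sided coverage 951/1001 ≈ 95.0% for an
exchangeable observation; `divarrest.calibration` measures this coverage
by simulation, and the acceptance script reports it.

Per-tree envelopes are computed with per-tree random streams spawned
deterministically from the master seed (results are independent of
iteration order); a pooled envelope over all replicates of all trees is
also reported. A quantile is flagged overdispersed/clustered on a tree
when its observed MPD is above/below that tree's envelope.

The MPD-vs-quantile trend over the tree set is summarised by Spearman rank
correlation of (quantile index, MPD) pooled over trees, with a two-sided
permutation p-value that redraws the quantile labels (default 1000
redraws). This particular trend statistic is this package's convention;
constant MPDs yield p = 1 with a degeneracy flag.

## The pure-birth simulation null

Family boundaries are a taxonomic convention, so the package also builds a
geometry-only null. Yule trees are grown from a single origin lineage:
with k extant lineages the waiting time to the next split is
Exponential(kλ) and the splitting lineage is uniform; growth stops at the
instant the n-th tip appears (so the two youngest sibling tips have
zero-length branches — the `extend` option instead adds one
Exponential(nλ) grace period). The origin→root interval is retained as the
seed-edge (stem) length, and `tree_height(include_stem=True)` measures
from the origin; the mean origin-to-tip height of an n-tip tree at rate λ
is then the harmonic sum (1/λ)·Σ_{k=1}^{n−1} 1/k, which the tests verify
by Monte Carlo.

Each simulated tree is rescaled to a target clade age (one rescaling per
empirical clade age of interest, supplied as a list in the run
configuration) and sliced at fraction 0.8 of its root age: every branch
whose parent node is older than the slice and whose child node is at or
below it founds a family; a node exactly on the slice belongs to the
rootward side (a measure-zero event fixed for reproducibility). Family
richness is the branch's descendant tip count (richnesses sum exactly to
n); family stem age is the parent node's age. The 0.8 cut-off approximates
the empirical ratio of family age to total clade age. MPD per quantile is
measured on the derived family-level tree, whose tips run from each
crossing branch's parent node to the present; the implementation computes
those distances directly as 2·(root age − MRCA depth) on the rootward part
of the tree. Simulations yielding fewer than 2k families (each quantile
needs ≥ 2 members for MPD) are redrawn, logged and capped at 100 redraws.

Reference settings are 1000 simulations of 10,000 tips; the acceptance
test verifies quantile invariance at a reduced size (200 simulations of
2000 tips, Kruskal–Wallis at α = 0.01 plus interquartile-range overlap),
chosen so the whole suite stays cheap while keeping ~400–500 families per
simulated tree.

## The synthetic-data generator

The generator emulates the statistical structure of the empirical inputs;
its defaults are the package's reference conditions.

**Trees.** A real family-level tree is the rootward part of a species
tree: pendant edges are family stem ages, which are deep splits. The base
tree is therefore obtained by growing a Yule tree with 4× the requested
number of tips and slicing it at the midpoint of the interval during which
exactly `n_families` lineages existed; with the 4× factor the resulting
stem ages start at roughly the last fifth of the clade age, matching the
family-age/clade-age ratio seen in real family trees. (A plain Yule tree
of `n_families` tips was rejected: its near-zero pendant edges produce
near-zero stem ages, which make ln(N)/t degenerate and phylogenetically
correlated — sister tips share their stem age — contaminating the lowest
quantile.) The base tree is rescaled to `tree_depth` (default 200 Myr) and
replicated `n_trees` times with multiplicative LogNormal(0, `age_jitter`)
noise on internal node ages (default 0.1), clipped in preorder to keep
children younger than parents; replicates are ultrametric by construction
and per-family stem ages are right-skewed across replicates, as in
posterior samples.

**Richness.** Each family receives an iid target rate
r = r_group · LogNormal(0, `rate_spread`) (defaults: r_low = 0.005,
r_high = 0.08 /Myr for the "arrested" fifth and the rest respectively,
spread 0.3) and richness N = max(1, round(exp(r·t) · LogNormal(0,
`richness_dispersion`))) (default dispersion 0.4), so realized ln(N)/t
clusters around the targets, the two groups separate cleanly, and richness
spans orders of magnitude. The per-family spread matters: with a single
shared group rate, the realized ranking reduces to noise/t, whose variance
structure is phylogenetically heritable and plants spurious clustering in
the extreme quantiles even under the random regime.

**Planted regimes.** The arrested set is placed on the tree set's *mean*
patristic distance matrix (the shared structure the replicates jitter
around): `planted_overdispersed` uses greedy MPD maximisation (start from
the most distant pair, repeatedly add the tip with the largest total
distance to the selection, then deterministic 1-swap local search — exact
maximum-dispersion subset selection is NP-hard; the greedy solution
attains the multistart local-search optimum in our checks);
`planted_clustered` packs the set into the clade whose size best matches
(topping up with the phylogenetically nearest outside tips, warning when
no clade is within a factor 2); `random` applies a uniform permutation.

**Ranges.** Bounding boxes with log-normal extents (median 8°); in the
congruent scenario each quantile's families draw centres around a shared
cluster centre (s.d. 10°), in the incongruent scenario centres are uniform
worldwide. Boxes are clipped to the geographic bounds.

What the generator does **not** emulate: real clade shapes and
imbalance beyond Yule geometry, topological uncertainty across replicates
(node-age jitter only, unless NNI noise is enabled), non-monophyly,
range-shape complexity (boxes only) and range-size/latitude correlations.
Passing tests therefore demonstrate correct recovery of planted structure
under these idealised conditions, not performance guarantees on empirical
data.

## Spatial conventions

Geographic (unprojected) grid at 1°, origin (−180, −90), cells half-open
in both axes; geometries crossing the antimeridian are split before
rasterization. Presence is "geometry intersects the open interior of the
cell" (any positive overlap counts; boundary touching does not) — an
unambiguous and conservative choice for narrow ranges at 1°; a
centre-within rule is available for sensitivity checks. Axis-aligned
boxes use exact index arithmetic; other geometries use interior/interior
DE-9IM predicates, repaired with `make_valid` and excluded (with a
warning) when irreparable. Quantile richness grids are column sums of the
presence matrix, so they add exactly to the all-family grid. No
quantitative congruence statistic is computed; comparison of the maps is
deliberately qualitative.

## Numerical conventions and degenerate inputs

- Ultrametricity: relative root-to-tip depth spread ≤ 1e-6 accepted
  silently, ≤ 1e-3 with a warning (posterior trees carry rounding noise),
  larger is an error.
- Pruning a species-level tree keeps, per family, the lexicographically
  smallest species name (deterministic; stem age is unaffected for
  monophyletic families) and relabels it with the family name; suppressed
  degree-2 nodes sum their edge lengths, so root-to-tip paths are
  preserved. Non-monophyletic families keep the chosen representative and
  drop the rest, with a logged warning.
- MPD of fewer than two tips is an error, never silently zero.
- One master seed fans out to named substreams per stage and per tree, so
  enabling or disabling a stage never changes another stage's draws, and
  all tabular outputs are bit-reproducible under a fixed seed and config.

## Limitations

The stem-age estimator's bias is inherited, not corrected. The permutation
envelope is a resampling interval, not a standardized effect size (no
SES-MPD machinery). The trend test pools (tree, quantile) observations and
treats trees as exchangeable draws. Spatial analysis supports bounding-box
CSV and GeoJSON input but not shapefiles, and no equal-area reprojection
or range-size correction is applied.
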