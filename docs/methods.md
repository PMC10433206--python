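# Methods

This note documents the models and procedures implemented in `georf`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Iterated weighted forests

**Trees.** Regression trees (CART) with the SSE criterion on labels
encoded case = 1 / control = 0. A leaf predicts the weighted mean label
of its samples — an estimated case proportion — so all scores are in
[0, 1]. Recursion stops when a node is pure (SSE ≤ 1e-12), when its
weighted size is below twice `min_leaf`, or when no candidate split
leaves ≥ `min_leaf` weight on each side with positive gain. Thresholds
sit at the midpoint between the adjacent distinct values (or bin
boundary values, below) spanning the cut; SSE ties break toward the
lower feature index, then the lower threshold, making trees fully
deterministic given their seed.

**Histogram split search.** Each feature is discretized once per fit
into at most 256 bins: exactly on its distinct values when there are no
more than 256 of them (in particular always at small n, where the search
is therefore *identical* to exhaustive enumeration — the property the
oracle tests check), otherwise on quantile cut points. The split gain
depends only on per-side weight and label sums, so candidate evaluation
is a single pass per node and feature.

**Weighted row collapse.** All patients of one ZIP code share a feature
vector, so a patient-level design collapses to one weighted row per ZIP
(weight = patient count, label sum = case count) without changing any
split statistic or leaf value. The bootstrap stays at patient level: a
multinomial over (ZIP, label) cells has exactly the distribution of
resampling patients with replacement. This makes 50,000-patient fits run
on ~2,000 rows. Collapse requires binary labels; continuous targets (the
network stage) fit uncollapsed.

**Iteration.** Iteration 1 samples split candidates uniformly.
Iteration *t* + 1 samples them without replacement with probability
proportional to iteration *t*'s normalized importances plus a floor
ε = 1/(100 F). The floor keeps every feature samplable — without it a
feature that misses every split in one iteration would die irreversibly.
Importance is the total SSE decrease per feature across all splits of
all trees, normalized to sum to one; a splitless forest (constant
labels) yields a flagged zero vector instead. The candidate set is drawn
by exponential-race keys (−ln u / w), equivalent to successive weighted
sampling without replacement.

**Defaults and units.** `n_trees = 100`, `min_leaf = 50` patients,
`n_iterations = 5`, `mtry_fraction = sqrt(F)/F`, patient-level bootstrap
on. The tree and leaf settings are desk-scale stand-ins preserving the
ratio of a national-scale configuration (1,000 trees, 1,000-patient
leaves on a ~10× larger cohort); `RunConfig` exposes the full-scale
values. The reweighting rule and mtry are implementation decisions —
they follow the iterative-forest literature, not a published
specification of the reference analysis, whose compiled implementation
does not document them.

Random-intersection-tree interaction discovery from the original
iterative-forest literature is deliberately not implemented; only the
importance ranking is consumed downstream.

## Correlation pruning

Groups are connected components of the graph joining feature pairs with
sample |Pearson r| ≥ 0.90 (boundary inclusive) over ZIP-level rows.
"Feature group" admits several constructions; components are the minimal
deterministic choice and guarantee the retained set contains no pair at
or above the threshold. The representative is the highest-variance
member (most informative under variance-reduction splitting), ties
broken by lexicographically smallest name. Zero-variance columns are
dropped outright: their correlation is undefined and no split can use
them. Correlations are computed over ZIP rows, not patient rows —
features are ZIP-level quantities, and patient-weighting would let
populous ZIPs redefine collinearity.

## Cross-validation and AUPRC

Five independent group-shuffle repeats at 80/20: each repeat randomly
permutes the ZIP codes and assigns a permutation prefix to the test side
so the held-out *patient* fraction is the closest achievable to 20%.
Whole-group assignment makes train/test ZIP-disjoint by construction.
Five repeats of a shuffle split (rather than a 5-fold partition) is the
operational reading of the workflow this package reproduces, which
describes an 80/20 group shuffle replicated five times.

AUPRC is the average-precision step sum Σ (R_k − R_{k−1}) P_k over
distinct score thresholds, tied scores processed as one block; linear
interpolation between PR points is biased and is not used. The chance
baseline equals the test prevalence. A drawn test side with zero cases
(possible at desk scale, never at national scale) is redrawn with a
logged warning, at most ten times before erroring.

The reduced model unites the top 20 features of a full-stratum fit with
the two vendor-rate features (≤ 22 features) and re-validates. The
ranking is fitted on the full stratum rather than nested inside each CV
repeat, mirroring the select-then-validate sequence it reproduces; this
carries a known optimistic bias for the reduced model's absolute AUPRC,
which is why the package reports the comparison, not the absolute score,
as the finding.

## Directionality

Every final-forest split on a feature contributes two points — each
child's (mean feature value, mean outcome) — weighted by child size. A
weighted least-squares line through the pooled points gives the effect
sign (positive slope = risk, negative = protective) and a weighted R².
Only the final iteration's forest is used: it produces the ranking being
explained, and earlier iterations are exploratory. A feature never split
on, or whose points share one x value, is *undetermined* (as is an exact
zero slope, a measure-zero event). Negating a feature column flips its
recovered sign.

## Feature network (leave-one-out prediction)

Each feature of the pruned table becomes the regression target of an
iterated forest on all remaining features, ZIP codes as samples; the
target model's normalized importance vector yields directed
predictor → target edges, so each fitted target's incoming weights sum
to one. "Top 1% of edges" is interpreted as 1% of all F·(F − 1) ordered
candidate pairs (not of nonzero-weight edges), floor-rounded; weight
ties break lexicographically so files are reproducible. Per-target
forests default to 20 trees (`loop_n_trees`) with the main model's other
settings — the all-against-all loop is F complete fits, and the network
stage would otherwise dominate the run time; the full-scale settings
remain configurable.

Because importances are normalized *per target*, a target with no real
predictors still distributes weight 1 across noise features. Top-edge
filtering is therefore only meaningful when genuinely related features
are common enough to out-compete that noise — true of real geospatial
panels, and reflected in the planted-dependency fixture below.

## Synthetic data

The generator emulates the *shape* of a national ZIP-level covariate
panel and case/control cohort; its defaults are the package's study
conditions.

- **Climate block**: 12 monthly measurement types × 12 months = 144
  columns plus 30 static terrain/climate columns. A shared latitude
  latent induces weak (|r| ≲ 0.5) cross-column correlation; strong
  correlation appears only in planted groups.
- **Demographics**: beta-distributed population shares in [0, 1]
  (defaults: 200 columns, standing in for ~1,600 census variables),
  plus log-normal population density and a water/land area ratio.
- **Vendor rates**: zero-inflated gamma (35% zeros, gamma shape 1.4) —
  per-capita business counts are skewed with many zero-vendor ZIPs.
- **Correlated groups**: noised, rescaled copies of a seed column
  planted over the tail of the monthly climate block, one member
  anti-correlated; the common loading is chosen, and tightened if a
  sample check fails, so that every pairwise sample |r| reaches the
  configured target (≥ 0.90). Copy construction gives exact control of
  group membership for pruning tests.
- **Ages**: integer years in [18, 95]; a 45% normal component (mean 52,
  sd 10) below 60 and a 55% exponential tail (scale 7 years) from 60,
  so patient mass peaks near 60 and declines steeply above — the shape
  that motivates stratifying at 60 (boundary age 60 is "older").
- **Labels**: Bernoulli(sigmoid(c_band + Σ β_f z_f)) on the patient's
  ZIP feature z-scores, coefficients and age bands configurable; the
  per-band intercept is solved by root-finding so the expected
  prevalence matches the configuration exactly (defaults 7.2% under 60,
  1.6% at 60+). ZIP assignment is multinomial proportional to
  population density.

**What the generator does not emulate**: spatial autocorrelation and
real ZCTA geometry, the joint distribution of real census/climate
variables (marginals are stand-ins), multi-ZIP residential histories,
and individual-level confounders. Passing recovery tests therefore shows
the *pipeline* identifies planted ZIP-level structure under realistic
shapes and prevalences — not that any particular real-world association
would be recovered.

**Dependency fixture for the network stage.** Five planted linear
dependencies among 50 features: each target is a standardized sum of 3
parents drawn round-robin from a pool of 6 independent sources, with 10%
residual variance (parent–target r ≈ 0.55, all pairwise correlations
below the 0.90 pruning threshold). Multi-parent targets are essential,
not cosmetic: the iterated forest is strongly winner-take-all, so a
single-parent target concentrates its whole importance on one edge,
leaving the rest of a top-1% network to per-target-normalized noise.
Composite targets force importance to split across parents and make
sources predictable from the targets they feed — the block-correlated
structure real covariate panels actually have.

## Numerical and policy details

- All randomness flows from configured integer seeds through named
  `SeedSequence` substreams (per stage, per iteration, per tree, per
  target), so every artifact is bit-reproducible and trees could be fit
  concurrently without changing results.
- Weighted sampling keys, bootstrap cell counts and label sums are
  integer-valued at patient scale, keeping collapse and mirror-image
  (negated-feature) fits exact in floating point.
- Readers reject rather than impute: missing cells, non-numeric cells
  and duplicate ZIP identifiers are errors naming the offending cell.
- Desk-scale problem sizes used by the test suite and the acceptance
  script (2,000 ZIPs / 50,000 patients / ~200 features; 1,000 samples /
  50 features for the network fixture) preserve the many-features,
  many-groups geometry of the national-scale analysis at one to two
  orders of magnitude reduction.

## Known limitations

- Importance is impurity-based (SSE decrease) and inherits its known
  preference for high-cardinality features; at 256 bins per feature the
  effect is mild and shared across features of the same type.
- The reduced-model comparison is optimistically biased by full-stratum
  feature selection (documented above).
- Network edge weights are per-target-normalized importances; they do
  not encode model fit, so edge weight is comparable across targets only
  insofar as targets are comparably predictable.
- Directionality summarizes a possibly non-linear response by a single
  weighted slope; a low R² flags exactly the features for which one
  sign is an oversimplification.
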