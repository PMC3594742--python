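# Methods

`mica` implements Maximal Information Component Analysis: gene
co-expression network construction from the maximal information
coefficient (MIC), fuzzy module detection with an interaction-component
Gibbs sampler (ICMg), eigengene module summaries, a simplified
correlation-network baseline, and the network-fitness statistics used to
compare decompositions. This note records the models, the numerical
conventions, and the design choices made where the design was open.

## MIC estimation

For a sample of n paired observations, MIC considers axis-aligned grids
that partition the x-ranks into `x_bins` and the y-ranks into `y_bins`
cells, computes the mutual information of the empirical cell
frequencies, and normalizes by the maximum achievable value for that
grid shape. The score of a pair is the maximum normalized value over
all admissible grids:

    MIC(x, y) = max over grids of I(grid) / log2(min(x_bins, y_bins))

Conventions, all fixed by tests:

- **Units.** Mutual information is computed in bits and the normalizer
  is `log2(min(x_bins, y_bins))`; the normalization is only
  base-independent if both use the same base, so base 2 is used
  throughout. Empty cells contribute 0 (the 0·log 0 convention).
- **Resolution bound.** Searched grids satisfy
  `x_bins * y_bins < n**exponent` with `exponent = 0.6` by default. The
  strict bound admits no grid at all for n ≤ 10 (2·2 = 4 ≥ 10^0.6), so
  the minimal 2×2 grid is always searched; this keeps small samples
  scoreable and is this package's convention.
- **Ties.** Grid lines may only fall between distinct values on an
  axis, so tied observations are never split across a cell boundary.
  Constant vectors score 0. Because the search acts on ranks, MIC is
  exactly invariant under strictly increasing transforms of either
  variable.

Two search modes exist. `exhaustive` enumerates every admissible cut
placement and serves as the oracle (feasible up to n ≈ 60).
`heuristic` follows the MINE scheme: partition one axis, optimize the
other by dynamic programming, in both orientations. The DP is exact
given the fixed-axis partition: the objective decomposes over columns
as `sum_cols sum_rows (c/n) log2(c / n_col)`, so a standard
segment-partition DP over candidate boundaries finds the true optimum.
Candidate boundaries are the distinct-value boundaries, thinned to
`clump_factor * l_max` quantile-spaced positions for large n
(`clump_factor = 15`). When the fixed axis has only 2 bins and at most
64 candidate boundaries, the single fixed cut is enumerated rather than
equipartitioned; every grid admitted at n ≤ 38 has a 2-bin axis, so the
heuristic is exactly optimal there and `heuristic ≤ exhaustive` holds
structurally everywhere.

## Scale-free topology

Connectivity at power p is `k_i = sum_{j != i} a_ij**p`. Connectivities
are binned into 10 equal-width bins (bins are in k, not log k; empty
bins are dropped) and `log10(bin frequency)` is regressed on
`log10(mean bin connectivity)`. The signed fit is
`-sign(slope) * R^2`, positive for the decreasing profile a power law
implies. The soft-threshold rule picks the *first* power in 1..20 with
signed R² ≥ 0.9; the hard-threshold rule scans cutoffs in 0.05 steps,
binarizes at `score >= cutoff`, and picks the *lowest* passing cutoff.
Degenerate degree profiles (all equal, fewer than two usable bins)
score 0 with a warning rather than erroring mid-scan.

## ICMg

The network is modeled as a link community process: each edge carries a
latent component, components hold Dirichlet-multinomial distributions
over nodes (symmetric prior β per node), and component proportions have
a symmetric Dirichlet(α) prior. Collapsing the continuous parameters
gives the single-link conditional

    p(z0 = z) ∝ (n'_z + α)/(N' + Cα) ·
                (q'_{z,i0} + β)(q'_{z,j0} + β) /
                ((2n'_z + 1 + Mβ)(2n'_z + Mβ))

with n'_z links currently in component z, q'_{z,i} component–node
co-occurrences, C components, M nodes, and all primed counts excluding
the interrogated link. Defaults α = 10, β = 0.1.

Sampler conventions:

- A sweep visits every link once in fixed input order (edges are sorted
  by endpoint IDs), which makes runs bit-reproducible given a seed; a
  randomized visit order would also be valid but sacrifices exact
  reproducibility for no measurable benefit on the tested graphs.
- Initialization draws one global component-probability vector from
  Dirichlet(α) and assigns links multinomially.
- After `burn_in` sweeps, the component–node count table `q` is
  accumulated every `thin` sweeps for `sampling_iters` sweeps; the
  membership of gene i in module z is its accumulated co-occurrence
  share, `mm[i, z] = acc_q[z, i] / sum_z acc_q[z, i]`. Zero-degree
  genes get uniform rows flagged unsupported and are treated as
  unplaced downstream.
- Empty components may persist; no re-spawning heuristic.
- Full-scale defaults are 40,000 burn-in and 10,000 sampling sweeps at
  thinning 10. Desk-scale studies and tests use 2,000/1,000 at
  thinning 10, which already reproduce the exact enumerated posterior
  on small graphs and recover planted partitions with ARI 1.0.
- Correctness is validated against exhaustive enumeration of the
  collapsed joint (via its exchangeable sequential-predictive form) on
  all tested ≤ 4-link graphs, comparing label-permutation-invariant
  pair-agreement probabilities within 3 batch-means standard errors.
- Separation sharpness on very small graphs depends on the smoothing
  scale Mβ relative to the data: two disjoint triangles separate
  crisply (max membership > 0.9) under a weak prior (α = 1, β = 0.01),
  while two disjoint 5-cliques already separate at the α = 10, β = 0.1
  defaults.

## Eigengenes

An eigengene is the unit-norm first principal component of a module's
gene profiles across samples. Genes are standardized (mean 0, variance
1 across samples) before any PCA — the convention of the
correlation-network literature — and constant genes are dropped with a
warning. The weighted variant uses memberships as row weights in the
covariance,

    C = X^T W X / sum(w),  W = diag(w),

chosen among the common weighted-PCA conventions because it reduces
exactly to the unweighted case at uniform weights. The sign is oriented
so the eigengene correlates nonnegatively with the weighted mean module
profile, making outputs deterministic. Stability across membership
cutoffs (default 0.10..0.90 in 0.05 steps) averages |correlation| over
modules — absolute value because a principal component's sign is
arbitrary — and excludes undefined eigengenes (fewer than 2 passing
genes) with a logged count.

## Correlation/TOM baseline

The comparison pipeline is: |Pearson r| → first power passing the
scale-free criterion (falling back to the best-fitting power with a
warning when none passes) → unsigned power adjacency → topological
overlap

    TOM_ij = (sum_{u ∉ {i,j}} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij)

with diagonal 1 and dissimilarity 1 − TOM → average-linkage
hierarchical clustering cut to a requested module count, groups below
`min_size = 20` dissolved to unplaced → iterative merging of the module
pair with the highest eigengene correlation above 0.8. The dynamic
tree cut of the full method is replaced by this static cut: the
baseline's role here is comparative. When no module count is given it
is chosen by mean silhouette on the TOM dissimilarity over 2 up to
about a quarter of the gene count — the upper range matters, because
background genes must be free to fall out as small dissolvable leaves,
which is the job dynamic tree cut performs in the original method.

## Evaluation statistics

- **Standard gene classes.** Descending the annotation DAG from the
  root, a branch stops at a child with fewer than 30 network genes and
  emits the parent, unless the parent exceeds 300 network genes (too
  broad, omitted); leaves emit themselves under the same cap; emitted
  classes are deduplicated. Annotations are propagated child →
  ancestors before counting.
- **Perplexity.** From the module × class co-occurrence confusion
  matrix, `2**(-sum_l log2 Phat(c_l | r_l) / N)` with row-normalized
  probabilities. Events are gene-level — each placed gene contributes
  one event per (module, class) incidence, and multi-assigned genes
  contribute per module — so N is the total co-occurrence mass; a
  cell-level reading (each nonzero cell once) is available behind a
  flag and agrees on the diagonal and uniform closed forms. Base 2
  throughout, so a module spread uniformly over k classes scores
  exactly k. The normalized score multiplies by
  placed / total-dataset genes; comparisons between methods use the
  normalized value.
- **Enrichment.** Per-module score is the maximum −log10 one-sided
  hypergeometric p over annotation terms against the gene universe —
  a local, exactly reproducible stand-in for a DAVID-style enrichment
  score. No multiple-testing correction, by design: the usefulness
  formula consumes raw enrichment scores.
- **Usefulness.** `U = sum_i score_i / log2(N_i) − log10(M)` over
  modules of size N_i with M unplaced genes; singleton modules are
  skipped (log2 1 = 0) and M = 0 incurs no penalty, both with warnings.
- **Module stability.** Every module pair across two partitions gets a
  2×2 overlap table and a one-sided (over-representation) Fisher exact
  p, identical to the hypergeometric tail.
- **Nonlinearity census.** All pairs with MIC above a cutoff (default
  0.9) are profiled by |Pearson r|; the fractions below 0.6 and above
  0.9 summarize how much of the strong-association mass is nonlinear
  vs near-perfectly linear. Absolute r is used because association
  sign is not meaningful for the unsigned MIC network. An optional
  seeded uniform subsample matches census sizes between datasets.
- **Optimal cutoff scan.** Among membership cutoffs whose mean
  eigengene correlation (to the other cutoffs and to the weighted PCA)
  passes a stability floor (default 0.99), the cutoff maximizing
  usefulness is returned; ties break toward the lowest cutoff.

## Synthetic data

The generator emulates strain-panel expression with planted structure.
Each module is driven by a standardized latent factor f; member genes
are `loading · g(f) + N(0, noise_sd)` with g the relationship
archetype: identity (linear), a sharp logistic in f centered at its
median (high threshold), `log(f − min f + 1)` (logarithmic), `f²`
(quadratic), or the two-condition GxE construction below. Overlap
genes load 0.7 on two factors and are recorded as belonging to both
modules; background genes are independent standard normals. Samples
carry a binary condition label (default balanced split). All
generators are pure functions of design + seed.

**GxE construction.** A pooled X-shape (y = ±x with overlapping
branches) caps MIC near `1 − 1/log2(min bins)` because any grid loses
one bit to the branch ambiguity, so it cannot support the near-1 MIC
that condition-dependent biology shows when branches are separable.
The planted GxE module therefore mixes two response types: *shifted*
genes track the factor with slope + in both conditions plus a mean
offset of 6 factor-SDs under treatment, and *flipping* genes track the
factor with the opposite slope under treatment. A shifted–flipping
pair is then a piecewise-linear *function* (branches disjoint in the
shifted gene's range), giving MIC ≈ 1 with pooled correlation ≈ 0 under
a balanced split; same-type pairs remain linear. The ground truth
labels exactly the cross pairs "gxe", and those are the pairs the
nonlinearity census is expected to flag.

**What the generator does not emulate:** probe/batch effects, realistic
microarray noise, genetic relatedness between strains, or ontologies
with realistic term-size distributions. Passing tests therefore show
the algorithms behave as specified on data satisfying their structural
assumptions, not that biological datasets will show effects of the same
magnitude.

## Study sizes and numerical choices

The desk-scale study used by the end-to-end tests and the acceptance
script is 200 genes × 100 samples: five planted 30-gene modules (two
linear, one threshold, one logarithmic, one GxE at noise 0.1, others at
noise 0.3), 10 overlap genes, 40 background genes — large enough for
MIC to separate planted signal (null MIC at n = 100 rarely exceeds
~0.6) while the full MIC matrix (19,900 pairs) stays at minutes scale.
The network for ICMg is cut at MIC ≥ 0.7, chosen from that null/signal
separation; the baseline runs fully automatic. The ICMg schedule is
the reduced 2,000/1,000 one. Floating-point comparisons in tests use
1e-12 for algebraic identities, 1e-8..1e-9 where an eigendecomposition
or serialization round-trip intervenes, and Monte-Carlo tolerances are
3 standard errors estimated by batch means (sampler) or across seeds
(memberships).

## Known limitations

- MIC cost is quadratic in gene count with a large constant; the
  estimator here is for desk-scale studies, not transcriptome-wide
  matrices.
- The component count C must be supplied (matched to the baseline's
  module count in comparative studies); the model cannot infer it.
- The heuristic MIC search is exact only when a 2-bin axis admits full
  enumeration (n small); at large n it is the usual MINE-style
  approximation and can undershoot.
- The intensity pre-filter ("strictly above the grand mean of per-gene
  means") is deliberately strict, which makes the all-equal case well
  defined but means re-filtering survivors removes more genes; the CV
  filter is idempotent.
- Fisher/hypergeometric enrichment treats genes as exchangeable; no
  gene-length or expression-level bias correction.
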