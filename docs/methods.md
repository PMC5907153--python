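# Methods

This note records the models implemented in `comodule`, the parameter
choices that matter, and the design decisions taken where more than one
reasonable construction existed.

## Pipeline overview

1. **Preprocessing** (`preprocess`): mean imputation of missing expression
   values per gene; selection of a differentially expressed gene universe by
   requiring *both* a Welch t-test and a two-sample Kolmogorov–Smirnov test
   to clear a Benjamini–Hochberg adjusted p < α (default 0.01), with each
   test family adjusted across genes separately and the results intersected.
2. **Network construction** (`netbuild`): Pearson correlations per
   condition; Fisher z transform; standardization of the off-diagonal z
   values within each condition (mean 0, SD 1); inverse transform
   r′ = tanh(z′); one hard threshold at the pooled q-quantile (default
   0.995) of |r′|, edge iff strictly above.
3. **Joint module identification** (`jointcluster`): drop genes isolated in
   both networks; build C = [[L₁, −βI], [−βI, L₂]]; embed the 2n vertex
   copies with the eigenvectors of the M smallest eigenvalues (scaled so
   S̃ᵀS̃ = 2I_M); agglomerative clustering, complete linkage, rank-based
   distance, into M clusters; union of corresponding per-network clusters;
   split into connected components of the union graph A₁ ∨ A₂; size filter
   [5, 800].
4. **Module statistics** (`modulestats`): induced-subgraph average degree
   d̄ = 2m/n and density D = d̄/(n−1) per network; per-module comparison of
   edge probabilities by a two-sample t-test on the n(n−1)/2 edge
   indicators (Welch by default).
5. **Enrichment** (`enrichment`): hypergeometric upper-tail
   over-representation of each module in each supplied gene set, BH-adjusted
   per module.

## Model assumptions

* Networks are unweighted and undirected with a shared, identically ordered
  gene index; the coupling term −β·I assumes the two vertex copies of a gene
  refer to the same biological entity.
* The structure test models each unordered gene pair inside a module as an
  independent Bernoulli edge; dependence between pairs sharing a gene is
  ignored, which is adequate for the moderate densities it is applied to
  (its type-I error at the 5% level is 0.05 ± 0.02 under a Bernoulli(0.1)
  null in the packaged calibration).
* Standardizing Fisher z-scores within each condition assumes the two
  correlation populations differ mainly in location/scale; after the
  back-transform the two networks can share one quantile threshold.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `quantile_threshold` | 0.995 | pooled |r′| quantile above which a pair gets an edge; expected edge fraction ≈ 1 − q, so average degree ≈ (1−q)(n−1) |
| `beta` | 1 | cross-network alignment weight; 0 decouples the networks, values ≳ 1 make the two copies of a gene co-cluster; every eigenvalue of C is ≥ −β |
| `M_override` / eigengap | — / factor 3 | embedding dimension = cluster count; chosen at the first gap λ_{M+1} − λ_M that is positive and ≥ factor × median gap in the search range, else the argmax gap with a warning |
| `min/max_module_size` | 5 / 800 | inclusive size bounds on final modules |
| `de_alpha` | 0.01 | adjusted-p cutoff of the differential-expression filter (strict `<`) |
| `rank_mode` | `"column"` | rank reading for the clustering distance (below) |

## The rank-based clustering distance

Eigenvector entry *magnitudes* vary strongly with matrix size while the
*order* of the entries within an eigenvector is stable; the clustering
therefore operates on ranks rather than raw coordinates. Two readings are
implemented:

* `rank_mode="column"` (default): each eigenvector's entries are replaced by
  their ranks across the 2n vertex copies (scaled to [0, 1]); complete
  linkage operates on Euclidean distances between these rank profiles. The
  embedding is rounded to 9 decimals before ranking so rows that are equal
  up to eigensolver noise receive exactly tied ranks (this is what makes
  identical-layer runs produce exactly identical per-network partitions).
* `rank_mode="row"`: the classical Spearman distance, 1 − rank correlation
  between the M coordinates of two rows (the form MATLAB's `pdist`
  computes).

The column reading is the default because the row reading degrades sharply
when M is small: with M coordinates there are only M! possible rank
patterns, distinct clusters can collide on the same pattern, and near-ties
with the constant bottom eigenvector flip ranks randomly. On the packaged
benchmark (4 modules × 25 genes, intra-module edge probability 0.30,
background 0.02, β = 1, M = 4) the column reading attains median ARI ≈ 0.96
over 20 seeds while the row reading saturates near 0.71 — even though
k-means on the same embedding separates the planted modules perfectly,
i.e. the information loss is entirely in the row-rank metric. At large M
(hundreds of clusters, the regime the method is designed for) the two
readings behave similarly.

## Synthetic data: what it emulates, what it does not

`generate_two_layer_sbm` draws two independent planted-partition layers:
within planted module m, edges are Bernoulli(p_A(m)) in layer A and
Bernoulli(p_B(m)) in layer B; all other pairs use the background
probability. A module with p_A = p_B is shared; one with p dense in one
layer and background-level in the other is differential.
`generate_correlated_expression` draws a one-factor-per-module Gaussian
model: gene g in module m has value √ρ·f_{m,s} + √(1−ρ)·ε_{g,s}, giving
expected within-module Pearson correlation ρ and zero correlation
elsewhere; background genes are pure noise.

Packaged scenarios (chosen once, used by tests and the acceptance script):

* `default_sbm_scenario`: 100-gene universe of 4 modules × 25 genes,
  intra-module p = 0.30 in both layers, background p = 0.02 — the module
  recovery benchmark at true M = 4, β = 1.
* `default_expression_scenario`: 4 modules × 20 genes with ρ = 0.8 in both
  layers plus 40 noise genes, 200 samples per layer.
* `differential_expression_scenario`: one 20-gene module with ρ_A = 0.05,
  ρ_B = 0.8 over 100 noise genes, 200 samples; with thresholding at
  q = 0.98 the module reliably comes out denser in layer B with a
  structure-test p ≪ 0.01.

The generators do **not** mimic real expression marginals, batch effects,
sample-size imbalance, heavy-tailed noise, or overlapping/nested module
structure. Passing the packaged tests shows the pipeline recovers block
correlation/edge structure under Gaussian noise at desk scale; it does not
certify behaviour on production-scale tumour data.

## Numerical choices

* **Eigensolver**: dense symmetric decomposition up to 2n = 4000, an
  iterative sparse solver (smallest-algebraic) above.
* **Determinism**: every eigenvector's largest-magnitude entry is made
  positive (ties → lowest index); within numerically degenerate eigenvalue
  groups the basis is rebuilt by Gram–Schmidt on the coordinate projections
  in fixed vertex order, making results reproducible across solver backends.
  Eigenpair residuals are checked against 1e−8·‖C‖.
* **Quantiles** use the inclusive linear-interpolation definition
  (numpy's default), fixed for reproducibility.
* **Degenerate inputs**: zero-variance genes get zero correlations (warning);
  |r| = 1 off-diagonal is an error unless explicitly clipped to 1 − 1e−12
  (synthetic duplicates); a module whose two indicator vectors are both
  constant gets structure-test p = 1 when the means agree, 0 otherwise;
  constant embedding rows under `rank_mode="row"` get distance 1 to all rows.
* **Ties in clustering** are resolved by scipy's deterministic linkage
  order.

## Design decisions on open points

* **t-test variants**: Welch (unequal variance), two-sided, both for the
  differential-expression filter and the structure test; a pooled-variance
  option exists for the structure test. On the worked example of a 25-gene
  module with 14 vs 73 induced edges, Welch gives p ≈ 4.7e−12 and the pooled
  form ≈ 3.3e−12; published per-module p-values of this kind depend on the
  unspecified variant and are not regression targets.
* **Threshold pooling**: one quantile over both conditions' |r′| values
  (that is what the normalization is for); per-network thresholds are
  available as an option.
* **Connectivity for module splitting**: the union graph A₁ ∨ A₂ — the
  weakest requirement consistent with borrowing connection information
  across networks. A gene isolated in one network but wired in the other
  stays in its module.
* **Union modules may overlap** (a gene whose two copies received different
  labels belongs to both unions); overlap is flagged in provenance. A
  non-overlapping mode (`allow_overlap=False`) assigns such a gene to the
  lower-indexed of its two clusters — with two networks there is no majority
  vote, so the rule is a fixed deterministic choice. The ARI-based
  `recovery_score` resolves overlaps by first membership; `omega_index`
  scores overlapping covers directly (and reduces to the ARI on partitions).
* **BH families**: per test family (t and KS separately) in the gene
  filter; per module across its tested sets in enrichment.

## Known limitations

* The unnormalized Laplacian embedding is sensitive to large sparse
  background components: a sizable Erdős–Rényi background gene pool
  contributes many small eigenvalues whose eigenvectors localize on the
  background and crowd out module contrasts. The benchmark therefore plants
  modules over a background *edge probability*, not over a large pool of
  free background genes.
* Differential modules (dense in one layer, background-sparse in the other)
  populate the bottom of the spectrum with near −β "isolated-copy" modes;
  at the true cluster count the embedding may not yet contain the contrast
  that separates them, and recovery improves only when M is raised well
  above the module count. The differential signature is instead detected
  reliably through the module statistics route (density comparison plus
  structure test).
* With thresholding quantiles far below the fraction of truly correlated
  pairs, tanh saturation of standardized z-scores makes edge selection
  between two strongly correlated layers nearly winner-take-all; thresholds
  should satisfy 1 − q ≳ expected signal fraction.
* The method is defined for exactly two networks, and k-means is
  deliberately not offered as a clustering backend.
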