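# Methods

## Scope and model

`modhet` treats within-group variability of expression profiles —
β-diversity, in the ecological sense of variability among sampling units —
as the quantity of interest. A group's β-diversity is the mean distance of
its samples to the group's centre in a multivariate expression space, and
differences in β-diversity between groups are tested by multivariate
analysis of dispersion (PERMDISP): one-way ANOVA on the per-sample
distances-to-centre, with significance from a permutation null. Gene
modules detected from a weighted co-expression network localize the
analysis: β-diversity computed on one module's genes measures the
heterogeneity of that "trait" alone, as opposed to the global transcriptome.

## Preprocessing

* **Probe collapsing.** Probe rows mapping to the same gene symbol are
  averaged (arithmetic mean); probes without a symbol are discarded.
* **Quantile normalization.** Every sample's distribution is forced onto
  the mean of the order statistics across samples. Ties within a column
  receive the mean of the reference values over their tied ranks. This is
  the dominant dialect; note it is exactly idempotent only for tie-free
  (continuous) columns, since averaged ties can collide and re-average.
  Missing values are rejected rather than imputed.
* **MAD filter.** Genes whose MAD is *strictly* greater than the upper
  quartile Q3 of all gene MADs are kept. Q3 uses linear interpolation
  (R type 7, `np.quantile(..., method="linear")`). On a continuous MAD
  distribution this keeps just under 25% of genes; if all MADs are equal it
  keeps none. The filter's ranking is invariant to the MAD consistency
  constant.
* **Robust standardization** (per analysis, not once): per gene, subtract
  the median and divide by the MAD, so every transcript contributes equally
  to Euclidean distances. Default MAD constant is 1.4826 (the normal
  consistency factor, the common statistical-environment default); raw MAD
  is available via the `constant` argument. Zero-MAD genes raise an error
  naming the gene.

Pipeline order: collapse → select annotated samples → quantile-normalize →
MAD-filter → (per analysis) robust-standardize.

## Network construction

* **Biweight midcorrelation.** Observations are centred at the median and
  weighted by `w = (1 − u²)²`, `u = (x − median)/(9·mad_raw)`, `w = 0` for
  `|u| ≥ 1`; the coefficient is the correlation of weighted deviations.
  This tracks Pearson closely on clean data (within 0.02 on bivariate
  Gaussian samples at n = 10⁴) while being robust to single large outliers
  (a 100× outlier in 50 samples moves bicor by < 0.05 where Pearson moves
  by > 0.3). Note bicor never equals Pearson *exactly* on non-degenerate
  data: the biweight down-weights any observation off the median, even
  inside the weighting window. Rows with zero MAD raise, or fall back to
  Pearson-style centring when `pearson_fallback=True`.
* **Signed similarity** `s = (1 + cor)/2 ∈ [0,1]`, so strong negative
  correlation maps near 0 (a signed network); the absolute value in the
  power adjacency `a = |s|^β` is then a no-op and is implemented as
  written.
* **Soft threshold selection.** For each candidate β (integers 1–30 by
  default), connectivity `k_i = Σ_{j≠i} a_ij` is histogrammed into 10
  equal-width bins; `log10 p(k)` is regressed on `log10 k̄` over occupied
  bins; R² is the squared correlation. The chosen β is the smallest with
  R² ≥ 0.9 *and negative slope* (scale-free topology requires decreasing
  p(k)); if the target is never reached, the best negatively-sloped R²
  wins. On planted-block data (which is not scale-free) the fallback
  selects large β; module recovery is insensitive to this within a wide
  range (β 12–30 all give ARI ≥ 0.93 on the 8-block design).
* The adjacency diagonal is stored as 1 but excluded from connectivity.

## Module detection

* **TOM.** `ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
  `ℓ_ij = Σ_{u≠i,j} a_iu a_uj`, computed by matrix product with the
  diagonal zeroed; `1 − ω` is the clustering dissimilarity. The vectorized
  computation matches a triple-loop oracle to 1e-12.
* **Clustering.** UPGMA (average linkage) via scipy's nn-chain; merge
  heights are nondecreasing and tie-breaks are deterministic.
* **Cutting.** The dendrogram is cut at an adaptive height — a fraction of
  the merge-height range mapped from `deep_split`
  ({0: 0.997, 1: 0.994, 2: 0.99, 3: 0.98, 4: 0.96}; default level 2 is the
  conventional 99% adaptive cut) — and branches with at least
  `min_module_size` (default 30) leaves become modules. A PAM-like second
  stage assigns each leftover gene to the module with smallest average
  dissimilarity, provided that distance does not exceed the module's most
  peripheral member's average distance to its module. Remaining genes are
  labelled `grey`. Labels come from a fixed colour palette in decreasing
  size order, so colours are comparable across runs but carry no meaning.
  This is the documented core of dynamic-hybrid tree cutting, not a
  bit-compatible reimplementation; the certified behaviour is recovery of
  planted blocks (mean ARI ≥ 0.95 over 10 seeds on the 8-block design with
  sizes 109/369/329/620/509/241/228/67).

## Dispersion analysis

* **Embedding.** Pairwise Euclidean distances between standardized samples
  are double-centred (Gower) and eigendecomposed. Axes with
  `|λ| < 1e-8 · max λ` are dropped; negative-eigenvalue axes are kept in a
  separate "imaginary" block. Distances to a group centre combine the
  blocks as `z² = d²_real − d²_imag`, floored at 0. For Euclidean input
  the imaginary block is empty and the whole path equals direct geometry in
  gene space (verified to 1e-8 against an independent implementation).
* **Group centre.** Default `spatial_median` (geometric median, Weiszfeld
  iteration, tolerance 1e-10, max 1000 iterations, with the Vardi–Zhang
  adjustment when the iterate lands on a data point); `centroid` is the
  coordinate mean. The spatial median minimizes the *sum* of distances, so
  per-group summed `z` is minimal under it; it does not uniformly give
  smaller mean distance than the centroid.
* **Small-sample bias adjustment.** Distances to a *fitted* centre
  underestimate true dispersion by ≈ √((n−1)/n); each group's distances
  are multiplied by √(n/(n−1)) by default (`bias_adjust=True`). With this
  package's reference design the smallest groups have 5–8 samples against
  42–80, and without the correction the bias alone masquerades as a
  dispersion difference in exactly those pairs. The same correction exists
  in the standard R implementation (`betadisper(..., bias.adjust=TRUE)`).
* **Permutation test.** Observed statistic: one-way ANOVA F on `z` for the
  two groups of a comparison. Null: the full-model residuals (`z` minus its
  own group mean) are permuted across the two groups' samples and F is
  recomputed on the permuted residuals, removing any true group difference
  from the null while preserving the pooled residual distribution — the
  scheme of the reference R implementation. p = (1 + #{F* ≥ F_obs}) /
  (1 + B), so p is never 0 and the floor is 1/(B+1); B defaults to 10,000,
  matching a 0.01 significance level with two digits of resolution. A
  classical raw-label permutation is available via `scheme="labels"`.
  Measured calibration: type-I error 0.027–0.047 at α = 0.05 over 300–500
  null simulations; power 1.0 against a 3× dispersion ratio at n = 40/group,
  α = 0.01.
* **Seeding.** One master seed per run; each comparison derives its own
  `SeedSequence` from (master seed, analysis label, group pair) via CRC32,
  so results are reproducible and independent of comparison order.
* **FDR.** Benjamini–Hochberg step-up (statsmodels), in two families
  mirroring the analysis structure: the global plan (30 tests for the
  1+5+5 design) as one family, and all per-module p-values pooled
  (30 × 8 = 240) as the other. Per-family adjustment of modules is
  available by calling `fdr_adjust` on any sub-table.

## Comparison plan

Exactly one normal state is required; metastatic subtypes must be a subset
of the cancerous subtypes. The plan enumerates normal-vs-cancer (c),
cancer-vs-its-metastatic (m), cross-cancer (C(c,2)) and cross-metastatic
(C(m,2)) pairs. Groups with fewer than 2 members are skipped with a
warning. The reported significance matrix defaults to the non-metastatic
comparisons (c + C(c,2) = 15 columns for c = 5) at q < 0.01, with modules
excludable from display; rows order by the number of subtypes with
significantly higher β-diversity than normal.

## Synthetic data

The generator emulates a breast-tissue compendium: 11 phenotypic states
(normal; Claudin-low, HER2-enriched, Basal-like, Luminal A/B; metastatic
counterparts) with sample counts 17/42/22/31/80/45/8/13/17/6/5 (286 total),
8 modules of sizes 109/369/329/620/509/241/228/67 plus 39 background genes,
1–3 probes per gene and a 5% unmapped-probe fraction.

Each module has one latent factor per sample; gene `g` in module `m` is
`l_g · (f_{m,s} + τ_state · η_{g,state}) + ε`, with loadings
`l_g ~ U(0.6, 0.95)`, factor `f ~ N(0, σ²_state)`, unit-variance noise and
a fixed per-gene state program `η`. The within-state factor spread
`σ_state` *is* the planted dispersion: the default ladder is normal 1.0 <
Luminal A 1.25 < HER2-enriched 1.5 < Luminal B 1.75 < Claudin-low 2.0 <
Basal-like 2.25, with each metastatic state equal to its cancerous
counterpart (so cancer-vs-metastatic comparisons are true nulls). The
program strength complements the spread, `σ² + τ² = factor_energy²`
(energy 2.5), which keeps every gene's marginal variance identical across
states. This matters: quantile normalization equalizes per-sample marginal
distributions, so dispersion planted as pure per-sample amplitude is
removed by QN, and state programs shared coherently by a whole module make
all samples of a tight state occupy the same marginal-tail genes, where
QN's rank mapping amplifies tiny differences. Per-gene programs with
state-invariant marginals survive QN essentially undistorted; the planted
ladder is recovered monotonically in 20/20 end-to-end runs. A
module-coherent program option (`program_module_weight > 0`) and a
noise-scaling heterogeneity mode (`heterogeneity_source="noise"`) exist
for sensitivity studies but are not defaults, and per-module dispersion
overrides (`module_dispersion_scale`) let a single module carry a planted
difference.

Effect sizes were calibrated once so that the qualitative ladder ordering
is recoverable at the design's sample sizes; adjacent subtypes differ by
0.25 in factor SD, roughly a 10% step in group mean distance after
standardization.

What the generator does *not* emulate: microarray platform effects,
batch/cohort structure, missing values, probe-specific biases beyond i.i.d.
probe noise, heavy-tailed expression marginals, or correlated noise between
modules. Passing tests therefore certify the statistical machinery under a
clean block-factor model, not robustness to platform artefacts.

For module-recovery studies, `blocks_design` sets all states' dispersion to
`factor_energy` (no programs at all), yielding pure blocks with near-zero
cross-block correlation — the appropriate ground truth for scoring cluster
recovery. `planted_group_distances` is an intentionally independent oracle
(plain numpy, no shared code) for the dispersion path; it agrees with the
embedding-based path to 1e-9 for Euclidean input.

## Numerical and design choices

* Permutation F-statistics are computed vectorized over all permutations;
  a degenerate within-group sum of squares (0) maps F to +inf (or 0 when
  between-group SS is also 0).
* PCoA uses `scipy.linalg.eigh`; eigenvalue order is descending.
* Average linkage uses scipy's `linkage(method="average")`.
* The per-module analysis standardizes each module separately (not a slice
  of globally standardized data), so a module's β-diversity is
  self-contained.
* Problem sizes in the test suite and acceptance script (e.g. 300–500 null
  simulations at 199 permutations, 10 recovery seeds, 10–20 end-to-end
  runs at 999 permutations) were chosen to make sampling error small
  relative to the tested margins while keeping a full run in a few
  minutes on one CPU.

## Known limitations

* The dendrogram cutter implements the adaptive-height core of
  dynamic-hybrid cutting, not the full published sub-criteria
  (core-scatter, cluster-gap refinements); very unevenly separated or
  nested module structures may split or merge differently than the
  reference implementation.
* PERMDISP tests dispersion only; it does not test location (no PERMANOVA),
  and a significant result with strongly unbalanced tiny groups should be
  read alongside the per-sample distance tables.
* Quantile normalization assumes samples share a common underlying
  distribution; under strong global amplitude differences between groups it
  removes real signal by construction (this is a property of the method,
  exercised explicitly by the generator's design).
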