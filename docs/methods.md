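# Methods

This note documents the models, conventions and numerical choices behind
`coexpair`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing conventions

* **Filter boundaries.** "Mean below 100 RPKM" excludes strictly below:
  a gene with mean exactly 100 is kept. "Zero in over two-thirds of
  cells" excludes strictly above: a gene zero in exactly 2/3 of cells is
  kept. Both are literal readings of the stated rules and are pinned by
  exact tests.
* **Order of operations.** log2(x+1) → per-gene centering → quantile
  normalization across samples. Centering before quantile normalization is
  unusual (the reverse is more common) but follows the stated recipe; the
  state machine on `ExpressionMatrix` enforces the order.
* **Quantile normalization ties.** Tied values within a column receive the
  mean of the reference values across their rank span. This is the
  dominant convention and preserves within-column rank order; it means
  columns share one multiset of values exactly only when they are
  tie-free.
* **Centering scope.** Each level (single-cell, bulk) is centered and
  quantile-normalized separately; the two matrices only ever share a gene
  universe, never a sample space.

## Correlation and classification

* All-pairs Pearson correlation is computed by matrix product
  (`numpy.corrcoef`); a brute-force summation oracle pins it to 1e−10 in
  the tests. Zero-variance genes yield *undefined* correlations and are
  excluded from ranking and classification rather than coerced to r = 0,
  which would manufacture "no correlation" calls.
* **Permutation null.** Each replicate permutes every gene's values
  independently across samples and recomputes all pairwise correlations;
  values are pooled across replicates. The positive cutoff is the
  (1 − 10⁻⁶) quantile of the pooled null. When the pooled null is smaller
  than 1/tail, the tail is extrapolated from a normal fit to the null
  (logged via a warning and recorded in the thresholds metadata); the
  desk-scale default of 200 replicates × 44,850 pairs ≈ 9 × 10⁶ values
  supports the 10⁻⁶ quantile empirically.
* **No-correlation interval.** "0.3 of cumulative probability on each side
  around zero" is read as the central 60% of the pooled null centered on
  its median, i.e. [Q(0.2), Q(0.8)]. The alternative reading (0.3 mass
  *outside* each cutoff) gives a central 40% interval; both are reachable
  through `nocorr_mass_per_side`. The convention used is recorded in the
  thresholds metadata.
* **Four-way patterns.** Correlations between the no-correlation interval
  and the positive cutoff are "intermediate": a pair is level-specific
  only when the other level is *affirmatively* uncorrelated. This
  stringency has a hard statistical consequence: a pair that is genuinely
  independent at one level falls inside the central-60% interval with
  probability 0.6 by construction, so the expected recovery of planted
  level-specific pairs is ≈ 0.6 × (detection rate at the planted level),
  regardless of effect size or sample count. Shared pairs have no such
  cap. The test suite asserts the attainable values (planted-level
  detection ≥ 90%, specific-class recovery ≈ 0.5–0.65, cross-class
  mislabeling < 1%).
* **MIC** is a deliberately naive equi-count grid search (a × b bins with
  a·b ≤ n^0.6, mutual information normalized by log2 min(a, b)) — an
  approximation adequate as a robustness check, not the MINE algorithm.

## Synthetic data generator

The generator defines the study conditions for all tests; its defaults are
a desk-scale rendition of the motivating design (hundreds of single cells,
≈120 bulk tumors, reduced to 300 genes for quadratic all-pairs work).

* **Latent-factor plantings.** Background log2 expression is
  `mu_g + e`, e ~ N(0, 1), with per-gene baselines
  `mu_g ~ N(8, 0.5²)` (≈ 250 RPKM, comfortably above the bulk filter).
  A planted pair draws one latent factor z per sample at its planted
  level(s): `x = mu + √ρ·z + √(1−ρ)·e`, so its population correlation is
  exactly ρ (default 0.9) there and exactly 0 elsewhere. Modules
  (protein complexes, the prognostic module) share one factor, giving
  pairwise ρ inside the module. Factor-planted gene sets are pairwise
  disjoint so the closed form holds exactly.
* **Dropout.** Single-cell zero inflation uses a logistic
  detection-probability curve, the convention of scRNA-seq simulators
  such as Splatter: P(zero) is a decreasing logistic in the standardized
  log2 expression with steepness `dropout_shape` (default 0.3) and
  midpoint calibrated numerically so the marginal zero rate equals
  `dropout_rate`. Uniform (expression-independent) zeroing was rejected:
  at realistic expression levels the on/off indicator then dominates the
  per-gene variance and a planted ρ = 0.9 pair retains r ≈ 0.03 —
  no co-expression analysis could see it, and real technical zeros are
  strongly expression-dependent. With the logistic model the measured
  post-dropout correlation of a ρ = 0.9 pair is ≈ 0.58–0.61 at a 30% zero
  rate.
* **Prognostic module.** Six genes with a shared factor at both levels
  plus a signed bulk offset `w_g (δ/2) u_j` (w alternating ±1, u = ±1 by
  latent risk group, δ = 0.8). Chosen so that (a) every module pair stays
  above the bulk positive cutoff — the worst (opposite-sign) pair has
  population correlation (ρ − δ²/4)/(1 + δ²/4) ≈ 0.64 against a cutoff of
  ≈ 0.44 at n = 120 — and (b) patients of opposite groups are
  anti-correlated across the module after per-patient centering, so
  correlation-distance clustering separates the groups. A uniform
  (unsigned) offset would be invisible to correlation-based clustering,
  which removes patient-wise constants.
* **Survival.** Event times are exponential with hazard ratio
  `hazard_ratio` (default 3) between risk groups and a low-risk median of
  600 days; censoring is independent exponential with its rate solved by
  root-finding so the expected censored fraction equals
  `censor_fraction` (default 0.3).
* **Annotations.** Interaction edges are Bernoulli per pair with
  background density 0.0034 and per-class odds ratios
  (defaults 27 / 5 / 1.6 for shared / single-cell-only / bulk-only, the
  regimes reported for glioblastoma). The ontology is a small three-level
  DAG (root, 4 mid terms, 16 leaves); planted pairs are co-annotated to a
  common leaf with a per-class coupling calibrated a priori toward
  similarity-fraction folds of ≈ 4.6 / 1.5 / 1.0. The genome layout uses
  20 chromosomes of 50 Mb tiled into 1 Mb topological domains; same-
  chromosome probabilities per class default to 0.169 / 0.053 / 0.15
  (bulk-only / sc-only / shared) against a ≈ 5% random baseline.
  Promoter accessibility across 125 cell types shares a latent factor
  (ρ = 0.8) within shared and bulk-only pairs; contacts are planted at
  higher rates on the specific classes. Every coupling is a controllable
  argument of `simulate_annotations`.
* **Validation platform.** A microarray-like log2 matrix for 100 held-out
  patients plus one reference patient measured on both platforms, with a
  constant platform offset (2.0) and light measurement noise (sd 0.2).
* All generators are pure functions of (config, seed); seeds are spawned
  per operation from `numpy.random.SeedSequence`.

### What the generator does and does not emulate

It reproduces the two-level design, zero inflation, class-coupled
annotations and a survivable cohort; it does **not** model batch effects,
library-size variation, copy-number-driven expression, read-level noise,
gene-length effects, or the heavy-tailed mean–variance relationships of
real RNA-seq. Green tests therefore demonstrate correctness of the
*pipeline machinery* under a known model, not performance on real tumors.

## Enrichment

* Random-pair controls draw 1,000 sets of 1,000 uniformly random gene
  pairs. Significance of observed-vs-control is reported both as a
  one-sample t-test of the control fractions against the observed value
  (the stated convention) and as an empirical permutation p (the more
  orthodox choice).
* Ontology similarity is the Lin measure,
  `sim(t1, t2) = 2·IC(MICA)/(IC(t1) + IC(t2))` with
  `IC(t) = −ln f(t)` from propagated annotation frequencies, combined
  across two genes' term sets by best-match average; the method is the
  common default of ontology-similarity packages and has a closed form
  the tests pin by hand. The similarity-call threshold is 0.5.
* Term enrichment is an in-package hypergeometric upper-tail test with BH
  correction (no web service); genes enriched in several modules are
  assigned to the most significant one.
* Correlation bins are half-open `[k/10, (k+1)/10)`; bins with fewer than
  20 pairs are flagged low-support rather than dropped.

## Regulatory coordinates

Internal coordinates are 0-based half-open; the gene layout TSV is 1-based
inclusive, BED-like files 0-based half-open, with converters pinned by
round-trip tests. Promoters are 1,000 bp *strictly upstream* of the TSS
and strand-aware — on "−" genes that is genomically downstream of the TSS
coordinate; multiple overlapping peaks aggregate by sum (max available by
option). Gene contact regions are gene body ± 5,000 bp. Distribution
"highest peaks" are modes of a Gaussian KDE with Silverman bandwidth on a
fixed grid over [−1, 1].

## Survival signature search

* Communities come from greedy agglomerative modularity maximization
  (Clauset–Newman–Moore, via networkx) on sorted node/edge order for
  determinism; communities below `min_size` = 3 are discarded.
* Patient bi-clustering: distance 1 − Pearson r over the signature genes,
  complete linkage, tree cut at k = 2 (the one clustering recipe stated
  anywhere in the method, reused here).
* The combination search enumerates all 1..3-subnetwork unions of the
  log-rank-significant (α = 0.05) subnetworks; BH FDR is computed over
  *all* tested units (every screened subnetwork plus every combination).
  The winner minimizes p, with ties broken toward fewer genes and then
  lexicographic ids, so the search is deterministic.
* Because the combination universe is built from already-selected
  subnetworks and the chi-square log-rank tail is mildly anti-conservative
  for unbalanced data-driven partitions, the winner's q < 0.1 occurs in
  roughly 12–16% of structure-free (hazard ratio 1) runs rather than the
  nominal ≤ 10% — a property of the procedure itself, measured by the
  test suite, not corrected by post-hoc recalibration.
* Cross-platform validation subtracts each platform's scalar mean of one
  reference sample measured on both platforms, names the training groups
  poor/favorable by median survival, transfers labels with a
  nearest-shrunken-centroid classifier (scikit-learn `NearestCentroid`;
  shrinkage chosen by 5-fold cross-validated training accuracy over a
  fixed grid, ties toward less shrinkage), and reports the log-rank p
  between predicted groups in the validation cohort.
* Silhouette widths use the same 1 − r distance; patients in singleton
  groups get width 0 by convention (scikit-learn's behavior, kept).

## Problem sizes and determinism

Defaults are 300 genes × 200 cells / 120 bulk / 100 validation patients,
200 null shuffles per level in the pipeline (30 in the repeated-run test
harnesses), and 1,000 × 1,000 random-pair controls — sizes chosen so the
full pipeline runs in well under a minute on one CPU while keeping every
quantile and fold estimable. One root seed is split per stage through
`SeedSequence`; the report JSON is byte-identical across runs with the
same seed, and the suite asserts it.

## Known limitations

* Specific-class recovery is structurally capped near 60% by the
  stringent no-correlation requirement (see above); consumers who need
  higher recall should widen `nocorr_mass_per_side` toward 0.5 and accept
  weaker specificity claims.
* The MIC implementation is an approximation; do not compare its absolute
  values against published MIC scores.
* The log-rank p is asymptotic; with very unbalanced patient splits its
  extreme tail is slightly optimistic.
* At desk scale the classified sets are small (tens of pairs), so
  per-class fractions (same-chromosome, contacts) carry large sampling
  error; the acceptance script reports them with their n.
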