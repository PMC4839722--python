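# coexpair

Comparative co-expression analysis between **single-cell** and **bulk**
tumor expression profiles.

Co-expression — the tendency of two genes' expression levels to rise and
fall together across samples — looks very different depending on whether
the "samples" are individual cells from a tumor or whole bulk tumors from
a cohort. Pairs strongly correlated across cells are largely disjoint from
pairs strongly correlated across tumors, and the two kinds of pairs carry
different biology: cell-level co-expression is enriched for physical
protein–protein interactions and interchromosomal chromatin contacts,
while tumor-level co-expression tracks shared function, synchronized
promoter accessibility, and chromosomal co-location. `coexpair` implements
that comparative analysis as a tested, reusable pipeline for
transcriptomics researchers, together with a synthetic-data generator that
plants known structure so every stage can be validated against ground
truth.

## What the pipeline computes

1. **Preprocessing.** Bulk genes with mean expression < 100 RPKM and
   single-cell genes that are zero in more than two-thirds of cells are
   removed; the gene universes are intersected; values are transformed
   `log2(x + 1)`, centered per gene, and quantile-normalized across
   samples.
2. **Co-expression.** For every unordered gene pair, Pearson's
   correlation at each level:

   `R = Σᵢ (xᵢ − x̄)(yᵢ − ȳ) / sqrt( Σᵢ (xᵢ − x̄)² · Σᵢ (yᵢ − ȳ)² )`

   plus an optional naive maximal-information-coefficient (MIC) check,
   top-K pair selection, and split-half robustness analysis.
3. **Classification.** Per level, the expression of each gene is shuffled
   across samples many times; the pooled null correlation distribution
   gives a positive cutoff (the 1 − 10⁻⁶ quantile) and a "no correlation"
   interval (central 60% of the null). A pair is **shared** if positive at
   both levels, **single-cell specific** (positive in cells, affirmatively
   uncorrelated in bulk), **bulk specific** (the converse), or *other*.
4. **Annotation enrichment.** Per class: fraction of pairs with known
   protein interactions, ontology-similarity fraction (Lin semantic
   similarity ≥ 0.5, best-match average), per-complex co-expression maps,
   and hypergeometric term enrichment — each against 1,000 random sets of
   1,000 gene pairs.
5. **Regulatory genomics.** Promoter (1 kb strictly upstream of the TSS,
   strand-aware) accessibility correlation across cell types,
   chromatin-contact overlap of gene bodies ± 5 kb, and same-chromosome /
   same-topological-domain fractions.
6. **Survival signature.** The three class networks are decomposed into
   communities (greedy modularity); each community — and every combination
   of up to three log-rank-significant communities — is used to cluster
   patients into two groups (1 − r distance, complete linkage), scored by
   the log-rank test with Benjamini–Hochberg FDR and silhouette width, and
   the winner is validated on an independent cohort after
   reference-sample cross-platform normalization and nearest-shrunken-
   centroid label transfer.

The synthetic generator plants pair-level and module-level latent factors
(`x = √ρ·z + √(1−ρ)·ε` on the log2 scale, so a planted pair has population
correlation exactly ρ at its planted level), logistic
expression-dependent dropout for the single-cell matrix, annotation layers
statistically coupled to the pair classes, and a prognostic gene module
with an exponential survival model (`docs/methods.md` has the full model).

## Worked example

```python
from coexpair import RunConfig, run_all

report = run_all(RunConfig(seed=1))

counts = report["classification"]["counts"]
print(counts["shared"], counts["sc_specific"], counts["bulk_specific"])
# 73 23 37

sig = report["survival"]["signature"]
print(sig["composition"], sig["logrank_p"], sig["validation_logrank_p"])
# 6 shared 5.8215696364925485e-05 1.5075063810103675e-07
```

With the default study design (300 genes, 200 cells, 120 bulk tumors,
ρ = 0.9, 30% dropout), 73 of 44,850 gene pairs are called shared, 23
single-cell specific and 37 bulk specific. The signature search finds the
planted 6-gene prognostic module: it splits the 120 training patients into
groups whose survival differs at log-rank p ≈ 5.8 × 10⁻⁵, and the
transferred labels separate the 100 held-out validation patients at
p ≈ 1.5 × 10⁻⁷. The same report carries the enrichment folds (e.g. a
21.7-fold interaction enrichment for shared pairs against the random-pair
control) and the promoter-accessibility correlation modes per class
(0.74 / 0.77 for shared and bulk-specific vs −0.03 for single-cell
specific).

The same pipeline is available from the shell:

```bash
coexpair run --seed 1 --outdir out/        # full run, writes report.json
coexpair simulate --outdir data/ --seed 1  # synthetic inputs as TSV/BED/JSON
coexpair preprocess --sc data/expression_sc.tsv --bulk data/expression_bulk.tsv --outdir norm/
```

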