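# qtloverlap

Tools for asking whether trait QTL in a multi-breed livestock population are
also expression QTL. Identifying the gene through which a QTL acts is hard:
effects are small and linkage disequilibrium (LD) in cattle extends over
megabases, so an eQTL near a GWAS peak may be a coincidence of LD rather
than the same causal variant. `qtloverlap` implements the three
complementary strategies used to separate those possibilities, plus a
synthetic-data generator so the whole analysis is testable end to end
without access to (non-public) cattle genotype archives:

1. **Correlation of local GEBV with gene expression.** Variant effects are
   estimated jointly with Bayes R (a four-component normal-mixture prior,
   one component a point mass at zero, fitted by Gibbs sampling). A *local*
   genomic estimated breeding value restricts the sum `Σ dosage_ij a_j` to a
   250 kb window; windows are slid every 50 kb, ranked by the variance of
   their local GEBV across individuals, and greedily reduced to a
   non-overlapping set whose summed variance `Σσ²_locGEBV` anchors the
   "var.%" scale. Each window's local GEBV is correlated (Pearson) with the
   expression of every gene within 1 Mb; a permutation test that shuffles
   effects within windows quantifies how many significant correlations LD
   alone would generate.
2. **Top-k versus random-k enrichment.** The k non-overlapping windows
   explaining the most genetic variance are compared with k randomly placed
   windows (100 redraws) through a filter chain counting intervals that
   contain an eQTL (nE), a variant correlated with the local GEBV (nG),
   both for one variant and gene (nEG), a significant GEBV–expression
   correlation (nC, nEC), and all of it with consistent effect directions
   (nEGC).
3. **Colocalisation (CLPP).** Around every GWAS QTL lead (p ≤ 1e−6, ≥ 1 Mb
   apart) and every eQTL gene (p ≤ 1e−5, one lead per gene), fine-mapping
   posteriors are computed in both studies by enumerating causal
   configurations under `z ~ N(0, Σ + s²·Σ diag(c) Σ)`; the colocalisation
   posterior probability of a variant is the product of its two posterior
   inclusion probabilities, with CLPP ≥ 0.01 flagged as shared.

Supporting machinery: a two-breed mosaic-haplotype genotype simulator with
Balding–Nichols divergence and tunable LD decay, trait deviations with
sex-dependent accuracy (bull-like 0.95 vs cow-like 0.6), negative-binomial
expression counts with cis-eQTL effects and covariates, MAF/LD-pruning
filters, a VanRaden GRM, REML variance components, EMMAX association scans
(sex-stratified, combined by METAL-style √n-weighted z-scores), and the
study-style FDR estimator `(t × nTests)/nSign`.

## Worked example

```bash
qtloverlap -v all --seed 1 --out runs/demo
```

runs the full pipeline on the default demo genome (2 chromosomes × 40 Mb,
5,000 variants, 2,000 individuals in two breeds, 300 genes, 131 expression
cows, 10 trait QTL and 30 eQTL of which 5 shared). With seed 1 and the
top-50 interval set, the summary reports (abridged):

```
"gwas":        {"n_significant": 12, "fdr": 0.0004, "n_qtl": 6}
"windows":     {"n_windows": 1600, "u_nonoverlapping": 259}
"eqtl_milk":   {"n_pairs": 36048, "n_significant": 56, "fdr": 0.0064, "n_eqtl_genes": 30}
"overlap_milk":{"n_selected_correlations": 43, "observed_count": 43,
                "permuted_mean": 27.1, "top_share_pct": 99.95,
                "enrichment_top":        {"nE": 11, "nC": 7, "nEGC": 5},
                "enrichment_random_mean":{"nE": 4.7, "nC": 2.6, "nEGC": 1.7}}
"coloc_milk":  {"n_qtl": 6, "coloc_qtl": 5, "n_eqtl": 30, "coloc_eqtl": 9}
```

Reading: 12 meta-analysis variants pass p ≤ 1e−6, collapsing to 6 spaced QTL
leads; all 30 implanted eQTL genes are recovered; 43 window–gene
correlations pass p ≤ 1e−5, of which a mean of 27.1 survive within-window
effect permutation — i.e. roughly two thirds of the correlation signal here
is attributable to LD inside the window, the behaviour the permutation test
exists to expose. The 50 top-variance windows carry 99.95 % of
`Σσ²_locGEBV` and contain 11 eQTL-bearing intervals and 5 fully consistent
overlap intervals (nEGC), versus 4.7 and 1.7 for random window sets; 5 of
the 6 QTL colocalise with an eQTL at CLPP ≥ 0.01 (5 of the 10 implanted
trait QTL are also eQTL by construction).

Every output table (associations, windows, correlations, permutation
counts, enrichment, CLPP records) is written as TSV/BED/VCF under
`--out`, stamped with the config hash and seed; the same config and seed
reproduce the run bit-identically.

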