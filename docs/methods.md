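# Methods

`qtloverlap` implements a complete QTL/eQTL-overlap analysis for a
multi-breed dairy-cattle-style design, together with a synthetic-data
generator that reproduces the statistical structure the analysis assumes.
This note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic data do and do not emulate.

## Synthetic data (`synthdata`)

**Genotypes.** Two breeds diverge from shared ancestral allele frequencies
`p ~ U(0.05, 0.95)` under the Balding–Nichols model: each breed frequency is
Beta-distributed with mean `p` and variance `p(1−p)·Fst` (default
`Fst = 0.1`, a typical taurine between-breed value; `Fst = 0` returns the
ancestral frequencies unchanged). Within a breed, a founder pool (default
24 haplotypes) is drawn from a Gaussian-copula AR(1) along each chromosome
with correlation `exp(−d / ld_block_scale)` between variants `d` bp apart,
thresholded at the breed frequency. Individual haplotypes are mosaics of the
founder pool: the active founder switches between consecutive variants with
probability `1 − exp(−d / ld_block_scale)`, i.e. a per-bp switch rate of
`1/ld_block_scale` (default 100 kb). Dosages are sums of two independent
mosaics. The AR(1) founders are essential: an i.i.d. founder pool carries no
within-haplotype LD, and the mosaic scheme alone then produces only the
`~1/n_founders` background correlation. With the defaults, adjacent-variant
r² is ≈ 0.2 and r² at > 1 Mb is ≈ 0.01, which reproduces the
strong-local/weak-long-range LD profile of cattle without coalescent
machinery.

**Causal registry.** Trait-causal, expression-causal and shared variants are
drawn without replacement among variants with MAF ≥ 0.05. Trait effects are
Gaussian; expression effects are ± `expr_effect` natural-log units per
allele (default 1.0, a strong cis-eQTL).

**Phenotypes.** Trait effects are rescaled so the genetic variance equals
`h2` on a unit phenotypic-variance scale (default `h2 = 0.5`, production-
trait territory). A record for an individual with accuracy `acc` is the
genetic value plus noise of variance `σ²_g (1 − acc²)/acc²`, so
`corr²(record, genetic value) = acc²`. Sex enters only through the accuracy
class — bull-like 0.95 (progeny-average deviations), cow-like 0.6 (own
records) — which is exactly the precision difference that motivates
sex-stratified GWAS with meta-analysis. When the registry carries no trait
effects at all, noise is scaled to the nominal unit-phenotype variance so
null records are pure noise rather than identically zero.

**Expression.** The expression cohort defaults to 131 cows (105 breed A +
26 breed B) drawn from the genotyped individuals, mirroring a two-breed
RNA-seq design. Counts are Gamma–Poisson: `Poisson(μ·G)` with
`G ~ Gamma(1/φ, φ)` (dispersion `φ = 0.15` gives the mild extra-Poisson
noise of bulk RNA-seq; `φ → 0` is the Poisson limit), and
`log μ = baseline + gene offset + eQTL effect × dosage + covariates` with
breed, parity, days-in-milk and batch terms. Genes carrying an implanted
eQTL are placed within 100 kb of their causal variant so the effect is cis;
other genes are placed uniformly.

**What the generator does not emulate:** pedigree structure, imputation
error, allele-specific expression, expression networks between genes, or
non-additive trait architecture. Tests passing on these data therefore
certify the statistical machinery (calibration, recovery, discrimination
under LD), not robustness to those real-data complications.

**Seeding.** All draws descend from one seed through named child streams
(`stage_rng`), so each stage is reproducible in isolation and the whole run
is a function of the single seed.

## Association (`assoc`)

Variant filtering applies a MAF floor (default 0.002) and greedy
left-to-right LD pruning (drop a variant whose r² with a kept variant in the
preceding 50-kept-variant window exceeds 0.9). The GRM is VanRaden method 1,
`ZZ'/2Σp(1−p)`, with a 1e−6 diagonal ridge before eigendecomposition.
Variance components are REML estimates from a bounded 1-D search over h² on
the GRM eigenbasis. Single-variant tests use the EMMAX approximation:
whiten by `V^{−1/2}` at the null estimates, residualize phenotype and
dosages on the fixed effects (intercept + breed), and test each variant by
simple regression with a t-reference on `n − p − 1` degrees of freedom —
with an identity GRM this is numerically exact OLS. Note that the variance
split is unidentifiable when the GRM *is* the identity (V is then a scalar
matrix for every h²), and a GRM built from a handful of variants absorbs
those variants' own signal; null-model fitting assumes a genome-wide GRM.

Scans run separately per sex stratum and are combined by the
sample-size-weighted z-score scheme: `z_i = sign(β_i)·Φ⁻¹(1 − p_i/2)`,
`w_i = √n_i`, `z_meta = Σw_i z_i / √Σw_i²`. p-values are floored at 1e−300
before the normal-quantile transform. QTL leads are selected greedily —
smallest p first, suppressing variants strictly within 1 Mb on the same
chromosome (leads exactly 1 Mb apart are both kept, the literal reading of
"at least 1 Mb apart"); ties break by (chromosome, position).

## Bayes R (`bayesr`)

Standard single-stage Bayes R: effects have a four-component normal-mixture
prior with variances `(0, 1e−4, 1e−3, 1e−2)·σ²_g` and a flat
Dirichlet(1,1,1,1) prior on the mixture proportions. Each Gibbs sweep
samples the fixed effects (intercept + breed) from their Gaussian
conditional, each variant's class from the marginal likelihood across the
four components and its effect from the conditional normal, the proportions
from Dirichlet(1 + counts), and the residual variance from a scaled
inverse-χ².

Two variance choices matter:

* The **mixture scale** σ²_g is sampled by the conjugate scaled
  inverse-χ² update from the nonzero effects, `Σ β²_j/γ_{k_j}`, with a weak
  prior (ν = 4, centred at var(y)/4). Re-estimating it deterministically
  from the realized genetic variance is an absorbing state — small effects
  tighten the prior, which shrinks the effects further — and destroys QTL
  recovery.
* The **reported** genetic variance is the posterior mean of the variance
  across individuals of the current genetic values `Xβ`, which accounts for
  LD between variants (the linkage-equilibrium formula `Σ2pq β²`
  under-counts it on these data).

Identifiability caveat: at desk scale (n ≈ 10³) the two smallest
nonzero-variance classes imply prior effect SDs below 0.01 phenotype SD and
are likelihood-indistinguishable from the zero class, so under a null
phenotype the posterior mixture mass spreads roughly evenly over classes
0–2 while every effect is still shrunk to ~0. Shrinkage and large-class
avoidance are the testable null properties; the zero-class proportion alone
is not.

Defaults are 10,000 iterations, 2,000 burn-in, thinning 10; the pipeline
demo uses 4,000/1,000/3 (the recovery tests pass at 3,000/1,000/5 with
n = 2,000, m = 3,000, where a fit takes ~10 s via the JIT-compiled sweep).
Chains are bit-reproducible under a fixed seed.

## Local GEBV windows (`windows`)

Windows are 250 kb, half-open `[start, start + 250,000)`, with starts on a
50 kb grid anchored at bp 1 per chromosome; windows containing no variant
are dropped. The local GEBV of window w for individual i is
`Σ_{j∈w} dosage_ij · a_j` over the posterior-mean effects, and σ²_w is its
sample variance (n − 1) across individuals. The non-overlapping ranking is
a greedy sweep in descending σ²_w (ties by chromosome, then start): accept
a window iff it overlaps no previously accepted window; `Σσ²_locGEBV` is
the sum over accepted windows and var.% expresses any window's variance as
a percentage of that sum.

The within-window permutation reassigns the member-effect multiset to
member positions independently per window. Because windows overlap, a
variant shared by five windows is permuted separately in each; this is the
only scheme that preserves every window's effect multiset exactly. The
permuted local GEBVs isolate how much GEBV–expression correlation arises
from LD within the window rather than from the specific effect-to-variant
assignment.

## cis-eQTL (`eqtl`)

Genes expressed (count > 0) in fewer than 25 cows are dropped; expression is
`ln(count + 1)` (base and offset are this package's choice; no library-size
normalization is applied by default, a flag exposes it). Cis pairs are
variants within 1 Mb of the gene span (span ± 1 Mb inclusive; trans pairs
are never tested). Each gene gets its own null-model REML fit with the
expression-cohort GRM, then an EMMAX-style Wald test per cis variant with
intercept, breed, batch (indicators), parity and days-in-milk (linear) as
fixed effects. At most one eQTL call per gene: the smallest-p cis variant,
emitted iff p ≤ 1e−5.

## Overlap (`overlap`)

GEBV–expression correlations are Pearson r between a window's local GEBV
and the (covariate-residualized, by default) log expression of every gene
within 1 Mb, with a two-sided p from `t = r√(n−2)/√(1−r²)` on n − 2 df.
The permutation comparison recomputes these correlations under 100
within-window effect permutations and counts those with p ≤ 1e−5.

The enrichment filter chain is evaluated per interval: E — some member
variant is an eQTL (p ≤ 1e−5) for a gene within 1 Mb; G — some member
variant's genotype correlates with the interval's local GEBV (p ≤ 1e−5);
EG — one variant does both for the same gene; C — the local GEBV correlates
with a nearby gene's expression (p ≤ 1e−3); EC — E and C hold for the same
gene; EGC — EG and C hold for the same gene with consistent directions,
`sign(eQTL β) × sign(genotype–GEBV r) = sign(GEBV–expression r)`. Counts
are compared between the top-k windows by variance (k = 300 at genome
scale, 50 at demo scale, where only ~320 disjoint windows exist) and k
randomly placed non-overlapping windows, redrawn 100 times from all windows
(top-k members are not excluded from the random draw).

The FDR estimator is `(t × nTests)/nSign` — expected false positives at
threshold t over observed significant calls. It is deliberately oriented so
that, e.g., 4,333 significant of 4,812,745 tests at t = 1e−6 gives 0.001.

## Colocalisation (`coloc`)

For each QTL lead, genes within 1 Mb anchor loci containing all variants
within 1 Mb of the gene that carry finite statistics in both studies; each
eQTL gene anchors one locus the same way. Loci are capped to the 50
variants with the largest `max(|z_gwas|, |z_eqtl|)`. Within a study the
z-vector is modelled as `z ~ N(0, Σ + s²·Σ diag(c) Σ)` for a causal
configuration c, with Σ the dosage-correlation matrix (1e−4 diagonal
ridge), non-centrality scale s = 5.2 and per-variant causal prior γ = 0.01
— the published defaults of the configuration-enumeration fine-mapping
framework this module implements. Configurations up to 2 causals per study
are enumerated (the null configuration is included in the normalization);
the PIP of variant i is the posterior mass of configurations containing i.
CLPP is the product of the two studies' PIPs (independence assumption), and
variants with CLPP ≥ 0.01 are flagged as shared. Enumeration at
`max_causals = m` reproduces the full 2^m posterior exactly, which is the
oracle used in tests.

## Pipeline (`pipeline`, `cli`)

`run_all` chains synthetic data → filtering → GRM → stratified GWAS + meta
→ QTL leads → Bayes R → windows/ranking → per-cell-type eQTL scan,
correlations, permutation comparison, enrichment, FDRs → colocalisation,
writing TSV/BED/VCF outputs, all stamped with a config hash and seed;
reruns with the same config are bit-identical. Coordinates are 1-based
everywhere except BED exports (0-based half-open). Missing VCF genotypes
are mean-imputed with a logged count; unsorted VCFs are rejected with the
offending coordinate. The `qtloverlap` CLI exposes `all` plus per-stage
verbs over one YAML config. Plotting is not included; outputs are plain
tables chosen to be trivially plottable.

## Problem sizes

The demo configuration is 2 chromosomes × 40 Mb, 5,000 variants, 2,000
individuals (1,600 + 400 across breeds), 300 genes, 131 expression cows,
100 permutation replicates and 100 random-k draws; the full pipeline runs
in about a minute. Recovery and discrimination tests use n = 2,000 /
m = 3,000 (Bayes R window recovery) and twenty replicates of n = 1,000 /
m = 1,500 pipelines (enrichment discrimination). These sizes were chosen so
the implanted architecture (10–20 QTL at h² = 0.5–0.6, 1–1.5 log-unit
eQTL) is comfortably detectable by design, making test failures informative
about the code rather than about power.

## Known limitations

* The EMMAX approximation fixes variance components at the null estimate;
  per-variant exact REML is out of scope.
* Bayes R assumes complete genotypes (the VCF reader mean-imputes).
* The CLPP model assumes the two studies are independent given the causal
  configuration; shared individuals between GWAS and expression cohorts
  violate this mildly in the simulated design, as they did in the design
  the package emulates.
* The FDR estimator is the study's own simple expectation ratio, not a
  Benjamini–Hochberg procedure, and can exceed 1.
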