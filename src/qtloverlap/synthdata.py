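"""Synthetic genotype, phenotype and expression data with implanted causal variants.

The generators emulate the statistical structure of a multi-breed dairy-cattle
dataset: diploid dosage genotypes for two breeds with linkage disequilibrium
decaying over a tunable physical scale and Balding-Nichols allele-frequency
divergence between breeds; per-individual trait deviations whose precision
depends on sex (daughter trait deviations of bulls are far more accurate than
the cows' own trait deviations); and per-gene RNA-seq read counts carrying
cis-eQTL effects plus breed, parity, days-in-milk and sequencing-batch
covariates.  A ground-truth registry records which variants are causal for the
trait, for expression, or for both, so recovery of implanted signal can be
tested at every downstream stage.

All draws descend from a single seed through named child streams
(:func:`stage_rng`), so each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet",
    "GroundTruth",
    "PhenotypeTable",
    "ExpressionSet",
    "stage_rng",
    "draw_breed_freqs",
    "simulate_genotypes",
    "implant_truth",
    "simulate_phenotypes",
    "simulate_expression",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage.

    Hashes the stage name into the seed sequence so streams for different
    stages are independent while the whole run stays a function of one seed.
    """
    key = np.frombuffer(stage.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + key.tolist()))


@dataclass
class GenotypeSet:
    """Individuals x variants dosage matrix with coordinates and labels.

    ``dosages`` holds allele counts in {0, 1, 2}; ``chrom``/``pos`` are
    1-based physical coordinates, strictly increasing within a chromosome;
    ``af`` is the allele frequency of the counted allele in the simulated
    founder pool (or the empirical frequency for data read from files).
    """

    dosages: np.ndarray            # (n, m) float64
    chrom: np.ndarray              # (m,) int
    pos: np.ndarray                # (m,) int64, 1-based
    af: np.ndarray                 # (m,)
    ids: np.ndarray                # (n,) str
    breed: np.ndarray              # (n,) str
    sex: np.ndarray                # (n,) 'M' | 'F'

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.ids), len(self.pos)):
            raise ValueError("dosage matrix shape does not match labels")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    def freq(self) -> np.ndarray:
        """Empirical allele frequency per variant (dosage mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.freq()
        return np.minimum(f, 1.0 - f)

    def take_variants(self, idx: np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            af=self.af[idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx, :],
            ids=self.ids[idx],
            breed=self.breed[idx],
            sex=self.sex[idx],
        )


@dataclass
class GroundTruth:
    """Registry of implanted causal variants.

    ``trait_idx``/``trait_effect`` list trait-causal variants and their
    additive effects (trait units per allele); ``expr_idx``/``expr_gene``/
    ``expr_effect`` list expression-causal variants, the gene each acts on
    and the effect on the gene's natural-log mean count.  ``shared`` is the
    subset of variant indices causal for both a trait and a gene.
    """

    trait_idx: np.ndarray
    trait_effect: np.ndarray
    expr_idx: np.ndarray
    expr_gene: np.ndarray          # gene labels, e.g. "G0003"
    expr_effect: np.ndarray
    shared: np.ndarray

    def __post_init__(self) -> None:
        if not set(self.shared) <= (set(self.trait_idx) & set(self.expr_idx)):
            raise ValueError("shared causals must be both trait- and expression-causal")


@dataclass
class PhenotypeTable:
    """Per-individual trait deviations with accuracy class and record counts.

    ``accuracy`` is the correlation between the deviation and the true
    genetic value implied by the noise model; ``n_records`` is the per-record
    basis for meta-analysis weights (1 for an own-performance record).
    ``genetic_value`` keeps the simulated truth for calibration tests.
    """

    ids: np.ndarray
    value: np.ndarray
    accuracy: np.ndarray
    n_records: np.ndarray
    genetic_value: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite trait deviation")


@dataclass
class ExpressionSet:
    """Gene spans, read-count matrix and cow covariates for one cell type.

    ``counts`` is genes x cows (non-negative integers); ``cow_index`` maps
    each cow to its row in the genotype set it was drawn from.
    """

    gene_ids: np.ndarray
    gene_chrom: np.ndarray
    gene_start: np.ndarray
    gene_end: np.ndarray
    counts: np.ndarray             # (G, C) int64
    covariates: pd.DataFrame       # breed, parity, days_in_milk, batch
    cow_ids: np.ndarray
    cow_index: np.ndarray
    cell_type: str = "milk"

    def __post_init__(self) -> None:
        if np.any(self.gene_start > self.gene_end):
            raise ValueError("gene span start > end")
        if np.any(self.counts < 0):
            raise ValueError("negative read count")
        if self.covariates.isna().any().any():
            raise ValueError("incomplete covariates")
        if self.counts.shape != (len(self.gene_ids), len(self.cow_ids)):
            raise ValueError("count matrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cows(self) -> int:
        return self.counts.shape[1]

    def take_genes(self, idx: np.ndarray) -> "ExpressionSet":
        idx = np.asarray(idx)
        return replace(
            self,
            gene_ids=self.gene_ids[idx],
            gene_chrom=self.gene_chrom[idx],
            gene_start=self.gene_start[idx],
            gene_end=self.gene_end[idx],
            counts=self.counts[idx, :],
        )


def draw_breed_freqs(
    p_anc: np.ndarray, fst: float, n_breeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols breed allele frequencies around ancestral frequencies.

    Each breed frequency is Beta-distributed with mean ``p_anc`` and variance
    ``p_anc * (1 - p_anc) * fst``.  ``fst = 0`` returns the ancestral
    frequencies unchanged for every breed.
    """
    p_anc = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if fst < 0 or fst > 0.5:
        raise ValueError("fst must be in [0, 0.5]")
    if fst == 0.0:
        return np.tile(p_anc, (n_breeds, 1))
    scale = (1.0 - fst) / fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    out = rng.beta(np.tile(a, (n_breeds, 1)), np.tile(b, (n_breeds, 1)))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def _founder_haplotypes(
    freq: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_founders: int,
    ld_block_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotype pool with LD decaying over ``ld_block_scale`` bp.

    Alleles come from a Gaussian-copula AR(1) along each chromosome with
    correlation exp(-d / ld_block_scale) between consecutive variants,
    thresholded at the per-variant allele frequency, so the pool itself
    carries distance-decaying LD which the mosaics then inherit.
    """
    from scipy.stats import norm

    m = len(freq)
    d = np.diff(pos.astype(float), prepend=np.inf)
    d[np.concatenate([[True], np.diff(chrom) != 0])] = np.inf  # chromosome starts
    rho = np.exp(-d / float(ld_block_scale))
    z = np.empty((n_founders, m))
    z[:, 0] = rng.standard_normal(n_founders)
    noise = rng.standard_normal((n_founders, m))
    for j in range(1, m):
        z[:, j] = rho[j] * z[:, j - 1] + np.sqrt(1.0 - rho[j] ** 2) * noise[:, j]
    thresh = norm.ppf(np.clip(freq, 1e-6, 1 - 1e-6))
    return (z < thresh[None, :]).astype(np.int8)


def _mosaic_haplotypes(
    founders: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_hap: int,
    ld_block_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotypes as mosaics of a founder pool.

    Along each chromosome the active founder switches between consecutive
    variants with probability 1 - exp(-d / ld_block_scale), where d is the
    physical distance (per-bp recombination rate 1 / ld_block_scale).
    """
    n_founders, m = founders.shape
    d = np.diff(pos.astype(float), prepend=np.inf)
    d[np.concatenate([[True], np.diff(chrom) != 0])] = np.inf
    p_switch = 1.0 - np.exp(-d / float(ld_block_scale))
    switch = rng.random((n_hap, m)) < p_switch[None, :]
    draw = rng.integers(0, n_founders, size=(n_hap, m))
    # carry the last drawn founder forward where no switch occurred
    idx = np.where(switch, np.arange(m)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    source = np.take_along_axis(draw, idx, axis=1)
    return founders[source, np.arange(m)[None, :]]


def simulate_genotypes(
    n_per_breed: tuple[int, ...] = (1600, 400),
    m_variants: int = 5000,
    chrom_lengths: tuple[int, ...] = (40_000_000, 40_000_000),
    fst: float = 0.1,
    ld_block_scale: float = 100_000.0,
    n_founders: int = 24,
    seed: int = 0,
    sex_fraction_male: float = 0.5,
) -> GenotypeSet:
    """Two-breed diploid dosage genotypes with distance-decaying LD.

    Founder haplotypes are drawn per breed at Balding-Nichols frequencies
    around shared ancestral frequencies; individual haplotypes are mosaics of
    the breed's founder pool with per-bp switch rate ``1/ld_block_scale``;
    dosages are sums of two independent mosaics.
    """
    if m_variants < 2:
        raise ValueError("m_variants must be >= 2")
    if any(n <= 0 for n in n_per_breed) or any(L <= 0 for L in chrom_lengths):
        raise ValueError("non-positive dimension")
    rng = stage_rng(seed, "genotypes")

    # variant map: variants spread over chromosomes proportionally to length
    lengths = np.asarray(chrom_lengths, dtype=float)
    m_per = np.maximum(1, np.round(m_variants * lengths / lengths.sum()).astype(int))
    while m_per.sum() != m_variants:
        m_per[int(np.argmax(m_per))] += int(np.sign(m_variants - m_per.sum()))
    chrom_list, pos_list = [], []
    for c, (L, mc) in enumerate(zip(chrom_lengths, m_per), start=1):
        p = np.sort(rng.choice(np.arange(1, int(L) + 1), size=int(mc), replace=False))
        chrom_list.append(np.full(mc, c, dtype=np.int64))
        pos_list.append(p.astype(np.int64))
    chrom = np.concatenate(chrom_list)
    pos = np.concatenate(pos_list)
    m = len(pos)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    breed_freq = draw_breed_freqs(p_anc, fst, len(n_per_breed), rng)

    dosage_blocks, breed_labels, pool_freq_acc = [], [], np.zeros(m)
    n_total = int(sum(n_per_breed))
    for b, n_b in enumerate(n_per_breed):
        founders = _founder_haplotypes(
            breed_freq[b], chrom, pos, n_founders, ld_block_scale, rng
        )
        pool_freq_acc += founders.mean(axis=0) * (n_b / n_total)
        h1 = _mosaic_haplotypes(founders, chrom, pos, n_b, ld_block_scale, rng)
        h2 = _mosaic_haplotypes(founders, chrom, pos, n_b, ld_block_scale, rng)
        dosage_blocks.append((h1 + h2).astype(np.float64))
        breed_labels.append(np.full(n_b, chr(ord("A") + b)))
    dosages = np.vstack(dosage_blocks)
    breed = np.concatenate(breed_labels)
    sex = np.where(rng.random(n_total) < sex_fraction_male, "M", "F")
    ids = np.array([f"ind{i:05d}" for i in range(n_total)])
    return GenotypeSet(dosages, chrom, pos, pool_freq_acc, ids, breed, sex)


def implant_truth(
    g: GenotypeSet,
    n_trait_qtl: int = 10,
    n_eqtl: int = 30,
    n_shared: int = 5,
    effect_sd: float = 1.0,
    expr_effect: float = 1.0,
    min_maf: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Draw trait-causal, expression-causal and shared variants.

    Causals are sampled without replacement among variants with MAF >=
    ``min_maf``; shared causals receive both a trait effect and an
    expression effect.  Trait effects are N(0, effect_sd^2); expression
    effects are +/- ``expr_effect`` natural-log units per allele.
    """
    if n_shared > min(n_trait_qtl, n_eqtl):
        raise ValueError("n_shared exceeds causal set sizes")
    rng = stage_rng(seed, "truth")
    eligible = np.where(g.maf() >= min_maf)[0]
    n_needed = n_trait_qtl + n_eqtl - n_shared
    if len(eligible) < n_needed:
        raise ValueError(f"only {len(eligible)} variants with MAF >= {min_maf}; need {n_needed}")
    picked = rng.choice(eligible, size=n_needed, replace=False)
    shared = np.sort(picked[:n_shared])
    trait_only = picked[n_shared:n_trait_qtl]
    expr_only = picked[n_trait_qtl:]
    trait_idx = np.sort(np.concatenate([shared, trait_only])).astype(np.int64)
    expr_idx = np.sort(np.concatenate([shared, expr_only])).astype(np.int64)
    trait_effect = rng.normal(0.0, effect_sd, size=len(trait_idx))
    expr_gene = np.array([f"G{k:04d}" for k in range(len(expr_idx))])
    expr_effect_arr = rng.choice([-1.0, 1.0], size=len(expr_idx)) * expr_effect
    return GroundTruth(trait_idx, trait_effect, expr_idx, expr_gene, expr_effect_arr, shared)


def genetic_values(g: GenotypeSet, truth: GroundTruth) -> np.ndarray:
    """True additive genetic values implied by the registry."""
    return g.dosages[:, truth.trait_idx] @ truth.trait_effect


def simulate_phenotypes(
    g: GenotypeSet,
    truth: GroundTruth,
    h2: float = 0.5,
    accuracy: dict[str, float] | None = None,
    seed: int = 0,
) -> PhenotypeTable:
    """Trait deviations = genetic value + accuracy-dependent noise.

    Effects are rescaled so the genetic variance is ``h2`` on a unit
    phenotypic-variance scale.  For an individual with accuracy ``acc`` the
    deviation noise variance is ``sigma2_g * (1 - acc^2) / acc^2``, so the
    squared correlation between deviation and genetic value is ``acc^2`` in
    expectation; ``acc = sqrt(h2)`` reproduces a plain own-performance
    phenotype.  Bull-like records (high accuracy) emulate daughter trait
    deviations, cow-like records (low accuracy) plain trait deviations.

    The registry's trait effects are rescaled in place to the same scale so
    truth and phenotypes stay consistent for downstream recovery checks.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    accuracy = accuracy or {"M": 0.95, "F": 0.6}
    for a in accuracy.values():
        if not 0.0 < a <= 1.0:
            raise ValueError("accuracy must be in (0, 1]")
    rng = stage_rng(seed, "phenotypes")
    gv = genetic_values(g, truth)
    var_g = gv.var()
    if var_g > 0:
        scale = np.sqrt(h2 / var_g)
        gv = gv * scale
        truth.trait_effect = truth.trait_effect * scale
        var_g = h2
    acc = np.array([accuracy[s] for s in g.sex])
    # zero genetic variance (all effects zero): keep the nominal unit-phenotype
    # scale so deviations are pure noise rather than identically zero
    var_scale = var_g if var_g > 0 else h2
    noise_sd = np.sqrt(var_scale * (1.0 - acc**2) / acc**2)
    value = gv + rng.normal(0.0, 1.0, size=len(gv)) * noise_sd
    # effective record count behind each deviation (1 own record at acc=sqrt(h2))
    n_rec = np.maximum(1, np.round((acc**2 * (1 - h2)) / np.maximum(h2 * (1 - acc**2), 1e-12))).astype(int)
    return PhenotypeTable(g.ids.copy(), value, acc, n_rec, gv)


def simulate_expression(
    g: GenotypeSet,
    truth: GroundTruth,
    n_genes: int = 300,
    n_cows: tuple[int, ...] = (105, 26),
    baseline_log_mean: float = 4.0,
    dispersion: float = 0.15,
    covariate_effects: dict[str, float] | None = None,
    gene_offset_max: int = 100_000,
    gene_span: int = 20_000,
    cell_type: str = "milk",
    seed: int = 0,
) -> ExpressionSet:
    """Negative-binomial read counts with cis-eQTL effects and covariates.

    The expression cohort is a random female subset of the genotyped set
    (default 105 breed-A + 26 breed-B cows, mirroring a two-breed RNA-seq
    design).  Genes carrying an implanted eQTL are placed within
    ``gene_offset_max`` bp of their causal variant so the effect is cis;
    remaining genes are placed uniformly.  Counts are Gamma-Poisson:
    Poisson(mu * G) with G ~ Gamma(1/dispersion, dispersion), so
    ``dispersion -> 0`` recovers Poisson noise around
    ``mu = exp(baseline + eQTL effect x dosage + covariate terms)``.
    """
    if n_genes < len(truth.expr_idx):
        raise ValueError("n_genes smaller than number of eQTL genes in truth")
    if dispersion < 0:
        raise ValueError("negative dispersion")
    cov_eff = {"breed": 0.2, "parity": 0.05, "days_in_milk": 0.001, "batch": 0.1}
    cov_eff.update(covariate_effects or {})
    rng = stage_rng(seed, f"expression:{cell_type}")

    breeds = np.unique(g.breed)
    cow_index_parts = []
    for b, n_b in zip(breeds, n_cows):
        pool = np.where((g.breed == b) & (g.sex == "F"))[0]
        if len(pool) < n_b:
            pool = np.where(g.breed == b)[0]  # small sims: fall back to any sex
        cow_index_parts.append(rng.choice(pool, size=min(n_b, len(pool)), replace=False))
    cow_index = np.concatenate(cow_index_parts)
    n_c = len(cow_index)

    # gene map: eQTL genes sit near their causal variant, the rest uniform
    chroms = np.unique(g.chrom)
    chrom_max = {c: int(g.pos[g.chrom == c].max()) for c in chroms}
    gene_chrom = np.empty(n_genes, dtype=np.int64)
    gene_start = np.empty(n_genes, dtype=np.int64)
    gene_ids = np.array([f"G{k:04d}" for k in range(n_genes)])
    for k in range(n_genes):
        if k < len(truth.expr_idx):
            v = truth.expr_idx[k]
            gene_chrom[k] = g.chrom[v]
            off = rng.integers(-gene_offset_max, gene_offset_max + 1)
            gene_start[k] = max(1, int(g.pos[v]) + off)
        else:
            c = chroms[rng.integers(len(chroms))]
            gene_chrom[k] = c
            gene_start[k] = rng.integers(1, max(2, chrom_max[c] - gene_span))
    gene_end = gene_start + gene_span

    covariates = pd.DataFrame(
        {
            "breed": g.breed[cow_index],
            "parity": rng.integers(1, 6, size=n_c),
            "days_in_milk": rng.integers(5, 306, size=n_c),
            "batch": np.array([f"b{i}" for i in rng.integers(0, 3, size=n_c)]),
        },
        index=np.arange(n_c),
    )
    cov_term = (
        cov_eff["breed"] * (covariates["breed"].to_numpy() == breeds[-1]).astype(float)
        + cov_eff["parity"] * (covariates["parity"].to_numpy() - 1)
        + cov_eff["days_in_milk"] * (covariates["days_in_milk"].to_numpy() - 150)
        + cov_eff["batch"] * covariates["batch"].str.lstrip("b").astype(int).to_numpy()
    )

    log_mu = np.tile(baseline_log_mean + cov_term, (n_genes, 1))
    gene_base = rng.normal(0.0, 0.5, size=n_genes)  # gene-level abundance spread
    log_mu += gene_base[:, None]
    for k, (v, eff) in enumerate(zip(truth.expr_idx, truth.expr_effect)):
        log_mu[k] += eff * g.dosages[cow_index, v]
    mu = np.exp(np.clip(log_mu, -30, 30))
    if dispersion > 0:
        gamma_mult = rng.gamma(1.0 / dispersion, dispersion, size=mu.shape)
        counts = rng.poisson(mu * gamma_mult)
    else:
        counts = rng.poisson(mu)
    return ExpressionSet(
        gene_ids,
        gene_chrom,
        gene_start,
        gene_end,
        counts.astype(np.int64),
        covariates,
        g.ids[cow_index],
        cow_index,
        cell_type,
    )
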