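"""Colocalisation of QTL and eQTL via configuration-enumeration fine mapping.

For each QTL lead, genes within 1 Mb anchor loci of all variants within 1 Mb
of the gene; each eQTL gene anchors one locus the same way.  Within a locus,
the vector of marginal z-scores from one study is modelled as multivariate
normal: under a causal configuration c (a subset of variants),

    z ~ N(0, S + s^2 * S diag(c) S)

where S is the dosage-correlation (LD) matrix and s the non-centrality scale
of a causal effect.  With an independent Bernoulli(gamma) prior per variant,
the posterior inclusion probability (PIP) of variant i sums the posterior
weight of all configurations containing i.  PIPs are computed independently
in the GWAS and the eQTL study; their product is the colocalisation
posterior probability (CLPP), and variants with CLPP >= 0.01 are flagged as
shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .assoc import QtlCall
from .eqtl import EqtlCall
from .synthdata import GenotypeSet

__all__ = [
    "Locus",
    "build_loci",
    "ld_matrix",
    "finemap_pips",
    "clpp",
    "colocalisation_summary",
]

CLPP_THRESHOLD = 0.01


@dataclass
class Locus:
    """Variants around an anchor with z-vectors in both studies and their LD."""

    anchor: str                    # "qtl:<variant>" or "eqtl:<gene>"
    gene: str
    members: np.ndarray            # variant indices, ordered by position
    z_gwas: np.ndarray
    z_eqtl: np.ndarray
    ld: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.members)
        if self.z_gwas.shape != (m,) or self.z_eqtl.shape != (m,) or self.ld.shape != (m, m):
            raise ValueError("locus shapes inconsistent")


def ld_matrix(g: GenotypeSet, members: np.ndarray, ridge: float = 1e-4) -> np.ndarray:
    """Pairwise dosage correlation over ``members`` with a diagonal ridge."""
    members = np.asarray(members, dtype=int)
    if members.size < 1:
        raise ValueError("empty member set")
    x = g.dosages[:, members]
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = members[np.where(sd == 0)[0][0]]
        raise ValueError(f"variant {bad} is monomorphic in the cohort")
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[np.diag_indices_from(r)] += ridge
    return r


def build_loci(
    qtl: list[QtlCall],
    eqtl: list[EqtlCall],
    g: GenotypeSet,
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    gene_map: pd.DataFrame,
    radius: int = 1_000_000,
    cap: int = 50,
) -> list[Locus]:
    """Loci for every (QTL, nearby gene) pair and every eQTL gene.

    ``gene_map`` needs columns gene/chrom/start/end.  A locus holds the
    variants within ``radius`` of the gene span that carry finite statistics
    in both studies (the eQTL side is gene-specific), capped to the ``cap``
    variants with the largest max(|z_gwas|, |z_eqtl|).  Loci with no such
    variant are dropped; duplicate (anchor, gene) pairs are emitted once.
    """
    gz = gwas_stats.set_index("variant")["z"]
    loci: list[Locus] = []
    seen: set[tuple[str, str]] = set()

    def make_locus(anchor: str, gene_row) -> Locus | None:
        gene = str(gene_row.gene)
        eq = eqtl_stats.loc[eqtl_stats["gene"] == gene].set_index("variant")["z"]
        on = np.where(
            (g.chrom == gene_row.chrom)
            & (g.pos >= gene_row.start - radius)
            & (g.pos <= gene_row.end + radius)
        )[0]
        members, zg, ze = [], [], []
        for v in on:
            if v in eq.index and v in gz.index:
                z1, z2 = float(gz.loc[v]), float(eq.loc[v])
                if np.isfinite(z1) and np.isfinite(z2):
                    members.append(int(v))
                    zg.append(z1)
                    ze.append(z2)
        if not members:
            return None
        members = np.array(members)
        zg = np.array(zg)
        ze = np.array(ze)
        if len(members) > cap:
            score = np.maximum(np.abs(zg), np.abs(ze))
            keep = np.sort(np.argsort(-score)[:cap])
            members, zg, ze = members[keep], zg[keep], ze[keep]
        try:
            ld = ld_matrix(g, members)
        except ValueError:
            poly = g.dosages[:, members].std(axis=0) > 0
            if not poly.any():
                return None
            members, zg, ze = members[poly], zg[poly], ze[poly]
            ld = ld_matrix(g, members)
        return Locus(anchor, gene, members, zg, ze, ld)

    for q in qtl:
        near = gene_map.loc[
            (gene_map["chrom"] == q.chrom)
            & (gene_map["end"] >= q.pos - radius)
            & (gene_map["start"] <= q.pos + radius)
        ]
        for row in near.itertuples():
            key = (f"qtl:{q.variant}", str(row.gene))
            if key in seen:
                continue
            seen.add(key)
            loc = make_locus(key[0], row)
            if loc is not None:
                loci.append(loc)
    for eq_call in eqtl:
        row = gene_map.loc[gene_map["gene"] == eq_call.gene]
        if row.empty:
            continue
        key = (f"eqtl:{eq_call.gene}", eq_call.gene)
        if key in seen:
            continue
        seen.add(key)
        loc = make_locus(key[0], next(row.itertuples()))
        if loc is not None:
            loci.append(loc)
    return loci


def _config_loglik(z: np.ndarray, sigma: np.ndarray, idx: tuple[int, ...], ncp_sd: float) -> float:
    """Log N(z; 0, Sigma + ncp_sd^2 Sigma[:,c] Sigma[c,:])."""
    cov = sigma.copy()
    if idx:
        sc = sigma[:, list(idx)]
        cov = cov + (ncp_sd**2) * (sc @ sc.T)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    sol = np.linalg.solve(cov, z)
    return -0.5 * (len(z) * np.log(2 * np.pi) + logdet + float(z @ sol))


def finemap_pips(
    z: np.ndarray,
    sigma: np.ndarray,
    gamma: float = 0.01,
    ncp_sd: float = 5.2,
    max_causals: int = 2,
) -> np.ndarray:
    """Posterior inclusion probabilities by enumerating causal configurations.

    Configurations of size 0..max_causals get prior gamma^|c| (1-gamma)^(m-|c|)
    and the multivariate-normal likelihood above; PIP_i is the normalized
    posterior mass of configurations containing i (the null configuration
    contributes to the normalization only).
    """
    z = np.asarray(z, dtype=float)
    m = len(z)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z score")
    log_prior_per = np.log(gamma) - np.log(1.0 - gamma)
    base_prior = m * np.log(1.0 - gamma)
    logws = []
    configs: list[tuple[int, ...]] = []
    for size in range(0, min(max_causals, m) + 1):
        for idx in combinations(range(m), size):
            logws.append(
                base_prior + size * log_prior_per + _config_loglik(z, sigma, idx, ncp_sd)
            )
            configs.append(idx)
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    w /= w.sum()
    pips = np.zeros(m)
    for weight, idx in zip(w, configs):
        for i in idx:
            pips[i] += weight
    return np.clip(pips, 0.0, 1.0)


def clpp(
    pip_gwas: np.ndarray, pip_eqtl: np.ndarray, threshold: float = CLPP_THRESHOLD
) -> pd.DataFrame:
    """Per-variant CLPP = PIP_gwas x PIP_eqtl with the shared flag."""
    pip_gwas = np.asarray(pip_gwas, dtype=float)
    pip_eqtl = np.asarray(pip_eqtl, dtype=float)
    if pip_gwas.shape != pip_eqtl.shape:
        raise ValueError("PIP vectors differ in length")
    c = pip_gwas * pip_eqtl
    return pd.DataFrame(
        {"pip_gwas": pip_gwas, "pip_eqtl": pip_eqtl, "clpp": c, "shared": c >= threshold}
    )


def score_loci(
    loci: list[Locus],
    gamma: float = 0.01,
    ncp_sd: float = 5.2,
    max_causals: int = 2,
    threshold: float = CLPP_THRESHOLD,
) -> pd.DataFrame:
    """Fine-map both studies at every locus and tabulate per-variant CLPP."""
    frames = []
    for loc in loci:
        pg = finemap_pips(loc.z_gwas, loc.ld, gamma, ncp_sd, max_causals)
        pe = finemap_pips(loc.z_eqtl, loc.ld, gamma, ncp_sd, max_causals)
        df = clpp(pg, pe, threshold)
        df.insert(0, "variant", loc.members)
        df.insert(1, "anchor", loc.anchor)
        df.insert(2, "gene", loc.gene)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["variant", "anchor", "gene", "pip_gwas", "pip_eqtl", "clpp", "shared"]
        )
    return pd.concat(frames, ignore_index=True)


def colocalisation_summary(
    records: pd.DataFrame, qtl: list[QtlCall], eqtl: list[EqtlCall]
) -> dict[str, int]:
    """Counts of QTL and eQTL genes with at least one shared variant."""
    shared = records.loc[records["shared"]]
    coloc_qtl = sum(
        1
        for q in qtl
        if not shared.loc[shared["anchor"] == f"qtl:{q.variant}"].empty
    )
    shared_genes = set(shared["gene"].astype(str))
    coloc_eqtl = sum(1 for e in eqtl if e.gene in shared_genes)
    return {
        "n_qtl": len(qtl),
        "coloc_qtl": coloc_qtl,
        "n_eqtl": len(eqtl),
        "coloc_eqtl": coloc_eqtl,
    }
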