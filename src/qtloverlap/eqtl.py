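"""Expression preprocessing and cis-eQTL scanning.

Genes expressed (count > 0) in fewer than 25 cows are dropped; read counts
are transformed to ln(count + 1).  Each variant is tested against the
expression of every gene whose span lies within 1 Mb, using the same
mixed-model Wald test as the GWAS (variance components per gene under the
null, relatedness from a GRM over the expression cows) with breed, parity,
days in milk and sequencing batch as fixed effects.  At most one eQTL call
is emitted per gene (its smallest-p cis variant, if below threshold).
Trans pairs are never tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import Grm, VarianceComponents, _emmax_rotate, fit_null_variance, P_FLOOR
from .synthdata import ExpressionSet, GenotypeSet

__all__ = [
    "CisPair",
    "EqtlCall",
    "filter_genes",
    "log_transform",
    "covariate_design",
    "cis_pairs",
    "eqtl_scan",
    "select_eqtl",
]

CIS_RADIUS = 1_000_000


@dataclass(frozen=True)
class CisPair:
    """A variant-gene pair within the cis radius; distance 0 if inside the span."""

    variant: int
    gene: str
    distance: int


@dataclass(frozen=True)
class EqtlCall:
    """Lead cis variant for a gene (at most one call per gene)."""

    gene: str
    variant: int
    chrom: int
    pos: int
    p: float
    sign: float


def filter_genes(e: ExpressionSet, min_expressed: int = 25) -> ExpressionSet:
    """Keep genes with count > 0 in at least ``min_expressed`` cows."""
    n_expr = (e.counts > 0).sum(axis=1)
    return e.take_genes(np.where(n_expr >= min_expressed)[0])


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Natural log of (count + 1), elementwise."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return np.log1p(counts.astype(float))


def covariate_design(e: ExpressionSet) -> np.ndarray:
    """Intercept + breed and batch indicators + parity + days in milk."""
    cov = e.covariates
    cols = [np.ones(e.n_cows)]
    for name in ("breed", "batch"):
        levels = np.unique(cov[name])
        for lev in levels[1:]:
            cols.append((cov[name].to_numpy() == lev).astype(float))
    cols.append(cov["parity"].to_numpy(dtype=float))
    cols.append(cov["days_in_milk"].to_numpy(dtype=float))
    return np.column_stack(cols)


def cis_pairs(
    g: GenotypeSet, e: ExpressionSet, radius: int = CIS_RADIUS
) -> list[CisPair]:
    """All variant-gene pairs with the variant within ``radius`` of the gene span."""
    pairs: list[CisPair] = []
    for k in range(e.n_genes):
        c, s, t = int(e.gene_chrom[k]), int(e.gene_start[k]), int(e.gene_end[k])
        on_chrom = np.where(g.chrom == c)[0]
        p = g.pos[on_chrom]
        lo = np.searchsorted(p, s - radius, side="left")
        hi = np.searchsorted(p, t + radius, side="right")
        for j in on_chrom[lo:hi]:
            pos = int(g.pos[j])
            dist = 0 if s <= pos <= t else min(abs(pos - s), abs(pos - t))
            pairs.append(CisPair(int(j), str(e.gene_ids[k]), dist))
    return pairs


def eqtl_scan(
    g: GenotypeSet,
    e: ExpressionSet,
    grm: Grm,
    pairs: list[CisPair],
    log_expr: np.ndarray | None = None,
    study: str = "eqtl",
) -> pd.DataFrame:
    """Mixed-model Wald test of dosage on log expression per cis pair.

    ``g`` must be restricted to the expression cows in the same order as
    ``e``; variance components are fitted once per gene under the null.
    Genes with a singular covariate design are skipped with a NaN row.
    """
    if g.n_individuals != e.n_cows:
        raise ValueError("genotypes must be subset to the expression cows")
    y_all = log_transform(e.counts) if log_expr is None else log_expr
    x = covariate_design(e)
    by_gene: dict[str, list[CisPair]] = {}
    for pr in pairs:
        by_gene.setdefault(pr.gene, []).append(pr)
    gene_row = {str(gid): k for k, gid in enumerate(e.gene_ids)}

    rows = []
    n, p_fix = e.n_cows, x.shape[1]
    df = n - p_fix - 1
    for gene, prs in by_gene.items():
        if gene not in gene_row:
            continue
        y = y_all[gene_row[gene]]
        members = np.array([pr.variant for pr in prs], dtype=int)
        try:
            vc = fit_null_variance(y, x, grm)
        except ValueError:
            for pr in prs:
                rows.append((pr.variant, gene, np.nan, np.nan, np.nan))
            continue
        u, w = _emmax_rotate(grm, vc)
        yt = w * (u.T @ y)
        xt = w[:, None] * (u.T @ x)
        gt = w[:, None] * (u.T @ g.dosages[:, members])
        q, _ = np.linalg.qr(xt)
        yr = yt - q @ (q.T @ yt)
        gr = gt - q @ (q.T @ gt)
        xtx = np.einsum("ij,ij->j", gr, gr)
        mono = xtx <= 1e-12
        xtx_safe = np.where(mono, np.nan, xtx)
        xty = gr.T @ yr
        beta = xty / xtx_safe
        s2 = (float(yr @ yr) - beta * xty) / df
        se = np.sqrt(s2 / xtx_safe)
        tval = beta / se
        pv = 2.0 * stats.t.sf(np.abs(tval), df)
        for i, pr in enumerate(prs):
            rows.append((pr.variant, gene, beta[i], se[i], pv[i]))

    out = pd.DataFrame(rows, columns=["variant", "gene", "beta", "se", "p"])
    out["chrom"] = g.chrom[out["variant"].to_numpy()]
    out["pos"] = g.pos[out["variant"].to_numpy()]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z"] = out["beta"] / out["se"]
    out["p"] = out["p"].clip(P_FLOOR, 1.0)
    out["n"] = n
    out["direction"] = np.sign(out["beta"].fillna(0.0))
    out["study"] = study
    return out[
        ["variant", "chrom", "pos", "beta", "se", "z", "p", "n", "direction", "study", "gene"]
    ]


def select_eqtl(stats: pd.DataFrame, p_thresh: float = 1e-5) -> list[EqtlCall]:
    """Per-gene lead variant (smallest p; ties by chromosome then position).

    A call is emitted only if the lead p-value is at or below threshold.
    """
    calls: list[EqtlCall] = []
    ok = stats.loc[np.isfinite(stats["p"])]
    for gene, sub in ok.groupby("gene", sort=True):
        sub = sub.sort_values(["p", "chrom", "pos"], kind="mergesort")
        lead = sub.iloc[0]
        if lead["p"] <= p_thresh:
            calls.append(
                EqtlCall(
                    str(gene),
                    int(lead["variant"]),
                    int(lead["chrom"]),
                    int(lead["pos"]),
                    float(lead["p"]),
                    float(np.sign(lead["beta"])),
                )
            )
    return calls
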