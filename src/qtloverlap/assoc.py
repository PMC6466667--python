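"""Mixed-model single-variant association and meta-analysis.

GWAS follows the two-step mixed-model strategy common in livestock genetics:
variance components are estimated once per trait under the null model with a
genomic relationship matrix (GRM) capturing population structure, then every
variant is tested by generalized least squares with the covariance fixed at
the null estimates (the EMMAX approximation).  Scans are run separately for
the high-accuracy (bull-like) and low-accuracy (cow-like) strata and combined
with the sample-size-weighted z-score meta-analysis scheme used by METAL.
QTL leads are picked greedily: smallest p first, suppressing variants within
a 1 Mb spacing on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthdata import GenotypeSet

__all__ = [
    "Grm",
    "QtlCall",
    "filter_variants",
    "compute_grm",
    "fit_null_variance",
    "gwas_scan",
    "meta_weighted_z",
    "select_qtl",
    "breed_design",
]

P_FLOOR = 1e-300  # representable floor for p-values entering z transforms
GRM_RIDGE = 1e-6


@dataclass
class Grm:
    """VanRaden (method 1) genomic relationship matrix with its eigenbasis."""

    matrix: np.ndarray
    ids: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class QtlCall:
    """A QTL lead variant from greedy p-value selection."""

    variant: int
    chrom: int
    pos: int
    p: float
    trait: str = "trait"


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    x = dosages - dosages.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    r = (x.T @ x) / (len(x) * np.outer(sd, sd))
    return r**2


def filter_variants(
    g: GenotypeSet, maf_floor: float = 0.002, r2_cap: float = 0.9, scan_window: int = 50
) -> GenotypeSet:
    """MAF filter followed by greedy left-to-right LD pruning.

    Variants with MAF below ``maf_floor`` are dropped; then, sweeping each
    chromosome left to right, a variant is dropped if its r^2 with any
    *kept* variant among the previous ``scan_window`` kept variants exceeds
    ``r2_cap`` (the earlier variant wins).
    """
    if not 0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must be in [0, 0.5)")
    if not 0 < r2_cap <= 1:
        raise ValueError("r2_cap must be in (0, 1]")
    keep_maf = np.where(g.maf() >= maf_floor)[0]
    gm = g.take_variants(keep_maf)

    x = gm.dosages - gm.dosages.mean(axis=0)
    sd = x.std(axis=0)
    n = x.shape[0]
    kept: list[int] = []
    recent: list[int] = []  # kept indices on the current chromosome
    cur_chrom = None
    for j in range(gm.m_variants):
        if gm.chrom[j] != cur_chrom:
            cur_chrom = gm.chrom[j]
            recent = []
        prune = False
        if sd[j] > 0:
            for i in recent[-scan_window:]:
                if sd[i] == 0:
                    continue
                r = float(x[:, i] @ x[:, j]) / (n * sd[i] * sd[j])
                if r * r > r2_cap:
                    prune = True
                    break
        if not prune:
            kept.append(j)
            recent.append(j)
    return gm.take_variants(np.array(kept, dtype=int))


def compute_grm(g: GenotypeSet, ridge: float = GRM_RIDGE) -> Grm:
    """Centered-dosage cross-product scaled by 2*sum(p(1-p)) (VanRaden 1)."""
    p = g.freq()
    poly = g.dosages.std(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic variants for a GRM")
    z = g.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    k = (z @ z.T) / denom
    k[np.diag_indices_from(k)] += ridge
    vals, vecs = np.linalg.eigh(k)
    vals = np.maximum(vals, 0.0)
    return Grm(k, g.ids.copy(), vals, vecs)


def _reml_neg_loglik(h2: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    lam = h2 / (1.0 - h2)
    v = lam * d + 1.0
    n, p = xr.shape
    xtvx = xr.T @ (xr / v[:, None])
    xtvy = xr.T @ (yr / v)
    beta = np.linalg.solve(xtvx, xtvy)
    resid = yr - xr @ beta
    rss = float(resid @ (resid / v))
    sigma2 = rss / (n - p)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    ll = -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(v)) + logdet_x + (n - p))
    return -ll


def fit_null_variance(
    y: np.ndarray, covariates: np.ndarray, grm: Grm
) -> VarianceComponents:
    """REML variance components by 1-D search over h2 on the GRM eigenbasis."""
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("phenotype has zero variance")
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular covariate design")
    u, d = grm.eigvecs, grm.eigvals
    yr = u.T @ y
    xr = u.T @ x
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(1e-6, 1.0 - 1e-6),
        args=(d, yr, xr),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    lam = h2 / (1.0 - h2)
    v = lam * d + 1.0
    xtvx = xr.T @ (xr / v[:, None])
    beta = np.linalg.solve(xtvx, xr.T @ (yr / v))
    resid = yr - xr @ beta
    sigma2_e = float(resid @ (resid / v)) / (len(y) - x.shape[1])
    return VarianceComponents(lam * sigma2_e, sigma2_e, -float(res.fun))


def _emmax_rotate(grm: Grm, vc: VarianceComponents):
    """Whitening weights on the GRM eigenbasis for V = sg*K + se*I."""
    w = 1.0 / np.sqrt(vc.sigma2_g * grm.eigvals + vc.sigma2_e)
    return grm.eigvecs, w


def assoc_frame(
    chrom, pos, beta, se, p, n, study: str, variant=None, gene=None
) -> pd.DataFrame:
    """Standard marginal-statistics table (the S^(p) / S^(e) container)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.asarray(beta) / np.asarray(se)
    df = pd.DataFrame(
        {
            "variant": np.arange(len(pos)) if variant is None else variant,
            "chrom": chrom,
            "pos": pos,
            "beta": beta,
            "se": se,
            "z": z,
            "p": np.clip(p, P_FLOOR, 1.0),
            "n": n,
            "direction": np.sign(np.nan_to_num(beta)),
            "study": study,
        }
    )
    if gene is not None:
        df["gene"] = gene
    return df


def gwas_scan(
    g: GenotypeSet,
    y: np.ndarray,
    covariates: np.ndarray,
    grm: Grm,
    vc: VarianceComponents,
    study: str = "gwas",
) -> pd.DataFrame:
    """Per-variant GLS Wald test with covariance fixed at the null estimate.

    After whitening by V^{-1/2}, phenotype and dosages are residualized on
    the fixed effects and each variant is tested by simple regression; this
    reproduces exact per-variant GLS (EMMAX).  With an identity GRM the
    result coincides with OLS.  Monomorphic variants return NaN statistics.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    u, w = _emmax_rotate(grm, vc)
    yt = w * (u.T @ y)
    xt = w[:, None] * (u.T @ x)
    gt = w[:, None] * (u.T @ g.dosages)
    q, _ = np.linalg.qr(xt)
    yr = yt - q @ (q.T @ yt)
    gr = gt - q @ (q.T @ gt)
    xtx = np.einsum("ij,ij->j", gr, gr)
    xty = gr.T @ yr
    n, p_fix = len(y), x.shape[1]
    df = n - p_fix - 1
    mono = xtx <= 1e-12
    xtx_safe = np.where(mono, np.nan, xtx)
    beta = xty / xtx_safe
    sse = float(yr @ yr) - beta * xty
    s2 = sse / df
    se = np.sqrt(s2 / xtx_safe)
    tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    return assoc_frame(g.chrom, g.pos, beta, se, p, np.full(g.m_variants, n), study)


def breed_design(g: GenotypeSet) -> np.ndarray:
    """Intercept plus breed-indicator fixed-effect design."""
    breeds = np.unique(g.breed)
    cols = [np.ones(g.n_individuals)]
    for b in breeds[1:]:
        cols.append((g.breed == b).astype(float))
    return np.column_stack(cols)


def meta_weighted_z(stats_by_stratum: list[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis (METAL scheme).

    Per variant: z_i = direction x Phi^{-1}(1 - p_i/2), w_i = sqrt(n_i),
    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)), two-sided normal p.  Missing
    strata are dropped per variant; a variant missing everywhere stays NaN.
    """
    if not stats_by_stratum:
        raise ValueError("no strata")
    base = stats_by_stratum[0]
    m = len(base)
    zs = np.full((len(stats_by_stratum), m), np.nan)
    ws = np.zeros((len(stats_by_stratum), m))
    for k, s in enumerate(stats_by_stratum):
        if len(s) != m:
            raise ValueError("strata do not share variant order")
        p = s["p"].to_numpy()
        direction = s["direction"].to_numpy()
        ok = np.isfinite(p)
        zi = np.where(ok, direction * stats.norm.isf(np.clip(p, P_FLOOR, 1.0) / 2.0), np.nan)
        zs[k] = zi
        ws[k] = np.where(ok, np.sqrt(s["n"].to_numpy()), 0.0)
    num = np.nansum(ws * zs, axis=0)
    den = np.sqrt(np.sum(ws**2, axis=0))
    all_missing = den == 0
    z_meta = np.where(all_missing, np.nan, num / np.where(all_missing, np.nan, den))
    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
    n_tot = np.sum(ws**2, axis=0)
    out = pd.DataFrame(
        {
            "variant": base["variant"].to_numpy(),
            "chrom": base["chrom"].to_numpy(),
            "pos": base["pos"].to_numpy(),
            "beta": z_meta,  # on the z scale; effect units are not defined for this scheme
            "se": np.ones(m),
            "z": z_meta,
            "p": np.clip(p_meta, P_FLOOR, 1.0),
            "n": n_tot,
            "direction": np.sign(np.nan_to_num(z_meta)),
            "study": "meta",
        }
    )
    return out


def select_qtl(
    stats: pd.DataFrame, p_thresh: float = 1e-6, spacing: int = 1_000_000, trait: str = "trait"
) -> list[QtlCall]:
    """Greedy QTL lead selection with a minimum spacing between leads.

    Repeatedly takes the smallest-p remaining variant with p <= threshold and
    suppresses variants strictly within ``spacing`` bp on the same
    chromosome (leads exactly ``spacing`` apart are both kept).  Ties on p
    break by (chromosome, position) ascending.
    """
    s = stats.loc[np.isfinite(stats["p"]) & (stats["p"] <= p_thresh)]
    s = s.sort_values(["p", "chrom", "pos"], kind="mergesort")
    calls: list[QtlCall] = []
    taken_chrom: list[int] = []
    taken_pos: list[int] = []
    for row in s.itertuples():
        suppressed = any(
            c == row.chrom and abs(p - row.pos) < spacing
            for c, p in zip(taken_chrom, taken_pos)
        )
        if suppressed:
            continue
        calls.append(QtlCall(int(row.variant), int(row.chrom), int(row.pos), float(row.p), trait))
        taken_chrom.append(row.chrom)
        taken_pos.append(row.pos)
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls
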