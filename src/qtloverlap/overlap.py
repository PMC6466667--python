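"""Overlap analyses between trait QTL windows and expression signal.

Four devices connect the trait side (local GEBV windows) with the expression
side (cis-eQTL, log expression):

* Pearson correlation between a window's local GEBV and the expression of
  every gene within 1 Mb, with a t-based two-sided p-value;
* a permutation comparison that scrambles effects within windows and
  re-counts significant correlations, isolating how much correlation LD
  alone would produce;
* the top-k versus random-k enrichment with the interval filter chain
  nE (contains an eQTL), nG (variant correlated with the local GEBV),
  nEG (one variant does both for the same gene), nC (local GEBV correlated
  with a nearby gene), nEC, and nEGC (all of it with consistent signs);
* the study's FDR estimator: expected false positives (threshold x number
  of tests) over observed significant calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import CIS_RADIUS
from .synthdata import ExpressionSet, GenotypeSet, stage_rng
from .windows import (
    LocalGebvSet,
    NonOverlapRanking,
    Window,
    local_gebv_from_member_effects,
    permute_effects_within_windows,
)

__all__ = [
    "pearson_with_p",
    "correlate_gebv_expression",
    "correlate_genotype_gebv",
    "permutation_comparison",
    "select_top_k",
    "select_random_k",
    "interval_flags",
    "counts_from_flags",
    "enrichment_counts",
    "EnrichmentCounts",
    "fdr",
    "residualize",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df.

    Constant input yields (nan, nan) rather than an exception; |r| = 1
    returns p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return (r, float(p))


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of rows of ``y`` on a covariate design (least squares)."""
    q, _ = np.linalg.qr(design)
    return y - (y @ q) @ q.T


def _window_gene_pairs(
    windows: list[Window], e: ExpressionSet, radius: int
) -> list[tuple[int, int]]:
    """(window index, gene row) pairs with the gene span within radius of the window."""
    pairs = []
    for w_i, w in enumerate(windows):
        near = (
            (e.gene_chrom == w.chrom)
            & (e.gene_end >= w.start - radius)
            & (e.gene_start < w.end + radius)
        )
        for k in np.where(near)[0]:
            pairs.append((w_i, int(k)))
    return pairs


def _bulk_pearson(
    a: np.ndarray, b: np.ndarray, pairs_a: np.ndarray, pairs_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and p over index pairs of rows of ``a`` and ``b``."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    num = np.einsum("ij,ij->i", az[pairs_a], bz[pairs_b])
    den = asd[pairs_a] * bsd[pairs_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(num / den, -1.0, 1.0)
    r[den == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return r, p


def correlate_gebv_expression(
    lg: LocalGebvSet,
    e: ExpressionSet,
    log_expr: np.ndarray,
    radius: int = CIS_RADIUS,
    p_select: float = 1e-5,
) -> pd.DataFrame:
    """Correlation records for every (window, nearby gene) pair.

    ``log_expr`` is the genes x cows expression matrix (log counts, usually
    covariate-residualized), aligned with the cows of ``lg.gebv``.  The
    ``selected`` flag marks records with p <= ``p_select``.
    """
    if lg.gebv.shape[1] != log_expr.shape[1]:
        raise ValueError("GEBV and expression cohorts differ")
    pairs = _window_gene_pairs(lg.windows, e, radius)
    if not pairs:
        return pd.DataFrame(columns=["window", "gene", "r", "p", "n", "selected"])
    wi = np.array([p[0] for p in pairs])
    gi = np.array([p[1] for p in pairs])
    r, p = _bulk_pearson(lg.gebv, log_expr, wi, gi)
    return pd.DataFrame(
        {
            "window": wi,
            "gene": e.gene_ids[gi],
            "r": r,
            "p": p,
            "n": lg.gebv.shape[1],
            "selected": p <= p_select,
        }
    )


def correlate_genotype_gebv(g: GenotypeSet, lg: LocalGebvSet) -> pd.DataFrame:
    """Correlation of each member variant's dosage with its window's local GEBV.

    ``g`` holds the expression cohort (same cows as ``lg``).  Variants that
    are monomorphic in the cohort get NaN and a ``monomorphic`` flag.
    """
    rows_w, rows_v = [], []
    for w_i, w in enumerate(lg.windows):
        for v in w.members:
            rows_w.append(w_i)
            rows_v.append(v)
    wi = np.array(rows_w, dtype=int)
    vi = np.array(rows_v, dtype=int)
    r, p = _bulk_pearson(lg.gebv, np.ascontiguousarray(g.dosages.T), wi, vi)
    return pd.DataFrame(
        {
            "window": wi,
            "variant": vi,
            "r": r,
            "p": p,
            "monomorphic": ~np.isfinite(r),
        }
    )


def permutation_comparison(
    g: GenotypeSet,
    eff,
    windows: list[Window],
    e: ExpressionSet,
    log_expr: np.ndarray,
    reps: int = 100,
    p_select: float = 1e-5,
    radius: int = CIS_RADIUS,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Observed vs within-window-permuted significant-correlation counts.

    For each replicate the member effects of every window are permuted
    independently, local GEBVs recomputed, and correlations with nearby gene
    expression re-counted at ``p_select``.  Returns the observed count and
    the per-replicate permuted counts.
    """
    from .windows import local_gebv

    lg = local_gebv(g, eff, windows)
    obs = int(correlate_gebv_expression(lg, e, log_expr, radius, p_select)["selected"].sum())
    pairs = _window_gene_pairs(windows, e, radius)
    counts = np.zeros(reps, dtype=int)
    if not pairs:
        return obs, counts
    wi = np.array([p[0] for p in pairs])
    gi = np.array([p[1] for p in pairs])
    rng = stage_rng(seed, "permutation-comparison")
    for rep in range(reps):
        member_eff = permute_effects_within_windows(
            eff, windows, seed=int(rng.integers(2**31))
        )
        lg_perm = local_gebv_from_member_effects(g, windows, member_eff)
        _, p = _bulk_pearson(lg_perm.gebv, log_expr, wi, gi)
        counts[rep] = int(np.sum(p <= p_select))
    return obs, counts


def select_top_k(
    ranking: NonOverlapRanking, lg: LocalGebvSet, k: int = 300
) -> tuple[list[int], float]:
    """First k accepted windows by variance order and their share of the sum.

    Returns (window indices, share %).  If fewer than k windows were
    accepted the full accepted set is returned.
    """
    top = ranking.accepted[: min(k, ranking.u)]
    share = 100.0 * float(sum(lg.var[i] for i in top)) / ranking.sigma2_sum if ranking.sigma2_sum > 0 else 0.0
    return list(top), share


def select_random_k(
    windows: list[Window], k: int = 300, seed: int = 0, max_tries: int = 100_000
) -> list[int]:
    """k non-overlapping windows by uniform sequential rejection sampling."""
    rng = stage_rng(seed, "random-k")
    order = rng.permutation(len(windows))
    picked: list[int] = []
    for i in order:
        if len(picked) == k:
            break
        if not any(windows[i].overlaps(windows[j]) for j in picked):
            picked.append(int(i))
    if len(picked) < k:
        raise ValueError(f"could not place {k} non-overlapping windows")
    return picked


@dataclass
class EnrichmentCounts:
    """Interval counts for one window set and trait (Table-5-style)."""

    label: str
    n_windows: int
    nE: int
    nG: int
    nEG: int
    nC: int
    nEC: int
    nEGC: int

    def __post_init__(self) -> None:
        if not (
            self.nEG <= min(self.nE, self.nG)
            and self.nEC <= min(self.nE, self.nC)
            and self.nEGC <= min(self.nEG, self.nC)
        ):
            raise ValueError("inconsistent enrichment count chain")


def interval_flags(
    window_set: list[int],
    lg: LocalGebvSet,
    e: ExpressionSet,
    eqtl_stats: pd.DataFrame,
    geno_gebv: pd.DataFrame,
    gebv_expr: pd.DataFrame,
    p_e: float = 1e-5,
    p_g: float = 1e-5,
    p_c: float = 1e-3,
    radius: int = CIS_RADIUS,
) -> pd.DataFrame:
    """Per-interval boolean predicates of the filter chain.

    Per interval: E holds iff some variant in it has eQTL p <= p_e for a
    gene within ``radius``; G iff some member variant's genotype-GEBV
    correlation has p <= p_g; EG iff one variant satisfies both for the same
    gene; C iff the GEBV-expression correlation with a nearby gene has
    p <= p_c; EC iff E and C hold for the same gene; EGC iff EG and C hold
    for the same gene and sign(eQTL effect) x sign(variant-GEBV r) equals
    sign(GEBV-expression r).  Returns one row per window in ``window_set``.
    """
    def _sig(df: pd.DataFrame, thresh: float) -> pd.DataFrame:
        p = df["p"].astype(float)
        return df.loc[np.isfinite(p) & (p <= thresh)]

    eq = _sig(eqtl_stats, p_e)
    gg = _sig(geno_gebv, p_g)
    ce = _sig(gebv_expr, p_c)
    gg_by_w = dict(tuple(gg.groupby("window")))
    ce_by_w = dict(tuple(ce.groupby("window")))

    rows = []
    for w_i in window_set:
        w = lg.windows[w_i]
        members = set(w.members)
        near_genes = {
            str(e.gene_ids[k])
            for k in range(e.n_genes)
            if e.gene_chrom[k] == w.chrom
            and e.gene_end[k] >= w.start - radius
            and e.gene_start[k] < w.end + radius
        }
        eq_w = eq.loc[eq["variant"].isin(members) & eq["gene"].isin(near_genes)]
        has_e = len(eq_w) > 0
        gg_w = gg_by_w.get(w_i)
        has_g = gg_w is not None
        sig_vars = set(gg_w["variant"]) if has_g else set()
        eg_rows = eq_w.loc[eq_w["variant"].isin(sig_vars)]
        has_eg = len(eg_rows) > 0
        ce_w = ce_by_w.get(w_i)
        has_c = ce_w is not None
        c_genes = set(ce_w["gene"].astype(str)) if has_c else set()
        has_ec = has_e and len(set(eq_w["gene"].astype(str)) & c_genes) > 0
        has_egc = False
        if has_eg and has_c:
            gsign = {int(v): np.sign(r) for v, r in zip(gg_w["variant"], gg_w["r"])}
            csign = {str(gn): np.sign(r) for gn, r in zip(ce_w["gene"], ce_w["r"])}
            for row in eg_rows.itertuples():
                gn = str(row.gene)
                if gn in csign:
                    if np.sign(row.beta) * gsign[int(row.variant)] == csign[gn]:
                        has_egc = True
                        break
        rows.append((w_i, has_e, has_g, has_eg, has_c, has_ec, has_egc))
    return pd.DataFrame(rows, columns=["window", "E", "G", "EG", "C", "EC", "EGC"])


def counts_from_flags(flags: pd.DataFrame, window_set: list[int], label: str) -> EnrichmentCounts:
    """Sum precomputed interval flags over a window set."""
    sub = flags.loc[flags["window"].isin(set(window_set))]
    return EnrichmentCounts(
        label,
        len(window_set),
        int(sub["E"].sum()),
        int(sub["G"].sum()),
        int(sub["EG"].sum()),
        int(sub["C"].sum()),
        int(sub["EC"].sum()),
        int(sub["EGC"].sum()),
    )


def enrichment_counts(
    window_set: list[int],
    lg: LocalGebvSet,
    e: ExpressionSet,
    eqtl_stats: pd.DataFrame,
    geno_gebv: pd.DataFrame,
    gebv_expr: pd.DataFrame,
    p_e: float = 1e-5,
    p_g: float = 1e-5,
    p_c: float = 1e-3,
    radius: int = CIS_RADIUS,
    label: str = "top300",
) -> EnrichmentCounts:
    """Count intervals passing each predicate of the filter chain.

    See :func:`interval_flags` for the predicate definitions.
    """
    flags = interval_flags(
        window_set, lg, e, eqtl_stats, geno_gebv, gebv_expr, p_e, p_g, p_c, radius
    )
    return counts_from_flags(flags, window_set, label)


def fdr(n_sign: int, t: float, n_tests: int) -> float:
    """Expected false positives over observed positives: (t x nTests) / nSign.

    Returns NaN when no test passed the threshold (undefined rate).
    """
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1)")
    if not 0 <= n_sign <= n_tests:
        raise ValueError("need 0 <= n_sign <= n_tests")
    if n_sign == 0:
        return float("nan")
    return (t * n_tests) / n_sign
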