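"""Bayes R: four-class normal-mixture Bayesian regression by Gibbs sampling.

Variant effects get a mixture prior with variances (0, 1e-4, 1e-3, 1e-2)
times the genetic variance; mixture proportions get a flat Dirichlet(1,1,1,1)
prior.  Each Gibbs sweep samples the fixed effects (intercept + breed), every
variant's mixture class and effect from their full conditionals, the mixture
proportions from Dirichlet(1 + class counts), and the residual variance from
a scaled inverse chi-squared; the genetic variance is re-estimated each sweep
as the variance across individuals of the current genetic values (which,
unlike the linkage-equilibrium formula sum(2 p q a^2), accounts for LD
between variants).  Posterior means over retained samples are returned.

The inner sweep is JIT-compiled; chains are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .synthdata import GenotypeSet

__all__ = ["SamplerConfig", "EffectEstimates", "bayes_r_fit", "gebv_predict"]


@dataclass
class SamplerConfig:
    """Gibbs sampler settings; gammas are class-variance multipliers of sigma2_g."""

    gamma: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    iterations: int = 10_000
    burn_in: int = 2_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in or self.burn_in < 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.gamma[0] != 0.0 or any(np.diff(self.gamma) <= 0):
            raise ValueError("gamma must be ascending with gamma[0] = 0")


@dataclass
class EffectEstimates:
    """Posterior summaries of the mixture regression."""

    chrom: np.ndarray
    pos: np.ndarray
    effects: np.ndarray            # (m,) posterior-mean additive effect
    class_probs: np.ndarray        # (m, 4) posterior class membership
    pi: np.ndarray                 # (4,) posterior-mean mixture proportions
    sigma2_e: float
    sigma2_g: float

    def __post_init__(self) -> None:
        if not np.allclose(self.class_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("class probabilities must sum to 1 per variant")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("non-finite posterior-mean effect")


@njit(cache=False)
def _gibbs(xm, xtx, y, w, wtw_inv_chol, gamma, n_iter, burn, thin, seed):
    np.random.seed(seed)
    m, n = xm.shape
    p_fix = w.shape[1]
    beta = np.zeros(m)
    b = np.zeros(p_fix)
    cls = np.zeros(m, dtype=np.int64)
    pi = np.full(4, 0.25)
    var_y = np.var(y)
    sigma_e = var_y * 0.5
    sigma_g = var_y * 0.5
    # weak scaled-inverse-chi-squared prior on the mixture scale variance,
    # centred at half the phenotypic variance
    nu_g = 4.0
    s0_g = var_y * 0.25
    r = y.copy()

    eff_sum = np.zeros(m)
    cls_sum = np.zeros((m, 4))
    pi_sum = np.zeros(4)
    se_sum = 0.0
    sg_sum = 0.0
    kept = 0

    logpi = np.log(pi)
    probs = np.empty(4)
    for it in range(n_iter):
        # fixed effects: b | rest ~ N((W'W)^-1 W'(r + Wb), sigma_e (W'W)^-1)
        r_plus = r + w @ b
        mean_b = (wtw_inv_chol @ wtw_inv_chol.T) @ (w.T @ r_plus)
        b = mean_b + np.sqrt(sigma_e) * (wtw_inv_chol @ np.random.standard_normal(p_fix))
        wb = w @ b
        r = r_plus - wb

        counts = np.zeros(4)
        for j in range(m):
            xj = xm[j]
            rhs = np.dot(xj, r) + xtx[j] * beta[j]
            maxlog = logpi[0]
            probs[0] = logpi[0]
            for k in range(1, 4):
                vk = gamma[k] * sigma_g
                c = xtx[j] + sigma_e / vk
                probs[k] = (
                    logpi[k]
                    - 0.5 * np.log(vk * xtx[j] / sigma_e + 1.0)
                    + 0.5 * rhs * rhs / (sigma_e * c)
                )
                if probs[k] > maxlog:
                    maxlog = probs[k]
            tot = 0.0
            for k in range(4):
                probs[k] = np.exp(probs[k] - maxlog)
                tot += probs[k]
            u = np.random.random() * tot
            acc = 0.0
            k_new = 3
            for k in range(4):
                acc += probs[k]
                if u <= acc:
                    k_new = k
                    break
            old = beta[j]
            if k_new == 0:
                new = 0.0
            else:
                c = xtx[j] + sigma_e / (gamma[k_new] * sigma_g)
                new = rhs / c + np.random.standard_normal() * np.sqrt(sigma_e / c)
            if new != old:
                for i in range(n):
                    r[i] += xj[i] * (old - new)
            beta[j] = new
            cls[j] = k_new
            counts[k_new] += 1.0

        # mixture proportions ~ Dirichlet(1 + counts) via gamma draws
        tot = 0.0
        for k in range(4):
            pi[k] = np.random.gamma(1.0 + counts[k], 1.0)
            tot += pi[k]
        for k in range(4):
            pi[k] /= tot
            logpi[k] = np.log(pi[k])

        # residual variance ~ scaled inverse chi-squared (flat prior)
        rss = np.dot(r, r)
        chi = 2.0 * np.random.gamma(0.5 * (n - 2), 1.0)
        sigma_e = rss / chi

        # mixture scale variance: conjugate scaled-inverse-chi-squared update
        # from the nonzero effects (beta_j ~ N(0, gamma_k sigma_g))
        nz = 0
        ssq = 0.0
        for j in range(m):
            if cls[j] > 0:
                nz += 1
                ssq += beta[j] * beta[j] / gamma[cls[j]]
        chi = 2.0 * np.random.gamma(0.5 * (nz + nu_g), 1.0)
        sigma_g = (ssq + nu_g * s0_g) / chi

        if it >= burn and (it - burn) % thin == 0:
            kept += 1
            for j in range(m):
                eff_sum[j] += beta[j]
                cls_sum[j, cls[j]] += 1.0
            for k in range(4):
                pi_sum[k] += pi[k]
            se_sum += sigma_e
            # report the genomic variance of the current configuration
            # (variance over individuals of Xb = y - Wb - r)
            gvec = y - wb - r
            sg_sum += np.var(gvec) * n / (n - 1)

    return eff_sum / kept, cls_sum / kept, pi_sum / kept, se_sum / kept, sg_sum / kept


def bayes_r_fit(
    g: GenotypeSet, y: np.ndarray, cfg: SamplerConfig | None = None
) -> EffectEstimates:
    """Fit the mixture regression to a phenotype vector.

    Fixed effects (intercept + breed indicators) are sampled by GLS each
    sweep; variant dosages are used as stored (no centering is needed since
    the intercept is in the model, but columns are centered for numerical
    conditioning of the residual updates).
    """
    cfg = cfg or SamplerConfig()
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_individuals:
        raise ValueError("phenotype length does not match individuals")
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")
    n_kept = (cfg.iterations - cfg.burn_in + cfg.thinning - 1) // cfg.thinning
    if n_kept < 100:
        raise ValueError("need >= 100 post-burn-in retained samples")

    from .assoc import breed_design

    w = breed_design(g)
    xm = np.ascontiguousarray((g.dosages - g.dosages.mean(axis=0)).T)
    xtx = np.einsum("ij,ij->i", xm, xm)
    xtx = np.maximum(xtx, 1e-12)
    wtw_inv = np.linalg.inv(w.T @ w)
    wtw_inv_chol = np.linalg.cholesky(wtw_inv)

    eff, cls_probs, pi, se, sg = _gibbs(
        xm,
        xtx,
        y - y.mean(),
        w,
        wtw_inv_chol,
        np.asarray(cfg.gamma, dtype=float),
        cfg.iterations,
        cfg.burn_in,
        cfg.thinning,
        cfg.seed % (2**31),
    )
    return EffectEstimates(g.chrom.copy(), g.pos.copy(), eff, cls_probs, pi, float(se), float(sg))


def gebv_predict(g_new: GenotypeSet, eff: EffectEstimates) -> np.ndarray:
    """Genome-wide GEBV: sum over variants of dosage times posterior-mean effect.

    Variant sets must align by (chromosome, position).
    """
    if g_new.m_variants != len(eff.effects) or not (
        np.array_equal(g_new.chrom, eff.chrom) and np.array_equal(g_new.pos, eff.pos)
    ):
        raise ValueError("variant sets do not align by (chromosome, position)")
    return g_new.dosages @ eff.effects
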