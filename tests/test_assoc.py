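"""Filtering, GRM, REML, EMMAX scan, meta-analysis and QTL selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtloverlap import assoc
from qtloverlap.synthdata import GenotypeSet

from conftest import make_genotypes, random_genotypes


def brute_force_prune(dosages, chrom, r2_cap):
    """Independent greedy sweep: keep a variant unless r2 with any kept
    earlier variant on the same chromosome exceeds the cap."""
    n, m = dosages.shape
    kept = []
    for j in range(m):
        drop = False
        for i in kept:
            if chrom[i] != chrom[j]:
                continue
            xi, xj = dosages[:, i], dosages[:, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if r * r > r2_cap:
                drop = True
                break
        if not drop:
            kept.append(j)
    return kept


class TestFilterVariants:
    def test_duplicate_column_pruned(self, rng):
        d = rng.binomial(2, 0.4, size=(40, 3)).astype(float)
        d[:, 1] = d[:, 0]  # exact copy, r2 = 1
        g = make_genotypes(d)
        out = assoc.filter_variants(g, maf_floor=0.0, r2_cap=0.9)
        assert list(out.pos) == [10_000, 30_000]

    def test_maf_floor_boundary(self):
        # MAF 0.001 falls below a 0.002 floor and is removed
        n = 1000
        d = np.zeros((n, 2))
        d[0, 0] = 2.0  # freq 0.001
        d[: n // 2, 1] = 1.0  # freq 0.25
        g = make_genotypes(d)
        out = assoc.filter_variants(g, maf_floor=0.002, r2_cap=1.0)
        assert list(out.pos) == [20_000]

    def test_matches_brute_force_greedy(self, rng):
        for trial in range(10):
            d = rng.binomial(2, rng.uniform(0.2, 0.8, 6), size=(30, 6)).astype(float)
            d[:, 3] = d[:, 2]  # force an LD pair
            g = make_genotypes(d, chrom=np.array([1, 1, 1, 1, 2, 2]))
            out = assoc.filter_variants(g, maf_floor=0.0, r2_cap=0.8)
            expect = brute_force_prune(d, g.chrom, 0.8)
            assert [int(p) for p in out.pos] == [int(g.pos[j]) for j in expect]

    def test_bad_parameters(self, demo_genotypes):
        with pytest.raises(ValueError):
            assoc.filter_variants(demo_genotypes, maf_floor=0.6)
        with pytest.raises(ValueError):
            assoc.filter_variants(demo_genotypes, r2_cap=0.0)


class TestGrm:
    def test_clone_individuals(self, rng):
        d = rng.binomial(2, 0.5, size=(5, 30)).astype(float)
        d[1] = d[0]
        g = make_genotypes(d)
        grm = assoc.compute_grm(g, ridge=0.0)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[1, 1])

    def test_hand_computed_toy(self):
        d = np.array(
            [[0.0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0]]
        )
        g = make_genotypes(d)
        p = d.mean(axis=0) / 2
        z = d - 2 * p
        expect = z @ z.T / (2 * np.sum(p * (1 - p)))
        grm = assoc.compute_grm(g, ridge=0.0)
        assert np.allclose(grm.matrix, expect, atol=1e-12)

    def test_centered_columns_sum_to_zero(self, rng):
        d = rng.binomial(2, 0.3, size=(8, 20)).astype(float)
        p = d.mean(axis=0) / 2
        assert np.allclose((d - 2 * p).sum(axis=0), 0.0, atol=1e-10)

    def test_monomorphic_input_rejected(self):
        g = make_genotypes(np.ones((4, 3)))
        with pytest.raises(ValueError):
            assoc.compute_grm(g)

    def test_symmetric_psd(self, demo_genotypes):
        grm = assoc.compute_grm(demo_genotypes)
        assert np.allclose(grm.matrix, grm.matrix.T)
        assert grm.eigvals.min() >= -1e-8
        assert 0.8 < np.diag(grm.matrix).mean() < 1.2


class TestNullVariance:
    def _identity_grm(self, n):
        return assoc.Grm(np.eye(n), np.arange(n), np.ones(n), np.eye(n))

    def test_pure_noise_h2_near_zero(self):
        # needs a GRM with eigenvalue spread: with an exact identity the
        # variance split is unidentifiable (V is a multiple of I for any h2)
        r = np.random.default_rng(0)
        g = random_genotypes(r, 1000, 400)
        grm = assoc.compute_grm(g)
        vc = assoc.fit_null_variance(r.normal(size=1000), np.ones((1000, 1)), grm)
        assert vc.h2 < 0.1

    def test_recovers_h2(self):
        g = random_genotypes(np.random.default_rng(3), 1000, 400)
        grm = assoc.compute_grm(g)
        rng2 = np.random.default_rng(4)
        u = grm.eigvecs
        gv = u @ (rng2.normal(size=1000) * np.sqrt(grm.eigvals * 0.5))
        y = gv + rng2.normal(size=1000) * np.sqrt(0.5)
        vc = assoc.fit_null_variance(y, np.ones((1000, 1)), grm)
        assert 0.35 < vc.h2 < 0.65

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            assoc.fit_null_variance(np.ones(50), np.ones((50, 1)), self._identity_grm(50))

    def test_singular_design_rejected(self, rng):
        n = 50
        x = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError):
            assoc.fit_null_variance(rng.normal(size=n), x, self._identity_grm(n))


class TestGwasScan:
    def test_identity_grm_matches_ols(self, rng):
        import statsmodels.api as sm

        n, m = 150, 40
        g = random_genotypes(rng, n, m)
        y = rng.normal(size=n) + 0.3 * g.dosages[:, 0]
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        grm = assoc.Grm(np.eye(n), g.ids, np.ones(n), np.eye(n))
        vc = assoc.VarianceComponents(0.3, 0.7, 0.0)
        out = assoc.gwas_scan(g, y, x, grm, vc)
        for j in [0, 5, 17]:
            ols = sm.OLS(y, np.column_stack([x, g.dosages[:, j]])).fit()
            assert out["beta"].iloc[j] == pytest.approx(ols.params[-1], abs=1e-8)
            assert out["p"].iloc[j] == pytest.approx(ols.pvalues[-1], abs=1e-8)

    def test_power_on_planted_qtl(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = random_genotypes(r, 1000, 100)
            j_causal = 50
            x = g.dosages[:, j_causal]
            beta = np.sqrt(0.05 / x.var())
            y = beta * x + r.normal(size=1000) * np.sqrt(0.95)
            grm = assoc.Grm(np.eye(1000), g.ids, np.ones(1000), np.eye(1000))
            vc = assoc.VarianceComponents(0.05, 0.95, 0.0)
            out = assoc.gwas_scan(g, y, np.ones((1000, 1)), grm, vc)
            if out["p"].iloc[j_causal] < 1e-6:
                hits += 1
        assert hits >= 9

    def test_null_calibration_on_permuted_phenotype(self, rng):
        g = random_genotypes(rng, 400, 500)
        y = rng.permutation(rng.normal(size=400))
        grm = assoc.Grm(np.eye(400), g.ids, np.ones(400), np.eye(400))
        vc = assoc.VarianceComponents(0.1, 0.9, 0.0)
        out = assoc.gwas_scan(g, y, np.ones((400, 1)), grm, vc)
        frac = np.mean(out["p"] < 0.01)
        assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / 500)

    def test_monomorphic_flagged_not_raised(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        d[:, 1] = 2.0
        g = make_genotypes(d)
        grm = assoc.Grm(np.eye(50), g.ids, np.ones(50), np.eye(50))
        vc = assoc.VarianceComponents(0.5, 0.5, 0.0)
        out = assoc.gwas_scan(g, rng.normal(size=50), np.ones((50, 1)), grm, vc)
        assert np.isnan(out["p"].iloc[1])
        assert np.isfinite(out["p"].iloc[0])


def _frame(z, n, p=None):
    z = np.asarray(z, dtype=float)
    p = 2 * stats.norm.sf(np.abs(z)) if p is None else p
    return assoc.assoc_frame(
        np.ones(len(z), dtype=int),
        np.arange(1, len(z) + 1) * 1000,
        z,
        np.ones(len(z)),
        p,
        np.full(len(z), n),
        "gwas",
    )


class TestMeta:
    def test_single_stratum_identity(self):
        s = _frame([1.5, -2.0, 0.3], 100)
        out = assoc.meta_weighted_z([s])
        assert np.allclose(out["z"], s["z"], atol=1e-10)

    def test_equal_strata_scale_sqrt2(self):
        s = _frame([1.5, -2.0, 0.3], 100)
        out = assoc.meta_weighted_z([s, s.copy()])
        assert np.allclose(out["z"], np.sqrt(2) * s["z"], atol=1e-12)

    def test_opposite_z_cancel(self):
        a = _frame([2.0], 100)
        b = _frame([-2.0], 100)
        out = assoc.meta_weighted_z([a, b])
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_meta_with_itself_preserves_p_order(self, rng):
        z = rng.normal(size=50)
        s = _frame(z, 200)
        out = assoc.meta_weighted_z([s, s.copy()])
        assert list(np.argsort(out["p"].to_numpy())) == list(np.argsort(s["p"].to_numpy()))

    def test_missing_stratum_dropped_per_variant(self):
        a = _frame([2.0, 1.0], 100)
        b = _frame([2.0, 1.0], 100)
        b.loc[1, "p"] = np.nan
        out = assoc.meta_weighted_z([a, b])
        assert out["z"].iloc[0] == pytest.approx(np.sqrt(2) * 2.0, abs=1e-9)
        assert out["z"].iloc[1] == pytest.approx(1.0, abs=1e-9)


class TestSelectQtl:
    def test_empty_when_nothing_significant(self):
        s = _frame([1.0, 2.0], 100)
        assert assoc.select_qtl(s, 1e-6) == []

    def test_greedy_hand_walk(self):
        s = pd.DataFrame(
            {
                "variant": [0, 1, 2],
                "chrom": [1, 1, 1],
                "pos": [1_000_000, 1_500_000, 2_600_000],
                "p": [1e-9, 1e-8, 1e-7],
            }
        )
        calls = assoc.select_qtl(s, 1e-6, 1_000_000)
        assert [c.pos for c in calls] == [1_000_000, 2_600_000]

    def test_exact_spacing_both_kept(self):
        s = pd.DataFrame(
            {
                "variant": [0, 1],
                "chrom": [1, 1],
                "pos": [1_000_000, 2_000_000],
                "p": [1e-9, 1e-8],
            }
        )
        calls = assoc.select_qtl(s, 1e-6, 1_000_000)
        assert len(calls) == 2

    def test_input_order_invariance(self, rng):
        pos = rng.choice(np.arange(1, 30) * 400_000, size=15, replace=False)
        s = pd.DataFrame(
            {
                "variant": np.arange(15),
                "chrom": np.ones(15, dtype=int),
                "pos": pos,
                "p": 10.0 ** rng.uniform(-12, -5, 15),
            }
        )
        a = assoc.select_qtl(s, 1e-6)
        shuffled = s.sample(frac=1.0, random_state=1)
        b = assoc.select_qtl(shuffled, 1e-6)
        assert [(c.chrom, c.pos) for c in a] == [(c.chrom, c.pos) for c in b]
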