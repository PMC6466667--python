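"""Correlation records, permutation comparison, enrichment chain and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtloverlap import overlap, windows as win
from qtloverlap.windows import Window, LocalGebvSet

from test_eqtl import make_expression
from test_windows import make_effects
from conftest import random_genotypes


class TestPearson:
    def test_identity_gives_r_one_p_zero(self, rng):
        x = rng.normal(size=20)
        r, p = overlap.pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_closed_form_t(self):
        # r = 0.5, n = 30: t = 0.5*sqrt(28)/sqrt(0.75) = 3.0551, p ~ 4.9e-3
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r, p = overlap.pearson_with_p(x, y)
            t = r * np.sqrt(28) / np.sqrt(1 - r**2)
            assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-12)
        t_ref = 0.5 * np.sqrt(28) / np.sqrt(0.75)
        assert t_ref == pytest.approx(3.0550, abs=1e-4)
        assert 2 * stats.t.sf(t_ref, 28) == pytest.approx(4.9e-3, abs=2e-4)

    def test_constant_vector_flagged(self):
        r, p = overlap.pearson_with_p(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            overlap.pearson_with_p(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCorrelateGebvExpression:
    def _lg(self, gebv, starts, chrom=1):
        ws = [Window(chrom, s, s + 250_000, (0,)) for s in starts]
        return LocalGebvSet(ws, np.asarray(gebv, dtype=float), np.var(gebv, axis=1, ddof=1))

    def test_planted_identity_r_one(self, rng):
        gebv = rng.normal(size=(2, 30))
        lg = self._lg(gebv, [1, 500_001])
        e = make_expression(np.ones((1, 30), dtype=int), gene_start=np.array([100_000]), gene_end=np.array([110_000]))
        out = overlap.correlate_gebv_expression(lg, e, gebv[[0]], radius=1_000_000)
        r0 = out.loc[out["window"] == 0, "r"].iloc[0]
        assert r0 == pytest.approx(1.0)

    def test_gene_beyond_radius_excluded(self, rng):
        gebv = rng.normal(size=(1, 30))
        lg = self._lg(gebv, [1])
        e = make_expression(
            np.ones((1, 30), dtype=int),
            gene_start=np.array([2_000_000]),
            gene_end=np.array([2_100_000]),
        )
        # window [1, 250001): gene must start < 250001 + 1 Mb = 1,250,001
        out = overlap.correlate_gebv_expression(lg, e, rng.normal(size=(1, 30)), radius=700_000)
        assert len(out) == 0

    def test_matches_exhaustive_double_loop(self, rng):
        gebv = rng.normal(size=(4, 25))
        lg = self._lg(gebv, [1, 200_001, 400_001, 600_001])
        gene_start = np.array([100_000, 900_000])
        e = make_expression(
            rng.integers(1, 50, size=(2, 25)), gene_start=gene_start, gene_end=gene_start + 10_000
        )
        expr = rng.normal(size=(2, 25))
        out = overlap.correlate_gebv_expression(lg, e, expr, radius=1_000_000)
        for row in out.itertuples():
            k = list(e.gene_ids).index(row.gene)
            r_ref, p_ref = overlap.pearson_with_p(lg.gebv[row.window], expr[k])
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.p == pytest.approx(p_ref, abs=1e-12)


class TestCorrelateGenotypeGebv:
    def test_single_variant_window_perfect_r(self, rng):
        g = random_genotypes(rng, 30, 1)
        lg = LocalGebvSet(
            [Window(1, 1, 250_001, (0,))],
            (g.dosages[:, 0] * 0.7)[None, :],
            np.array([np.var(g.dosages[:, 0] * 0.7, ddof=1)]),
        )
        out = overlap.correlate_genotype_gebv(g, lg)
        assert abs(out["r"].iloc[0]) == pytest.approx(1.0)

    def test_hand_computed_five_cows(self):
        from conftest import make_genotypes

        d = np.array([[0.0, 1], [1, 0], [2, 2], [0, 1], [1, 2]])
        g = make_genotypes(d, pos=np.array([100, 200]))
        gebv = d @ np.array([0.5, -0.2])
        lg = LocalGebvSet([Window(1, 1, 250_001, (0, 1))], gebv[None, :], np.array([np.var(gebv, ddof=1)]))
        out = overlap.correlate_genotype_gebv(g, lg)
        for row in out.itertuples():
            r_ref, p_ref = overlap.pearson_with_p(d[:, row.variant], gebv)
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.p == pytest.approx(p_ref, abs=1e-12)

    def test_monomorphic_flagged(self, rng):
        g = random_genotypes(rng, 20, 2)
        g.dosages[:, 1] = 2.0
        gebv = g.dosages[:, 0][None, :]
        lg = LocalGebvSet([Window(1, 1, 250_001, (0, 1))], gebv, np.array([np.var(gebv, ddof=1)]))
        out = overlap.correlate_genotype_gebv(g, lg)
        assert bool(out.loc[out["variant"] == 1, "monomorphic"].iloc[0])


class TestPermutationComparison:
    def test_zero_effects_give_zero_counts(self, rng):
        g = random_genotypes(rng, 30, 20)
        eff = make_effects(g.chrom, g.pos, np.zeros(20))
        ws = win.make_windows(g.chrom, g.pos, 100_000, 50_000)
        e = make_expression(
            np.ones((2, 30), dtype=int),
            gene_start=np.array([50_000, 150_000]),
            gene_end=np.array([60_000, 160_000]),
        )
        obs, counts = overlap.permutation_comparison(
            g, eff, ws, e, rng.normal(size=(2, 30)), reps=10, seed=1
        )
        assert obs == 0 and np.all(counts == 0)

    def test_deterministic_under_seed(self, rng):
        g = random_genotypes(rng, 40, 30)
        eff = make_effects(g.chrom, g.pos, rng.normal(size=30))
        ws = win.make_windows(g.chrom, g.pos, 100_000, 50_000)
        e = make_expression(
            rng.integers(1, 40, size=(3, 40)),
            gene_start=np.array([50_000, 150_000, 250_000]),
            gene_end=np.array([60_000, 160_000, 260_000]),
        )
        expr = rng.normal(size=(3, 40))
        a = overlap.permutation_comparison(g, eff, ws, e, expr, reps=15, p_select=0.05, seed=4)
        b = overlap.permutation_comparison(g, eff, ws, e, expr, reps=15, p_select=0.05, seed=4)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])


class TestTopAndRandomK:
    def _ranking(self, rng, n_windows=10):
        ws = [Window(1, s * 300_000 + 1, s * 300_000 + 250_001, (0,)) for s in range(n_windows)]
        var = rng.uniform(0.5, 5.0, n_windows)
        lg = LocalGebvSet(ws, np.zeros((n_windows, 2)), var)
        return win.rank_nonoverlapping(lg), lg

    def test_full_set_share_100(self, rng):
        ranking, lg = self._ranking(rng)
        sel, share = overlap.select_top_k(ranking, lg, k=ranking.u)
        assert sel == ranking.accepted
        assert share == pytest.approx(100.0)

    def test_k1_is_argmax(self, rng):
        ranking, lg = self._ranking(rng)
        sel, _ = overlap.select_top_k(ranking, lg, k=1)
        assert sel == [int(np.argmax(lg.var))]

    def test_topk_matches_sort_oracle(self, rng):
        ranking, lg = self._ranking(rng)
        sel, _ = overlap.select_top_k(ranking, lg, k=3)
        assert sel == list(np.argsort(-lg.var)[:3])

    def test_random_k_deterministic(self, rng):
        _, lg = self._ranking(rng)
        a = overlap.select_random_k(lg.windows, 4, seed=2)
        b = overlap.select_random_k(lg.windows, 4, seed=2)
        assert a == b

    def test_random_k_whole_disjoint_set(self, rng):
        _, lg = self._ranking(rng, n_windows=5)
        sel = overlap.select_random_k(lg.windows, 5, seed=3)
        assert sorted(sel) == list(range(5))

    def test_random_k_infeasible(self, rng):
        ws = [Window(1, 1, 250_001, (0,)), Window(1, 100_001, 350_001, (0,))]
        with pytest.raises(ValueError):
            overlap.select_random_k(ws, 2, seed=1)

    def test_random_k_uniform_over_disjoint_windows(self, rng):
        _, lg = self._ranking(rng, n_windows=8)
        picks = [overlap.select_random_k(lg.windows, 1, seed=s)[0] for s in range(1000)]
        freq = np.bincount(picks, minlength=8) / 1000
        se = np.sqrt((1 / 8) * (7 / 8) / 1000)
        assert np.all(np.abs(freq - 1 / 8) < 4 * se)


class TestEnrichment:
    def _fixture(self, rng):
        ws = [Window(1, 1, 250_001, (0, 1)), Window(1, 500_001, 750_001, (2, 3))]
        lg = LocalGebvSet(ws, rng.normal(size=(2, 20)), np.array([2.0, 1.0]))
        e = make_expression(
            np.ones((2, 20), dtype=int),
            gene_start=np.array([100_000, 600_000]),
            gene_end=np.array([120_000, 620_000]),
        )
        return ws, lg, e

    def test_empty_window_set(self, rng):
        ws, lg, e = self._fixture(rng)
        empty = pd.DataFrame(columns=["variant", "gene", "p", "beta"])
        gg = pd.DataFrame(columns=["window", "variant", "r", "p"])
        ce = pd.DataFrame(columns=["window", "gene", "r", "p"])
        c = overlap.enrichment_counts([], lg, e, empty, gg, ce)
        assert (c.nE, c.nG, c.nEG, c.nC, c.nEC, c.nEGC) == (0, 0, 0, 0, 0, 0)

    def test_planted_shared_causal_counts_everywhere(self, rng):
        ws, lg, e = self._fixture(rng)
        eq = pd.DataFrame(
            {"variant": [0], "gene": ["G0000"], "p": [1e-8], "beta": [1.0]}
        )
        gg = pd.DataFrame({"window": [0], "variant": [0], "r": [0.9], "p": [1e-8]})
        ce = pd.DataFrame({"window": [0], "gene": ["G0000"], "r": [0.8], "p": [1e-6]})
        c = overlap.enrichment_counts([0, 1], lg, e, eq, gg, ce)
        assert (c.nE, c.nG, c.nEG, c.nC, c.nEC, c.nEGC) == (1, 1, 1, 1, 1, 1)

    def test_eqtl_only_interval_counts_e_only(self, rng):
        ws, lg, e = self._fixture(rng)
        eq = pd.DataFrame({"variant": [2], "gene": ["G0001"], "p": [1e-8], "beta": [1.0]})
        gg = pd.DataFrame(columns=["window", "variant", "r", "p"])
        ce = pd.DataFrame(columns=["window", "gene", "r", "p"])
        c = overlap.enrichment_counts([0, 1], lg, e, eq, gg, ce)
        assert (c.nE, c.nG, c.nEG, c.nC, c.nEC, c.nEGC) == (1, 0, 0, 0, 0, 0)

    def test_inconsistent_sign_blocks_egc(self, rng):
        ws, lg, e = self._fixture(rng)
        eq = pd.DataFrame({"variant": [0], "gene": ["G0000"], "p": [1e-8], "beta": [1.0]})
        gg = pd.DataFrame({"window": [0], "variant": [0], "r": [0.9], "p": [1e-8]})
        ce = pd.DataFrame({"window": [0], "gene": ["G0000"], "r": [-0.8], "p": [1e-6]})
        c = overlap.enrichment_counts([0], lg, e, eq, gg, ce)
        assert c.nEG == 1 and c.nC == 1 and c.nEGC == 0

    def test_count_chain_invariant(self, rng):
        ws, lg, e = self._fixture(rng)
        for trial in range(20):
            eq = pd.DataFrame(
                {
                    "variant": rng.integers(0, 4, 6),
                    "gene": rng.choice(["G0000", "G0001"], 6),
                    "p": 10.0 ** rng.uniform(-9, -1, 6),
                    "beta": rng.normal(size=6),
                }
            )
            gg = pd.DataFrame(
                {
                    "window": rng.integers(0, 2, 5),
                    "variant": rng.integers(0, 4, 5),
                    "r": rng.uniform(-1, 1, 5),
                    "p": 10.0 ** rng.uniform(-9, -1, 5),
                }
            )
            ce = pd.DataFrame(
                {
                    "window": rng.integers(0, 2, 4),
                    "gene": rng.choice(["G0000", "G0001"], 4),
                    "r": rng.uniform(-1, 1, 4),
                    "p": 10.0 ** rng.uniform(-6, -1, 4),
                }
            )
            c = overlap.enrichment_counts([0, 1], lg, e, eq, gg, ce)
            assert c.nEG <= min(c.nE, c.nG)
            assert c.nEC <= min(c.nE, c.nC)
            assert c.nEGC <= min(c.nEG, c.nC)


class TestFdr:
    def test_exact_unity(self):
        assert overlap.fdr(100, 0.01, 10_000) == pytest.approx(1.0)

    def test_homogeneous(self):
        a = overlap.fdr(50, 1e-4, 100_000)
        b = overlap.fdr(100, 1e-4, 200_000)
        assert a == pytest.approx(b)

    def test_zero_significant_is_nan(self):
        assert np.isnan(overlap.fdr(0, 1e-6, 1000))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            overlap.fdr(5, 1.5, 100)
        with pytest.raises(ValueError):
            overlap.fdr(200, 0.01, 100)
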