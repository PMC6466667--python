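"""End-to-end orchestration of the QTL/eQTL overlap analysis.

``run_all`` executes: synthetic data -> variant filtering -> GRM -> sex-
stratified mixed-model GWAS + meta-analysis -> QTL leads -> Bayes R ->
local-GEBV windows and greedy ranking -> cis-eQTL scan and leads ->
GEBV-expression correlations with the within-window permutation comparison
-> top-k/random-k enrichment and FDR -> CLPP colocalisation, writing TSV/BED
outputs plus a machine-readable summary.  Every output is stamped with the
config hash and seed, and a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, bayesr, coloc, eqtl, io, overlap, synthdata, windows

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All knobs of a run; defaults give a desk-scale two-chromosome demo."""

    seed: int = 1
    out_dir: str = "run_out"
    # synthetic data
    n_per_breed: tuple[int, ...] = (1600, 400)
    m_variants: int = 5000
    chrom_lengths: tuple[int, ...] = (40_000_000, 40_000_000)
    fst: float = 0.1
    ld_block_scale: float = 100_000.0
    n_trait_qtl: int = 10
    n_eqtl: int = 30
    n_shared: int = 5
    h2: float = 0.5
    accuracy: dict = field(default_factory=lambda: {"M": 0.95, "F": 0.6})
    n_genes: int = 300
    n_cows: tuple[int, ...] = (105, 26)
    expr_effect: float = 1.0
    dispersion: float = 0.15
    cell_types: tuple[str, ...] = ("milk",)
    # filtering
    maf_floor: float = 0.002
    r2_cap: float = 0.9
    # thresholds
    p_gwas: float = 1e-6
    p_eqtl: float = 1e-5
    p_cor: float = 1e-5
    p_c: float = 1e-3
    clpp_threshold: float = 0.01
    qtl_spacing: int = 1_000_000
    cis_radius: int = 1_000_000
    # windows
    window_size: int = 250_000
    window_step: int = 50_000
    # 50 at the demo scale: the 2 x 40 Mb demo genome holds ~320 disjoint
    # windows, too few to place 300 non-overlapping random intervals; set
    # 300 for genome-scale maps
    top_k: int = 50
    random_k_reps: int = 100
    permutation_reps: int = 100
    # sampler
    bayesr_iterations: int = 4000
    bayesr_burn_in: int = 1000
    bayesr_thinning: int = 3
    min_expressed: int = 25
    residualize_expression: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self) -> str:
        return f"qtloverlap config={self.config_hash()} seed={self.seed}"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_per_breed", "chrom_lengths", "n_cows", "cell_types"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    log.info("stage %-12s %6.1f s", name, t1 - t0)
    return t1


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and write outputs under ``cfg.out_dir``.

    Returns the machine-readable summary dictionary (also written as
    ``summary.json``).  A stage failure raises with the stage name; outputs
    of completed stages remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = cfg.stamp()
    cfg.to_yaml(str(out / "config.yaml"))
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    t0 = time.time()

    try:
        # --- synthetic data -------------------------------------------------
        g = synthdata.simulate_genotypes(
            cfg.n_per_breed,
            cfg.m_variants,
            cfg.chrom_lengths,
            cfg.fst,
            cfg.ld_block_scale,
            seed=cfg.seed,
        )
        truth = synthdata.implant_truth(
            g, cfg.n_trait_qtl, cfg.n_eqtl, cfg.n_shared, expr_effect=cfg.expr_effect, seed=cfg.seed
        )
        ph = synthdata.simulate_phenotypes(g, truth, cfg.h2, cfg.accuracy, seed=cfg.seed)
        expr_sets = [
            eqtl.filter_genes(
                synthdata.simulate_expression(
                    g,
                    truth,
                    cfg.n_genes,
                    cfg.n_cows,
                    dispersion=cfg.dispersion,
                    cell_type=ct,
                    seed=cfg.seed,
                ),
                cfg.min_expressed,
            )
            for ct in cfg.cell_types
        ]
        io.write_vcf(g, str(out / "genotypes.vcf"), stamp)
        io.write_phenotypes(ph, str(out / "phenotypes.tsv"), stamp)
        for e in expr_sets:
            io.write_expression(e, str(out / f"expression_{e.cell_type}"), stamp)
        truth_df = pd.DataFrame(
            {
                "kind": ["trait"] * len(truth.trait_idx) + ["expression"] * len(truth.expr_idx),
                "variant": np.concatenate([truth.trait_idx, truth.expr_idx]),
                "effect": np.concatenate([truth.trait_effect, truth.expr_effect]),
                "gene": [""] * len(truth.trait_idx) + list(truth.expr_gene),
            }
        )
        io.write_tsv(truth_df, str(out / "ground_truth.tsv"), stamp)
        t0 = _stage("synthdata", t0)

        # --- filtering + GWAS ----------------------------------------------
        gf = assoc.filter_variants(g, cfg.maf_floor, cfg.r2_cap)
        grm = assoc.compute_grm(gf)
        x = assoc.breed_design(gf)
        strata = []
        for sex in ("M", "F"):
            idx = np.where(gf.sex == sex)[0]
            if len(idx) < x.shape[1] + 3:
                continue
            g_s = gf.take_individuals(idx)
            grm_s = assoc.compute_grm(g_s)
            x_s = assoc.breed_design(g_s)
            y_s = ph.value[idx]
            vc = assoc.fit_null_variance(y_s, x_s, grm_s)
            strata.append(assoc.gwas_scan(g_s, y_s, x_s, grm_s, vc, study=f"gwas_{sex}"))
        meta = assoc.meta_weighted_z(strata)
        qtl_calls = assoc.select_qtl(meta, cfg.p_gwas, cfg.qtl_spacing)
        io.write_tsv(meta, str(out / "gwas_meta.tsv"), stamp)
        n_sign_gwas = int((meta["p"] <= cfg.p_gwas).sum())
        summary["gwas"] = {
            "m_filtered": gf.m_variants,
            "n_significant": n_sign_gwas,
            "fdr": overlap.fdr(n_sign_gwas, cfg.p_gwas, len(meta)) if n_sign_gwas else None,
            "n_qtl": len(qtl_calls),
        }
        t0 = _stage("gwas", t0)

        # --- Bayes R + windows ----------------------------------------------
        cfg_b = bayesr.SamplerConfig(
            iterations=cfg.bayesr_iterations,
            burn_in=cfg.bayesr_burn_in,
            thinning=cfg.bayesr_thinning,
            seed=cfg.seed,
        )
        eff = bayesr.bayes_r_fit(gf, ph.value, cfg_b)
        eff_df = pd.DataFrame(
            {
                "chrom": eff.chrom,
                "pos": eff.pos,
                "effect": eff.effects,
                "p_class0": eff.class_probs[:, 0],
                "p_class1": eff.class_probs[:, 1],
                "p_class2": eff.class_probs[:, 2],
                "p_class3": eff.class_probs[:, 3],
            }
        )
        io.write_tsv(eff_df, str(out / "bayesr_effects.tsv"), stamp)

        cows = expr_sets[0].cow_index
        g_cows = gf.take_individuals(cows)
        wins = windows.make_windows(gf.chrom, gf.pos, cfg.window_size, cfg.window_step)
        lg = windows.local_gebv(g_cows, eff, wins)
        ranking = windows.rank_nonoverlapping(lg)
        win_df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in wins],
                "start": [w.start for w in wins],
                "end": [w.end for w in wins],
                "n_variants": [len(w.members) for w in wins],
                "sigma2": lg.var,
                "var_pct": 100.0 * lg.var / ranking.sigma2_sum if ranking.sigma2_sum else 0.0,
                "accepted": [i in set(ranking.accepted) for i in range(len(wins))],
            }
        )
        io.write_tsv(win_df, str(out / "windows.tsv"), stamp)
        io.write_bed(win_df.loc[win_df["accepted"]], str(out / "accepted_windows.bed"), stamp)
        summary["windows"] = {
            "n_windows": len(wins),
            "u_nonoverlapping": ranking.u,
            "sigma2_sum": ranking.sigma2_sum,
        }
        t0 = _stage("bayesr", t0)

        # --- eQTL + overlap + coloc per cell type ---------------------------
        for e in expr_sets:
            ct = e.cell_type
            g_e = gf.take_individuals(e.cow_index)
            # drop variants monomorphic in the cohort only for the eQTL scan
            grm_e = assoc.compute_grm(g_e)
            prs = eqtl.cis_pairs(g_e, e, cfg.cis_radius)
            log_e = eqtl.log_transform(e.counts)
            stats_e = eqtl.eqtl_scan(g_e, e, grm_e, prs, log_expr=log_e, study=f"eqtl_{ct}")
            eq_calls = eqtl.select_eqtl(stats_e, cfg.p_eqtl)
            io.write_tsv(stats_e, str(out / f"eqtl_{ct}.tsv"), stamp)
            n_sign_e = int((stats_e["p"] <= cfg.p_eqtl).sum())
            expr_mat = (
                overlap.residualize(log_e, eqtl.covariate_design(e))
                if cfg.residualize_expression
                else log_e
            )
            cor = overlap.correlate_gebv_expression(lg, e, expr_mat, cfg.cis_radius, cfg.p_cor)
            io.write_tsv(cor, str(out / f"correlations_{ct}.tsv"), stamp)
            gg = overlap.correlate_genotype_gebv(g_cows, lg)
            obs, perm_counts = overlap.permutation_comparison(
                g_cows,
                eff,
                wins,
                e,
                expr_mat,
                reps=cfg.permutation_reps,
                p_select=cfg.p_cor,
                radius=cfg.cis_radius,
                seed=cfg.seed,
            )
            io.write_tsv(
                pd.DataFrame({"replicate": np.arange(len(perm_counts)), "count": perm_counts}),
                str(out / f"permutation_{ct}.tsv"),
                stamp,
            )

            k = min(cfg.top_k, ranking.u)
            top_set, top_share = overlap.select_top_k(ranking, lg, k)
            flags = overlap.interval_flags(
                list(range(len(wins))), lg, e, stats_e, gg, cor,
                cfg.p_eqtl, cfg.p_cor, cfg.p_c, cfg.cis_radius,
            )
            top_counts = overlap.counts_from_flags(flags, top_set, f"top{k}")
            rand_rows = []
            rng = synthdata.stage_rng(cfg.seed, f"randomk:{ct}")
            for rep in range(cfg.random_k_reps):
                try:
                    rset = overlap.select_random_k(wins, k, seed=int(rng.integers(2**31)))
                except ValueError:
                    break
                rand_rows.append(overlap.counts_from_flags(flags, rset, f"random{k}_rep{rep}"))
            enr = pd.DataFrame([asdict(c) for c in [top_counts] + rand_rows])
            io.write_tsv(enr, str(out / f"enrichment_{ct}.tsv"), stamp)

            n_sel = int(cor["selected"].sum())
            summary[f"eqtl_{ct}"] = {
                "n_pairs": len(stats_e),
                "n_significant": n_sign_e,
                "fdr": overlap.fdr(n_sign_e, cfg.p_eqtl, len(stats_e)) if n_sign_e else None,
                "n_eqtl_genes": len(eq_calls),
            }
            summary[f"overlap_{ct}"] = {
                "n_correlation_tests": len(cor),
                "n_selected_correlations": n_sel,
                "fdr_correlations": overlap.fdr(n_sel, cfg.p_cor, len(cor)) if n_sel else None,
                "observed_count": obs,
                "permuted_mean": float(perm_counts.mean()),
                "top_k": k,
                "top_share_pct": top_share,
                "enrichment_top": asdict(top_counts),
                "enrichment_random_mean": {
                    f: float(np.mean([getattr(c, f) for c in rand_rows]))
                    for f in ("nE", "nG", "nEG", "nC", "nEC", "nEGC")
                }
                if rand_rows
                else None,
            }

            gene_map = pd.DataFrame(
                {
                    "gene": e.gene_ids,
                    "chrom": e.gene_chrom,
                    "start": e.gene_start,
                    "end": e.gene_end,
                }
            )
            loci = coloc.build_loci(
                qtl_calls, eq_calls, g_e, meta, stats_e, gene_map, cfg.cis_radius
            )
            records = coloc.score_loci(loci, threshold=cfg.clpp_threshold)
            io.write_tsv(records, str(out / f"clpp_{ct}.tsv"), stamp)
            summary[f"coloc_{ct}"] = coloc.colocalisation_summary(records, qtl_calls, eq_calls)
            t0 = _stage(f"overlap:{ct}", t0)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
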