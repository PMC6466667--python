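"""Readers and writers for the pipeline's standard formats.

Genotypes round-trip through uncompressed VCF (diploid GT records, with the
dosage mirrored in a DS FORMAT field) or a plain dosage TSV; phenotypes,
covariates, expression counts, association results and windows go to TSV;
accepted intervals export to 0-based half-open BED.  All TSV/BED files carry
a comment header stamping the config hash and seed when provided.  Internal
and TSV coordinates are 1-based; only BED is 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import ExpressionSet, GenotypeSet, PhenotypeTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_tsv",
    "write_bed",
    "write_phenotypes",
    "write_expression",
]


def _header_lines(stamp: str | None) -> list[str]:
    return [f"# {stamp}"] if stamp else []


def write_vcf(g: GenotypeSet, path: str, stamp: str | None = None) -> None:
    """Write dosages as unphased diploid GT calls (0/0, 0/1, 1/1) plus DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if stamp:
            fh.write(f"##source={stamp}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        for c in np.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(g.m_variants):
            fields = [
                str(g.chrom[j]),
                str(g.pos[j]),
                f"var{j}",
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            col = g.dosages[:, j]
            fields += [f"{gt_map[int(round(d))]}:{d:g}" for d in col]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str) -> GenotypeSet:
    """Read a VCF into a GenotypeSet (dosage = alt-allele count from GT).

    Missing genotypes are mean-imputed; unsorted positions within a
    chromosome raise with the offending coordinate.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = np.array(vcf.samples)
    chrom_l, pos_l, dos_l = [], [], []
    n_imputed = 0
    last: dict[str, int] = {}
    for rec in vcf:
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise ValueError(
                f"unsorted VCF: {rec.CHROM}:{rec.POS} after {rec.CHROM}:{last[rec.CHROM]}"
            )
        last[rec.CHROM] = rec.POS
        gts = rec.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        d = gts.sum(axis=1)
        if np.isnan(d).any():
            n_imputed += int(np.isnan(d).sum())
            d = np.where(np.isnan(d), np.nanmean(d), d)
        chrom_l.append(int(rec.CHROM))
        pos_l.append(rec.POS)
        dos_l.append(d)
    dosages = np.column_stack(dos_l) if dos_l else np.zeros((len(ids), 0))
    chrom = np.array(chrom_l, dtype=np.int64)
    pos = np.array(pos_l, dtype=np.int64)
    af = dosages.mean(axis=0) / 2.0 if len(pos) else np.zeros(0)
    g = GenotypeSet(
        dosages,
        chrom,
        pos,
        af,
        ids,
        np.full(len(ids), "A"),
        np.full(len(ids), "F"),
    )
    if n_imputed:
        import logging

        logging.getLogger(__name__).info("mean-imputed %d missing genotypes", n_imputed)
    return g


def write_dosage_tsv(g: GenotypeSet, path: str, stamp: str | None = None) -> None:
    df = pd.DataFrame(g.dosages.T, columns=g.ids)
    df.insert(0, "chrom", g.chrom)
    df.insert(1, "pos", g.pos)
    df.insert(2, "af", g.af)
    write_tsv(df, path, stamp)


def read_dosage_tsv(path: str) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta = df[["chrom", "pos", "af"]]
    samples = [c for c in df.columns if c not in ("chrom", "pos", "af")]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeSet(
        dosages,
        meta["chrom"].to_numpy(np.int64),
        meta["pos"].to_numpy(np.int64),
        meta["af"].to_numpy(float),
        np.array(samples),
        np.full(len(samples), "A"),
        np.full(len(samples), "F"),
    )


def write_tsv(df: pd.DataFrame, path: str, stamp: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(stamp):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str, stamp: str | None = None) -> None:
    """BED export: 0-based half-open; expects 1-based chrom/start/end columns."""
    with open(path, "w") as fh:
        for line in _header_lines(stamp):
            fh.write(line + "\n")
        for row in intervals.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end - 1}\n")


def write_phenotypes(ph: PhenotypeTable, path: str, stamp: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "id": ph.ids,
            "trait": ph.trait,
            "deviation": ph.value,
            "accuracy": ph.accuracy,
            "n_records": ph.n_records,
        }
    )
    write_tsv(df, path, stamp)


def write_expression(e: ExpressionSet, prefix: str, stamp: str | None = None) -> None:
    counts = pd.DataFrame(e.counts, index=e.gene_ids, columns=e.cow_ids)
    counts.index.name = "gene"
    write_tsv(counts.reset_index(), f"{prefix}_counts.tsv", stamp)
    genes = pd.DataFrame(
        {
            "gene": e.gene_ids,
            "chrom": e.gene_chrom,
            "start": e.gene_start,
            "end": e.gene_end,
        }
    )
    write_tsv(genes, f"{prefix}_genes.tsv", stamp)
    cov = e.covariates.copy()
    cov.insert(0, "id", e.cow_ids)
    write_tsv(cov, f"{prefix}_covariates.tsv", stamp)
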