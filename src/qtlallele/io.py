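"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (GT field, 1-based CHROM/POS) or as a coded
TSV; phenotypes, maturity-group labels, the genetic map and the simulation
truth table are plain TSV; gene models are GFF3.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .datatypes import MISSING, GenotypeMatrix, SnpldbSet

_GT_CODE = {(0, 0): 0, (1, 1): 2, (0, 1): 1, (1, 0): 1}


def read_vcf(path: str, genetic_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load a biallelic VCF into a :class:`GenotypeMatrix`.

    Heterozygous calls become code 1, missing genotypes -1.  If a genetic
    map (columns ``chrom, pos, cM``) is given, per-SNP cM positions are
    joined on (chrom, pos); otherwise cM is filled with NaN.
    """
    records = []
    calls = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        accessions = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            row = np.full(len(accessions), MISSING, dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                row[i] = _GT_CODE.get(tuple(gt), MISSING)
            records.append(
                (rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom, rec.pos,
                 np.nan, rec.ref, rec.alts[0])
            )
            calls.append(row)
    snps = pd.DataFrame(records, columns=["id", "chrom", "pos", "cM", "ref", "alt"])
    if genetic_map is not None:
        key = genetic_map.set_index(["chrom", "pos"])["cM"]
        snps["cM"] = [
            key.get((c, p), np.nan) for c, p in zip(snps["chrom"], snps["pos"])
        ]
    return GenotypeMatrix(accessions, snps, np.asarray(calls, dtype=np.int8))


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write homozygous-coded genotypes as uncompressed VCF v4.2."""
    gt_str = {0: "0/0", 2: "1/1", 1: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in gm.snps.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions) + "\n"
        )
        for i, snp in gm.snps.iterrows():
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[i])
            fh.write(
                f"{snp.chrom}\t{int(snp.pos)}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    """Coded TSV: columns id, chrom, pos, cM, ref, alt then one per accession."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "cM", "ref", "alt"]
    acc = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(acc, df[meta_cols], df[acc].to_numpy(dtype=np.int8))


def write_genotype_tsv(gm: GenotypeMatrix, path: str) -> None:
    out = gm.snps.copy()
    for j, a in enumerate(gm.accessions):
        out[a] = gm.calls[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Plot-level phenotype TSV: accession, environment, replication, value."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "environment": str})
    expected = {"accession", "environment", "replication", "value"}
    if not expected <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(expected)}")
    if not np.isfinite(df["value"]).all():
        raise ValueError("non-finite phenotype values")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mg_labels(path: str) -> pd.Series:
    """Maturity-group TSV (accession, mg) as a Series indexed by accession."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("accession")["mg"]


def write_mg_labels(labels: pd.Series, path: str) -> None:
    labels.rename("mg").rename_axis("accession").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path: str) -> pd.DataFrame:
    """Map TSV with columns chrom, pos, cM (per-SNP genetic positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "cM"} <= set(df.columns):
        raise ValueError("map table needs columns chrom, pos, cM")
    return df


def write_genetic_map(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gff3(genes: pd.DataFrame, path: str) -> None:
    """Write gene models (gene_id, chrom, start, end, strand, category) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id}"
            if "category" in genes.columns and pd.notna(g.get("category")):
                attrs += f";Note={g.category}"
            fh.write(
                f"{g.chrom}\tqtlallele\tgene\t{int(g.start)}\t{int(g.end)}\t.\t"
                f"{g.get('strand', '+')}\t.\t{attrs}\n"
            )


def write_snpldb_definitions(snpldbs: SnpldbSet, path: str) -> None:
    """Marker definition TSV: id, chrom, start, end, member SNPs, alleles."""
    rows = []
    for m in snpldbs.markers:
        rows.append(
            {
                "marker": m.id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "n_snps": len(m.snp_ids),
                "snp_ids": ",".join(m.snp_ids),
                "alleles": ",".join(m.haplotypes),
                "frequencies": ",".join(f"{f:.6g}" for f in m.frequencies),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_allele_codes(snpldbs: SnpldbSet, path: str) -> None:
    """Per-accession allele-code matrix TSV (markers x accessions)."""
    df = pd.DataFrame(
        snpldbs.code_matrix(),
        index=[m.id for m in snpldbs.markers],
        columns=snpldbs.accessions,
    )
    df.rename_axis("marker").to_csv(path, sep="\t")


def read_allele_codes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="marker")


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
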