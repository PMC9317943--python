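"""Candidate-gene prediction around detected QTL intervals.

Each QTL interval is padded (default 200 kb each side, the LD-decay
distance of cultivated soybean), genes overlapping the padded span are
collected from the GFF3 annotation, and gene-QTL association is tested by
Pearson chi-square independence between the QTL's allele classes and a
gene-local haplotype class built from SNPs inside the gene span (+/- 5 kb
flanks).  Classes with low expected counts are pooled before testing.
Candidates are then tallied into functional categories.
"""

from __future__ import annotations

import os

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix


class IndependenceTestUndefined(ValueError):
    """Fewer than two classes remain on a margin after pooling."""


def extend_interval(start: int, end: int, pad_bp: int,
                    chrom_length: int | None = None) -> tuple[int, int]:
    """Pad a 1-based inclusive span on both sides, clipping to [1, length]."""
    if pad_bp < 0:
        raise ValueError("pad must be >= 0")
    lo = max(1, start - pad_bp)
    hi = end + pad_bp
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def load_annotation(gff3_path: str) -> gffutils.FeatureDB:
    """In-memory gffutils database of a GFF3 file."""
    return gffutils.create_db(
        os.fspath(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def genes_in_interval(db: gffutils.FeatureDB, chrom: str, start: int,
                      end: int) -> pd.DataFrame:
    """Genes overlapping [start, end] by >= 1 bp (1-based inclusive).

    Raises KeyError for a chromosome absent from the annotation.
    """
    known = {r[0] for r in db.execute("SELECT DISTINCT seqid FROM features")}
    if chrom not in known:
        raise KeyError(f"chromosome {chrom!r} not in annotation")
    rows = []
    for feat in db.region(seqid=chrom, start=start, end=end,
                          featuretype="gene", completely_within=False):
        rows.append(
            {"gene_id": feat.id, "chrom": feat.seqid, "start": feat.start,
             "end": feat.end, "strand": feat.strand}
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


def gene_haplotype_classes(gm: GenotypeMatrix, chrom: str, start: int,
                           end: int, flank_bp: int = 5000,
                           rare_freq: float = 0.01) -> np.ndarray | None:
    """Per-accession haplotype class from SNPs in the gene span +/- flank.

    Rare haplotypes (< ``rare_freq``) are pooled into an 'other' class.
    Returns None when the window contains no SNP.
    """
    mask = ((gm.snps["chrom"] == chrom)
            & (gm.snps["pos"] >= start - flank_bp)
            & (gm.snps["pos"] <= end + flank_bp)).to_numpy()
    if not mask.any():
        return None
    sub = gm.calls[mask] // 2
    strings = ["".join(map(str, sub[:, a])) for a in range(sub.shape[1])]
    codes, counts = np.unique(strings, return_counts=True)
    freq = counts / len(strings)
    code_of = {}
    nxt = 0
    for h, f in zip(codes, freq):
        if f >= rare_freq:
            code_of[h] = nxt
            nxt += 1
    other = nxt
    return np.array([code_of.get(s, other) for s in strings], dtype=np.int32)


def _pool_expected(table: np.ndarray, min_expected: float
                   ) -> np.ndarray:
    """Merge the smallest margin class into its margin's smallest peer
    until every expected count reaches ``min_expected``."""
    t = table.astype(float)
    while True:
        n = t.sum()
        exp = np.outer(t.sum(1), t.sum(0)) / n
        if (exp >= min_expected).all():
            return t
        r, c = np.unravel_index(np.argmin(exp), exp.shape)
        if t.shape[0] > 2 and (t.shape[0] >= t.shape[1] or t.shape[1] <= 2):
            rows = np.argsort(t.sum(1))
            a, b = sorted(rows[:2])
            t[a] += t[b]
            t = np.delete(t, b, axis=0)
        elif t.shape[1] > 2:
            cols = np.argsort(t.sum(0))
            a, b = sorted(cols[:2])
            t[:, a] += t[:, b]
            t = np.delete(t, b, axis=1)
        else:
            return t  # 2x2: nothing left to pool


def test_independence(qtl_codes: np.ndarray, gene_codes: np.ndarray,
                      min_expected: float = 5.0) -> dict:
    """Pearson chi-square test of QTL-allele x gene-haplotype independence.

    Low-expected classes are pooled before testing; the result dict holds
    the pooled table, statistic, df and p.  Raises
    :class:`IndependenceTestUndefined` when pooling leaves fewer than two
    classes on a margin.
    """
    qtl_codes = np.asarray(qtl_codes)
    gene_codes = np.asarray(gene_codes)
    if qtl_codes.shape != gene_codes.shape:
        raise ValueError("code vectors must cover the same accessions")
    table = pd.crosstab(qtl_codes, gene_codes).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise IndependenceTestUndefined("need >= 2 classes on both margins")
    pooled = _pool_expected(table, min_expected)
    if pooled.shape[0] < 2 or pooled.shape[1] < 2:
        raise IndependenceTestUndefined("pooling left a degenerate table")
    chi2, p, df, _ = stats.chi2_contingency(pooled, correction=False)
    return {"chi2": float(chi2), "p": float(p), "df": int(df),
            "table": pooled, "n": int(pooled.sum())}


def candidate_scan(db: gffutils.FeatureDB, gm: GenotypeMatrix,
                   qtl_table: pd.DataFrame, qtl_codes: np.ndarray,
                   pad_bp: int = 200_000, alpha: float = 0.05,
                   flank_bp: int = 5000) -> pd.DataFrame:
    """Full scan: pad each QTL span, test every gene in the padded span.

    ``qtl_table`` needs columns qtl, chrom, start, end aligned with the
    rows of ``qtl_codes`` (loci x accessions allele codes).  Genes whose
    test rejects independence at ``alpha`` are flagged candidates.
    """
    rows = []
    for r, qtl in qtl_table.reset_index(drop=True).iterrows():
        lo, hi = extend_interval(int(qtl["start"]), int(qtl["end"]), pad_bp)
        genes = genes_in_interval(db, qtl["chrom"], lo, hi)
        for g in genes.itertuples(index=False):
            classes = gene_haplotype_classes(gm, g.chrom, g.start, g.end,
                                             flank_bp)
            if classes is None:
                continue
            try:
                res = test_independence(qtl_codes[r], classes)
            except IndependenceTestUndefined:
                continue
            rows.append(
                {"qtl": qtl["qtl"], "gene_id": g.gene_id, "chrom": g.chrom,
                 "start": g.start, "end": g.end, "chi2": res["chi2"],
                 "df": res["df"], "p": res["p"],
                 "candidate": res["p"] <= alpha}
            )
    return pd.DataFrame(rows, columns=["qtl", "gene_id", "chrom", "start",
                                       "end", "chi2", "df", "p", "candidate"])


def categorize_genes(candidates: pd.DataFrame | list[str],
                     go_table: pd.DataFrame) -> pd.DataFrame:
    """Tally candidate genes into functional categories.

    ``go_table`` maps gene_id to category; genes without a mapping count
    as 'unannotated'.  Duplicated candidate genes (associated with several
    QTLs) are counted once.
    """
    if isinstance(candidates, pd.DataFrame):
        ids = (candidates.loc[candidates.get("candidate", True) == True,
                              "gene_id"].unique()
               if len(candidates) else [])
    else:
        ids = pd.unique(pd.Series(candidates)) if len(candidates) else []
    mapping = go_table.set_index("gene_id")["category"]
    tallies: dict[str, int] = {}
    for gid in ids:
        cat = mapping.get(gid, "unannotated")
        if pd.isna(cat):
            cat = "unannotated"
        tallies[cat] = tallies.get(cat, 0) + 1
    return (pd.DataFrame(sorted(tallies.items()),
                         columns=["category", "n_genes"])
            if tallies else pd.DataFrame(columns=["category", "n_genes"]))
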