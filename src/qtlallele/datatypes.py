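"""Core in-memory containers shared across the pipeline.

Genotypes of inbred accessions are coded per SNP as ``0`` (homozygous
reference), ``2`` (homozygous alternate), ``1`` (heterozygous, treated as
noise in inbred material) and ``-1`` (missing).  Haplotype-block (SNPLDB)
markers carry multiple alleles per locus: each allele is the haplotype
string over the member SNPs, and every accession is assigned one allele
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ("id", "chrom", "pos", "cM", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """SNP calls for a panel of inbred accessions.

    Parameters
    ----------
    accessions
        Unique accession identifiers, one per column of ``calls``.
    snps
        One row per SNP with columns ``id, chrom, pos, cM, ref, alt``;
        ``pos`` is the 1-based physical coordinate, ``cM`` the genetic
        position.  Positions must strictly increase within a chromosome.
    calls
        ``int8`` array of shape ``(n_snps, n_accessions)`` with entries in
        ``{0, 1, 2, -1}``.
    """

    accessions: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accessions = list(self.accessions)
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("accession ids must be unique")
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing_cols:
            raise ValueError(f"snps table lacks columns: {sorted(missing_cols)}")
        if not self.snps["id"].is_unique:
            raise ValueError("SNP ids must be unique")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snps), len(self.accessions)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.accessions)} accessions"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be coded {0, 1, 2, -1}")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Sub-matrix restricted to the SNP rows in ``index`` (order kept)."""
        return GenotypeMatrix(
            self.accessions, self.snps.iloc[index], self.calls[index]
        )


@dataclass
class SnpldbMarker:
    """One SNPLDB marker: an LD block whose haplotypes are the alleles.

    ``haplotypes`` are strings over the member SNPs ('0' reference /
    '1' alternate); ``codes`` maps each accession to the index of the
    haplotype it carries (after rare-haplotype pooling).
    """

    id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    haplotypes: list[str]
    frequencies: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if len(self.snp_ids) < 1:
            raise ValueError("marker needs at least one member SNP")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("one frequency per haplotype required")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if self.codes.min() < 0 or self.codes.max() >= len(self.haplotypes):
            raise ValueError("allele code outside haplotype set")

    @property
    def n_alleles(self) -> int:
        return len(self.haplotypes)

    @property
    def is_single_snp(self) -> bool:
        return len(self.snp_ids) == 1


@dataclass
class SnpldbSet:
    """Ordered collection of SNPLDB markers partitioning the retained SNPs."""

    markers: list[SnpldbMarker]
    accessions: list[str]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_single_snp(self) -> int:
        return sum(m.is_single_snp for m in self.markers)

    @property
    def n_multi_snp(self) -> int:
        return sum(not m.is_single_snp for m in self.markers)

    @property
    def allele_counts(self) -> np.ndarray:
        return np.array([m.n_alleles for m in self.markers], dtype=int)

    def code_matrix(self) -> np.ndarray:
        """Allele codes, shape ``(n_markers, n_accessions)``."""
        return np.stack([m.codes for m in self.markers])

    def total_member_snps(self) -> int:
        return sum(len(m.snp_ids) for m in self.markers)


@dataclass
class QtlAlleleMatrix:
    """Detected loci x accessions; entries are the allele main effects.

    The companion ``codes`` matrix holds the allele index each accession
    carries; ``effects[l, a]`` is the estimated (frequency-centred) effect
    of that allele, so ``intercept + effects[:, a].sum()`` is the predicted
    genotypic value of accession ``a``.
    """

    locus_ids: list[str]
    accessions: list[str]
    effects: np.ndarray
    codes: np.ndarray
    intercept: float
    allele_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.codes = np.asarray(self.codes, dtype=np.int32)
        shape = (len(self.locus_ids), len(self.accessions))
        if self.effects.shape != shape or self.codes.shape != shape:
            raise ValueError("effects/codes must be loci x accessions")

    def predicted_values(self) -> np.ndarray:
        """Genotypic value prediction per accession."""
        return self.intercept + self.effects.sum(axis=0)

    def subset(self, accession_mask: np.ndarray) -> "QtlAlleleMatrix":
        idx = np.asarray(accession_mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return QtlAlleleMatrix(
            self.locus_ids,
            [self.accessions[i] for i in idx],
            self.effects[:, idx],
            self.codes[:, idx],
            self.intercept,
            self.allele_effects,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects, index=self.locus_ids, columns=self.accessions)
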