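"""SNP quality control and multi-allelic SNPLDB marker assembly.

An SNPLDB marker is a run of adjacent SNPs in strong linkage
disequilibrium (all pairwise |D'| above a threshold) whose haplotypes act
as the marker's alleles; SNPs left over become single-SNP markers.  In a
panel of inbred lines every homozygous call is read directly as a
haplotype, so no phasing is needed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix, SnpldbMarker, SnpldbSet


class EmptyGenotypeError(ValueError):
    """All SNPs were removed by filtering."""


class MonomorphicSnpError(ValueError):
    """D' is undefined for a monomorphic SNP."""


def allele_frequency(calls: np.ndarray) -> float:
    """Alternate-allele frequency from coded calls, ignoring missing."""
    obs = calls[calls != MISSING]
    if obs.size == 0:
        return np.nan
    return float(obs.mean() / 2.0)


def d_prime(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Normalized LD coefficient |D'| in [0, 1] between two biallelic SNPs.

    Homozygous calls are counted as haplotypes; pairs where either call is
    heterozygous or missing are excluded.  Raises
    :class:`MonomorphicSnpError` when either SNP is monomorphic among the
    retained pairs.
    """
    a = np.asarray(snp_a)
    b = np.asarray(snp_b)
    keep = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    a = a[keep] // 2
    b = b[keep] // 2
    n = a.size
    if n == 0:
        raise MonomorphicSnpError("no jointly homozygous calls")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSnpError("monomorphic SNP: D' undefined")
    p_ab = np.mean(a & b)
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max == 0:
        return 0.0
    return float(abs(d) / d_max)


class SnpFilter(BaseEstimator, TransformerMixin):
    """Remove SNPs by missing rate, heterozygosity rate and minor allele
    frequency.

    Thresholds follow the convention that a SNP is dropped when its
    missing rate or het rate *exceeds* the cap, or its MAF falls strictly
    *below* the floor (a SNP at exactly ``min_maf`` is retained).

    Attributes
    ----------
    report_ : dict
        Counts of SNPs failing each criterion (a SNP may fail several)
        and the totals before/after.
    """

    def __init__(self, max_missing: float = 0.20, max_het: float = 0.20,
                 min_maf: float = 0.01):
        self.max_missing = max_missing
        self.max_het = max_het
        self.min_maf = min_maf

    def fit(self, gm: GenotypeMatrix, y=None):
        calls = gm.calls
        n = gm.n_accessions
        miss = (calls == MISSING).sum(axis=1) / n
        obs = np.maximum((calls != MISSING).sum(axis=1), 1)
        het = (calls == 1).sum(axis=1) / obs
        with np.errstate(invalid="ignore"):
            dose = np.where(calls == MISSING, np.nan, calls.astype(float))
            p = np.nanmean(dose, axis=1) / 2.0
        p = np.nan_to_num(p, nan=0.0)
        maf = np.minimum(p, 1.0 - p)
        fail_miss = miss > self.max_missing
        fail_het = het > self.max_het
        fail_maf = maf < self.min_maf
        self.keep_mask_ = ~(fail_miss | fail_het | fail_maf)
        self.report_ = {
            "n_input": gm.n_snps,
            "fail_missing": int(fail_miss.sum()),
            "fail_het": int(fail_het.sum()),
            "fail_maf": int(fail_maf.sum()),
            "n_removed": int((~self.keep_mask_).sum()),
            "n_retained": int(self.keep_mask_.sum()),
        }
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        out = gm.take_snps(np.flatnonzero(self.keep_mask_))
        if out.n_snps == 0:
            raise EmptyGenotypeError("no SNPs survive filtering")
        return out


class HaplotypeImputer(BaseEstimator, TransformerMixin):
    """Fill missing calls by majority vote over k nearest haplotype
    neighbours in a local SNP window.

    Residual heterozygous calls in the inbred panel are set missing first
    (they are treated as genotyping noise), so imputed output is fully
    homozygous.  A stateless transformer: ``fit`` is a no-op.
    """

    def __init__(self, k: int = 5, window: int = 20, het_to_missing: bool = True):
        self.k = k
        self.window = window
        self.het_to_missing = het_to_missing

    def fit(self, gm: GenotypeMatrix, y=None):
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        calls = gm.calls.copy()
        if self.het_to_missing:
            calls[calls == 1] = MISSING
        half = max(self.window // 2, 1)
        for s in np.flatnonzero((calls == MISSING).any(axis=1)):
            row = calls[s]
            observed = row != MISSING
            if not observed.any():
                raise ValueError(f"SNP {gm.snps['id'].iat[s]}: all calls missing")
            lo, hi = max(0, s - half), min(gm.n_snps, s + half + 1)
            ctx = calls[lo:hi]
            counts0 = (row[observed] == 0).sum()
            major = 0 if counts0 >= observed.sum() - counts0 else 2
            for a in np.flatnonzero(row == MISSING):
                both = (ctx != MISSING) & (ctx[:, [a]] != MISSING)
                diff = (ctx != ctx[:, [a]]) & both
                n_cmp = both.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    dist = np.where(n_cmp > 0, diff.sum(axis=0) / np.maximum(n_cmp, 1),
                                    np.inf)
                dist[a] = np.inf
                dist[~observed] = np.inf
                order = np.argsort(dist, kind="stable")
                nbr = order[: self.k]
                nbr = nbr[np.isfinite(dist[nbr])]
                if nbr.size == 0:
                    calls[s, a] = major
                    continue
                votes = row[nbr]
                n0 = (votes == 0).sum()
                n2 = (votes == 2).sum()
                calls[s, a] = 0 if n0 > n2 else 2 if n2 > n0 else major
        return GenotypeMatrix(gm.accessions, gm.snps, calls)


def _pool_rare(haps: list[str], freq: np.ndarray, codes: np.ndarray,
               floor: float) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Merge haplotypes rarer than ``floor`` into the nearest common one."""
    common = np.flatnonzero(freq >= floor)
    if common.size == 0:
        common = np.array([int(np.argmax(freq))])
    remap = np.empty(len(haps), dtype=int)
    for i, h in enumerate(haps):
        if i in common:
            remap[i] = i
        else:
            dists = [sum(x != y for x, y in zip(h, haps[j])) for j in common]
            remap[i] = common[int(np.argmin(dists))]
    codes = remap[codes]
    # re-index kept haplotypes by descending pooled frequency
    kept = sorted(set(remap.tolist()))
    pooled = np.array([np.mean(codes == j) for j in kept])
    order = np.argsort(-pooled, kind="stable")
    final_ids = [kept[i] for i in order]
    new_index = {old: new for new, old in enumerate(final_ids)}
    return (
        [haps[i] for i in final_ids],
        pooled[order],
        np.array([new_index[c] for c in codes], dtype=np.int32),
    )


class SnpldbAssembler(BaseEstimator, TransformerMixin):
    """Greedy left-to-right LD-block partition into SNPLDB markers.

    Adjacent SNPs on a chromosome join the current block while every
    pairwise |D'| inside the candidate block exceeds ``d_threshold`` and
    the physical span stays within ``max_span_bp``.  Haplotypes rarer than
    ``rare_freq`` are pooled into the closest (minimum-Hamming) common
    haplotype, mirroring the minor-allele floor used for SNP filtering.
    """

    def __init__(self, d_threshold: float = 0.7, max_span_bp: int = 200_000,
                 rare_freq: float = 0.01):
        self.d_threshold = d_threshold
        self.max_span_bp = max_span_bp
        self.rare_freq = rare_freq

    def fit(self, gm: GenotypeMatrix, y=None):
        return self

    def transform(self, gm: GenotypeMatrix) -> SnpldbSet:
        if gm.snps["chrom"].isna().any():
            raise ValueError("all SNPs must be mapped to a chromosome")
        markers: list[SnpldbMarker] = []
        for chrom, grp in gm.snps.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            i = 0
            while i < idx.size:
                members = [i]
                j = i + 1
                while j < idx.size:
                    if pos[j] - pos[members[0]] > self.max_span_bp:
                        break
                    try:
                        ok = all(
                            d_prime(gm.calls[idx[m]], gm.calls[idx[j]])
                            > self.d_threshold
                            for m in members
                        )
                    except MonomorphicSnpError:
                        ok = False
                    if not ok:
                        break
                    members.append(j)
                    j += 1
                markers.append(self._make_marker(gm, idx[members], chrom,
                                                 len(markers) + 1))
                i = members[-1] + 1
        snpldbs = SnpldbSet(markers, gm.accessions)
        assert snpldbs.total_member_snps() == gm.n_snps
        return snpldbs

    def _make_marker(self, gm: GenotypeMatrix, rows: np.ndarray, chrom: str,
                     number: int) -> SnpldbMarker:
        sub = gm.calls[rows]
        if np.isin(sub, (1, MISSING)).any():
            raise ValueError("assembly requires imputed, homozygous calls")
        hap_per_acc = sub // 2
        strings = ["".join(map(str, hap_per_acc[:, a])) for a in range(sub.shape[1])]
        uniq = sorted(set(strings))
        code_of = {h: i for i, h in enumerate(uniq)}
        codes = np.array([code_of[s] for s in strings], dtype=np.int32)
        freq = np.array([np.mean(codes == i) for i in range(len(uniq))])
        haps, freq, codes = _pool_rare(uniq, freq, codes, self.rare_freq)
        pos = gm.snps["pos"].iloc[rows]
        return SnpldbMarker(
            id=f"LDB{number:05d}_{chrom}",
            chrom=str(chrom),
            start=int(pos.iloc[0]),
            end=int(pos.iloc[-1]),
            snp_ids=gm.snps["id"].iloc[rows].tolist(),
            haplotypes=haps,
            frequencies=freq,
            codes=codes,
        )


def filter_snps(gm: GenotypeMatrix, max_missing: float = 0.20,
                max_het: float = 0.20, min_maf: float = 0.01):
    """Functional wrapper around :class:`SnpFilter`; returns (matrix, report)."""
    f = SnpFilter(max_missing, max_het, min_maf).fit(gm)
    return f.transform(gm), f.report_


def impute_missing(gm: GenotypeMatrix, k: int = 5, window: int = 20) -> GenotypeMatrix:
    return HaplotypeImputer(k=k, window=window).fit(gm).transform(gm)


def assemble_snpldb(gm: GenotypeMatrix, d_threshold: float = 0.7,
                    max_span_bp: int = 200_000) -> SnpldbSet:
    return SnpldbAssembler(d_threshold, max_span_bp).fit(gm).transform(gm)
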