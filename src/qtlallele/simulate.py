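"""Synthetic germplasm study generator.

Emulates the statistical structure the analysis assumes: a panel of fully
homozygous (inbred) accessions genotyped at SNPs that fall into
linkage-disequilibrium blocks, a handful of multi-allelic QTLs whose
haplotype effects carry both signs, maturity-group (MG) subpopulations with
mildly differentiated haplotype frequencies, and plot-level phenotypes from
a balanced multi-environment randomized-block trial with prescribed
entry-mean heritability and genotype-by-environment (GxE) heritability.

Within a block, every accession carries one founder haplotype, so
within-block LD is essentially complete while blocks segregate freely —
the regime under which haplotype-block (SNPLDB) markers are exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as qio
from .datatypes import GenotypeMatrix

#: default MG composition, proportional to a 361-accession panel spanning
#: late (III) to very early (000) maturity classes
DEFAULT_MG_LABELS = ("III", "II", "I", "0", "00", "000")
DEFAULT_MG_WEIGHTS = (21, 43, 79, 157, 45, 16)

GO_CATEGORIES = (
    "metabolic process",
    "protein metabolism",
    "transport",
    "transcription",
    "signal transduction",
    "response to stress",
    "response to stimulus",
    "development",
    "cell organization",
    "catabolic process",
    "biosynthetic process",
    "DNA or RNA metabolism",
    "electron transport",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``target_h2`` and ``target_h2_gei`` are the entry-mean heritability
    shares of genotype and GxE; their sum may not exceed 1.  Trait units
    are percent (seed protein content scale), hence the default population
    mean of 40.77.
    """

    n_accessions: int = 361
    n_chromosomes: int = 20
    chrom_cM_length: float = 110.0
    chrom_bp_length: int = 50_000_000
    n_blocks_per_chrom: int = 12
    snps_per_block: int = 6
    single_snp_block_frac: float = 0.4
    n_qtls: int = 30
    alleles_per_qtl: tuple[int, int] = (2, 10)
    qtl_effect_sd: float = 0.30
    #: rescale every QTL's allele effects so each locus contributes the
    #: same genetic variance (qtl_effect_sd^2); useful for power studies
    equalize_qtl_variance: bool = False
    n_environments: int = 2
    n_replications: int = 4
    target_h2: float = 0.83
    target_h2_gei: float = 0.12
    mg_labels: tuple[str, ...] = DEFAULT_MG_LABELS
    mg_weights: tuple[float, ...] = DEFAULT_MG_WEIGHTS
    mean: float = 40.77
    founder_pool_size: int = 12
    mg_concentration: float = 60.0
    env_effect_sd: float = 0.5
    rep_effect_sd: float = 0.2
    genes_per_chromosome: int = 40
    rng_seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_chromosomes": self.n_chromosomes,
            "n_blocks_per_chrom": self.n_blocks_per_chrom,
            "snps_per_block": self.snps_per_block,
            "n_environments": self.n_environments,
            "n_replications": self.n_replications,
            "founder_pool_size": self.founder_pool_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_qtls < 0:
            raise ValueError("n_qtls must be >= 0")
        if not 0 < self.target_h2 <= 1:
            raise ValueError("target_h2 must lie in (0, 1]")
        if not 0 <= self.target_h2_gei < 1:
            raise ValueError("target_h2_gei must lie in [0, 1)")
        if self.target_h2 + self.target_h2_gei > 1 + 1e-12:
            raise ValueError(
                "infeasible variance targets: target_h2 + target_h2_gei > 1"
            )
        if not 0 <= self.single_snp_block_frac < 1:
            raise ValueError("single_snp_block_frac must lie in [0, 1)")
        if self.n_qtls > self.n_chromosomes * self.n_blocks_per_chrom:
            raise ValueError("more QTLs requested than blocks available")
        if len(self.mg_labels) != len(self.mg_weights):
            raise ValueError("mg_labels and mg_weights must align")


@dataclass
class SyntheticStudy:
    """All artefacts of one simulated study, plus the generating truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    mg_labels: pd.Series
    genetic_map: pd.DataFrame
    genes: pd.DataFrame
    truth: pd.DataFrame
    genetic_values: pd.Series
    variance: dict[str, float] = field(default_factory=dict)


def _mg_sizes(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n accessions to MG classes."""
    quota = n * weights / weights.sum()
    sizes = np.floor(quota).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(quota - sizes))
    sizes[order[:rem]] += 1
    return sizes


def generate_population(config: SimulationConfig) -> SyntheticStudy:
    """Simulate genotypes, phenotypes and annotation for one study.

    The error and GxE variances are solved from the realized genetic
    variance so that the entry-mean heritabilities hit the configured
    targets up to sampling noise in the random effects.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cfg = config

    accessions = [f"L{i + 1:03d}" for i in range(cfg.n_accessions)]
    mg_sizes = _mg_sizes(cfg.n_accessions, np.asarray(cfg.mg_weights, float))
    mg = pd.Series(
        np.repeat(list(cfg.mg_labels), mg_sizes), index=accessions, name="mg"
    )
    mg_index = {label: np.flatnonzero(mg.to_numpy() == label) for label in cfg.mg_labels}

    n_blocks = cfg.n_chromosomes * cfg.n_blocks_per_chrom

    snp_rows: list[tuple] = []
    call_rows: list[np.ndarray] = []
    block_meta: list[dict] = []
    block_codes = np.empty((n_blocks, cfg.n_accessions), dtype=np.int32)
    block_haps: list[np.ndarray] = []

    b = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"Chr{c + 1:02d}"
        seg = cfg.chrom_bp_length // cfg.n_blocks_per_chrom
        for k in range(cfg.n_blocks_per_chrom):
            # a fraction of blocks are isolated single SNPs (the S.SNPLDB
            # class); the rest carry the configured SNP count
            s = (1 if rng.random() < cfg.single_snp_block_frac
                 else cfg.snps_per_block)
            pool = min(cfg.founder_pool_size, s + 1)
            start = k * seg + seg // 4
            positions = start + 150 * np.arange(s)
            cms = positions / cfg.chrom_bp_length * cfg.chrom_cM_length
            # founder pool built as a perfect phylogeny (each SNP mutates
            # once on the tree): every SNP pair then shows at most three
            # gametic classes, i.e. complete LD (|D'| = 1) within the
            # block.  Geometric frequency decay with a per-block rate so
            # common-allele counts vary across blocks.
            haps = np.zeros((pool, s), dtype=np.int8)
            sites = rng.permutation(s)
            for h in range(1, pool):
                haps[h] = haps[rng.integers(0, h)]
                haps[h, sites[h - 1]] ^= 1
            decay = rng.uniform(0.25, 0.75)
            base = (1 - decay) ** np.arange(pool)
            base /= base.sum()
            # mild MG differentiation of haplotype frequencies
            codes = np.empty(cfg.n_accessions, dtype=np.int32)
            for label in cfg.mg_labels:
                idx = mg_index[label]
                freq = rng.dirichlet(base * cfg.mg_concentration)
                codes[idx] = rng.choice(pool, size=idx.size, p=freq)
            block_codes[b] = codes
            block_haps.append(haps)
            block_meta.append(
                {"block": f"B{b + 1:04d}", "chrom": chrom,
                 "start": int(positions[0]), "end": int(positions[-1])}
            )
            for j in range(s):
                snp_rows.append(
                    (f"{chrom}_{int(positions[j])}", chrom, int(positions[j]),
                     float(cms[j]), "A", "G")
                )
                call_rows.append((2 * haps[codes, j]).astype(np.int8))
            b += 1

    snps = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "cM", "ref", "alt"])
    genotypes = GenotypeMatrix(accessions, snps, np.asarray(call_rows, dtype=np.int8))

    # QTL blocks: pick blocks whose common-haplotype count falls in range
    lo, hi = cfg.alleles_per_qtl
    n_common = np.array(
        [
            np.sum(np.bincount(block_codes[i], minlength=len(block_haps[i]))
                   / cfg.n_accessions >= 0.01)
            for i in range(n_blocks)
        ]
    )
    eligible = np.flatnonzero((n_common >= lo) & (n_common <= hi))
    if eligible.size < cfg.n_qtls:
        eligible = np.arange(n_blocks)
    qtl_blocks = np.sort(rng.choice(eligible, size=cfg.n_qtls, replace=False))

    g = np.zeros(cfg.n_accessions)
    truth_rows = []
    for q, bi in enumerate(qtl_blocks):
        codes = block_codes[bi]
        pool = len(block_haps[bi])
        freq = np.bincount(codes, minlength=pool) / cfg.n_accessions
        eff = rng.normal(0.0, cfg.qtl_effect_sd, size=pool)
        eff -= freq @ eff  # frequency-weighted zero mean over the panel
        if cfg.equalize_qtl_variance:
            var = float(freq @ eff**2)
            if var > 0:
                eff *= cfg.qtl_effect_sd / np.sqrt(var)
        g += eff[codes]
        meta = block_meta[bi]
        for h in range(pool):
            if freq[h] == 0:
                continue
            truth_rows.append(
                {
                    "qtl_id": f"qtl{q + 1:02d}",
                    "block_id": meta["block"],
                    "chrom": meta["chrom"],
                    "start": meta["start"],
                    "end": meta["end"],
                    "haplotype": "".join(map(str, block_haps[bi][h])),
                    "effect": eff[h],
                    "frequency": freq[h],
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["qtl_id", "block_id", "chrom", "start", "end",
                 "haplotype", "effect", "frequency"],
    )

    # variance components solved from realized genetic variance
    nt, nr = cfg.n_environments, cfg.n_replications
    sigma_g2 = float(np.var(g, ddof=1)) if cfg.n_qtls > 0 else 0.0
    if sigma_g2 > 0:
        denom = sigma_g2 / cfg.target_h2
        sigma_gt2 = cfg.target_h2_gei * denom * nt
        sigma_e2 = max(1.0 - cfg.target_h2 - cfg.target_h2_gei, 0.0) * denom * nt * nr
    else:
        sigma_gt2, sigma_e2 = 0.0, 1.0

    env_eff = rng.normal(0.0, cfg.env_effect_sd, size=nt)
    rep_eff = rng.normal(0.0, cfg.rep_effect_sd, size=(nt, nr))
    gxe = rng.normal(0.0, np.sqrt(sigma_gt2), size=(nt, cfg.n_accessions))
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=(nt, nr, cfg.n_accessions))

    recs = []
    for i in range(nt):
        for j in range(nr):
            y = cfg.mean + env_eff[i] + rep_eff[i, j] + g + gxe[i] + noise[i, j]
            for k, acc in enumerate(accessions):
                recs.append((acc, f"E{i + 1}", j + 1, y[k]))
    phenotypes = pd.DataFrame(
        recs, columns=["accession", "environment", "replication", "value"]
    )

    genetic_map = snps[["chrom", "pos", "cM"]].copy()
    genes = _simulate_genes(cfg, block_meta, qtl_blocks, rng)

    realized = {
        "sigma_g2": sigma_g2,
        "sigma_gt2": sigma_gt2,
        "sigma_e2": sigma_e2,
        "target_h2": cfg.target_h2,
        "target_h2_gei": cfg.target_h2_gei,
    }
    return SyntheticStudy(
        config=cfg,
        genotypes=genotypes,
        phenotypes=phenotypes,
        mg_labels=mg,
        genetic_map=genetic_map,
        genes=genes,
        truth=truth,
        genetic_values=pd.Series(g + cfg.mean, index=accessions, name="genetic_value"),
        variance=realized,
    )


def _simulate_genes(
    cfg: SimulationConfig,
    block_meta: list[dict],
    qtl_blocks: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene models: background genes plus one gene overlapping each QTL block."""
    rows = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"Chr{c + 1:02d}"
        starts = np.sort(
            rng.integers(1, cfg.chrom_bp_length - 5000, size=cfg.genes_per_chromosome)
        )
        for st in starts:
            gid += 1
            rows.append(
                {
                    "gene_id": f"Gene{gid:05d}",
                    "chrom": chrom,
                    "start": int(st),
                    "end": int(st + rng.integers(1000, 5000)),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "category": rng.choice(GO_CATEGORIES + ("other",)),
                }
            )
    for bi in qtl_blocks:
        meta = block_meta[bi]
        gid += 1
        rows.append(
            {
                "gene_id": f"Gene{gid:05d}",
                "chrom": meta["chrom"],
                "start": max(1, meta["start"] - 500),
                "end": meta["end"] + 500,
                "strand": "+",
                "category": rng.choice(GO_CATEGORIES),
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    return df.reset_index(drop=True)


def write_study(study: SyntheticStudy, directory: str) -> dict[str, str]:
    """Write all study files; returns a name -> path map.

    Files round-trip losslessly through the package readers.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "genotypes_vcf": os.path.join(directory, "genotypes.vcf"),
        "phenotypes": os.path.join(directory, "phenotypes.tsv"),
        "mg_labels": os.path.join(directory, "mg_labels.tsv"),
        "genetic_map": os.path.join(directory, "genetic_map.tsv"),
        "genes_gff3": os.path.join(directory, "genes.gff3"),
        "gene_categories": os.path.join(directory, "gene_categories.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
        "config": os.path.join(directory, "config.json"),
    }
    qio.write_vcf(study.genotypes, paths["genotypes_vcf"])
    qio.write_phenotypes(study.phenotypes, paths["phenotypes"])
    qio.write_mg_labels(study.mg_labels, paths["mg_labels"])
    qio.write_genetic_map(study.genetic_map, paths["genetic_map"])
    qio.write_gff3(study.genes, paths["genes_gff3"])
    qio.write_tsv(study.genes[["gene_id", "category"]], paths["gene_categories"])
    qio.write_tsv(study.truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(study.config), fh, indent=2, default=list)
    return paths
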