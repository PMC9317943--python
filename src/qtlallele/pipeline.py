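"""End-to-end orchestration: synthetic data or user inputs through QC,
SNPLDB assembly, phenotype analysis, GWAS, allele evolution, cross
prediction and candidate genes, with a provenance manifest.

Every output lands in a run directory; the manifest records the config,
the seed fan-out and a SHA-256 per file so a rerun with the same config is
verifiably identical.  The reporter only re-reads stage outputs — it never
recomputes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cross as xmod
from . import evolution, genes as gmod, gwas, io as qio, phenotype, snpldb
from .simulate import SimulationConfig, generate_population, write_study

ALL_STAGES = ("simulate", "qc", "snpldb", "anova", "gwas", "evolution",
              "cross", "genes", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class MissingDependencyError(StageError):
    pass


@dataclass
class PipelineConfig:
    """All stage settings; defaults are the analysis's standard settings
    (QC caps 20%/20%, MAF floor 1%, D' > 0.7, stage levels 0.05/0.01, 10
    eigenvectors, 200 kb gene pad, 2,000 progenies, percentiles 90/95/99).
    """

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either a synthetic config or paths to study files
    synthetic: SimulationConfig | None = None
    genotypes_vcf: str | None = None
    phenotypes: str | None = None
    mg_labels: str | None = None
    genetic_map: str | None = None
    genes_gff3: str | None = None
    gene_categories: str | None = None
    # qc + snpldb
    max_missing: float = 0.20
    max_het: float = 0.20
    min_maf: float = 0.01
    d_threshold: float = 0.7
    max_span_bp: int = 200_000
    # gwas
    alpha1: float = 0.05
    alpha2: float = 0.01
    n_eigenvectors: int = 10
    lc_threshold_pct: float = 1.0
    # evolution
    old_groups: tuple[str, ...] = ("III", "II", "I")
    new_groups: tuple[str, ...] = ("0", "00", "000")
    # cross prediction
    n_progeny: int = 2000
    cross_model: str = "linkage"
    progeny_model: str = "doubled_gamete"
    percentiles: tuple[float, ...] = (90.0, 95.0, 99.0)
    top_k: int = 5
    # candidate genes
    pad_bp: int = 200_000
    gene_alpha: float = 0.05
    gene_flank_bp: int = 5000

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds fanned out from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(ALL_STAGES))
    return {s: int(v % (2**31)) for s, v in zip(ALL_STAGES, state)}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Executes stages in dependency order inside ``config.out_dir``."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.dir = config.out_dir
        os.makedirs(self.dir, exist_ok=True)
        self.seeds = _stage_seeds(config.seed)
        self.outputs: dict[str, str] = {}

    def path(self, name: str) -> str:
        return os.path.join(self.dir, name)

    def _record(self, name: str) -> str:
        p = self.path(name)
        self.outputs[name] = p
        return p

    def _need(self, attr: str, stage: str):
        if getattr(self, attr, None) is None:
            raise MissingDependencyError(
                stage, f"missing dependency '{attr}' (stage toggled off?)"
            )
        return getattr(self, attr)

    # -- stages ----------------------------------------------------------

    def stage_simulate(self):
        cfg = self.cfg.synthetic or SimulationConfig()
        cfg = dataclasses.replace(cfg, rng_seed=self.seeds["simulate"])
        study = generate_population(cfg)
        paths = write_study(study, os.path.join(self.dir, "inputs"))
        for k, p in paths.items():
            self.outputs[os.path.relpath(p, self.dir)] = p
        self.cfg.genotypes_vcf = paths["genotypes_vcf"]
        self.cfg.phenotypes = paths["phenotypes"]
        self.cfg.mg_labels = paths["mg_labels"]
        self.cfg.genetic_map = paths["genetic_map"]
        self.cfg.genes_gff3 = paths["genes_gff3"]
        self.cfg.gene_categories = paths["gene_categories"]
        self._study = study

    def _load_inputs(self):
        for attr in ("genotypes_vcf", "phenotypes", "mg_labels",
                     "genetic_map"):
            if getattr(self.cfg, attr) is None:
                raise MissingDependencyError(
                    "qc", f"no input path for '{attr}' and simulate stage off"
                )
        self.map_ = qio.read_genetic_map(self.cfg.genetic_map)
        self.genotypes_ = qio.read_vcf(self.cfg.genotypes_vcf, self.map_)
        self.records_ = qio.read_phenotypes(self.cfg.phenotypes)
        self.mg_ = qio.read_mg_labels(self.cfg.mg_labels)

    def stage_qc(self):
        self._load_inputs()
        filt = snpldb.SnpFilter(self.cfg.max_missing, self.cfg.max_het,
                                self.cfg.min_maf).fit(self.genotypes_)
        gm = filt.transform(self.genotypes_)
        gm = snpldb.HaplotypeImputer().fit(gm).transform(gm)
        self.qc_genotypes_ = gm
        with open(self._record("qc_report.json"), "w") as fh:
            json.dump(filt.report_, fh, indent=2)

    def stage_snpldb(self):
        gm = self._need("qc_genotypes_", "snpldb")
        self.snpldbs_ = snpldb.SnpldbAssembler(
            self.cfg.d_threshold, self.cfg.max_span_bp
        ).fit(gm).transform(gm)
        qio.write_snpldb_definitions(self.snpldbs_,
                                     self._record("snpldb_markers.tsv"))
        qio.write_allele_codes(self.snpldbs_,
                               self._record("snpldb_codes.tsv"))

    def stage_anova(self):
        records = self._need("records_", "anova")
        table = phenotype.fit_joint_anova(records)
        qio.write_tsv(table, self._record("anova.tsv"))
        vc = phenotype.estimate_variance_components(records)
        self.vc_ = vc
        self.h2_ = phenotype.heritability(vc, "multi")
        summary = {
            "sigma_g2": vc.sigma_g2, "sigma_gt2": vc.sigma_gt2,
            "sigma_e2": vc.sigma_e2, "method": vc.method,
            "grand_mean": vc.grand_mean,
            "h2_multi": self.h2_,
            "h2_single": phenotype.heritability(vc, "single"),
            "h2_gei": phenotype.gei_heritability(vc),
            "gcv_pct": phenotype.gcv(vc),
        }
        with open(self._record("variance_components.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        mg_table = phenotype.summarize_by_mg(records, self.mg_)
        qio.write_tsv(mg_table.reset_index(), self._record("mg_summary.tsv"))

    def stage_gwas(self):
        snpldbs = self._need("snpldbs_", "gwas")
        records = self._need("records_", "gwas")
        h2 = getattr(self, "h2_", None)
        est = gwas.RtmGwas(
            alpha1=self.cfg.alpha1, alpha2=self.cfg.alpha2,
            n_eigenvectors=self.cfg.n_eigenvectors,
        ).fit(snpldbs, records, h2_cap=h2 if h2 is not None else 1.0)
        self.gwas_ = est
        self.model_ = est.model_
        qio.write_tsv(est.preselection_, self._record("stage1_scan.tsv"))
        qio.write_tsv(est.model_.table(), self._record("qtl_table.tsv"))
        qio.write_tsv(
            gwas.classify_contribution(est.model_, self.cfg.lc_threshold_pct),
            self._record("qtl_classes.tsv"),
        )
        eff_rows = []
        for l in est.model_.loci:
            for a, (hap, e, f) in enumerate(
                zip(l.alleles, l.effects, l.frequencies)
            ):
                eff_rows.append({"qtl": l.name, "allele": a, "haplotype": hap,
                                 "effect": e, "frequency": f})
        qio.write_tsv(
            pd.DataFrame(eff_rows, columns=["qtl", "allele", "haplotype",
                                            "effect", "frequency"]),
            self._record("allele_effects.tsv"),
        )
        self.matrix_ = gwas.build_matrix(est.model_, snpldbs)
        qio.write_tsv(
            self.matrix_.to_frame().rename_axis("qtl").reset_index(),
            self._record("qtl_allele_matrix.tsv"),
        )
        codes_df = pd.DataFrame(self.matrix_.codes,
                                index=self.matrix_.locus_ids,
                                columns=self.matrix_.accessions)
        qio.write_tsv(codes_df.rename_axis("qtl").reset_index(),
                      self._record("qtl_allele_codes.tsv"))

    def stage_evolution(self):
        matrix = self._need("matrix_", "evolution")
        if matrix.effects.shape[0] == 0:
            pd.DataFrame(columns=["category", "total", "negative",
                                  "positive", "fraction"]).to_csv(
                self._record("allele_changes.tsv"), sep="\t", index=False)
            return
        summary = evolution.compare_mg_groups(
            matrix, self.mg_, self.cfg.old_groups, self.cfg.new_groups
        )
        qio.write_tsv(summary.to_frame(), self._record("allele_changes.tsv"))

    def stage_cross(self):
        matrix = self._need("matrix_", "cross")
        model = self._need("model_", "cross")
        crosses = xmod.enumerate_crosses(matrix.accessions, self.mg_)
        loci = pd.DataFrame(
            {"locus": [l.name for l in model.loci],
             "chrom": [l.chrom for l in model.loci],
             "pos": [l.start for l in model.loci]}
        )
        loci_map = (xmod.locus_map_positions(loci, self.map_)
                    if len(loci) else
                    pd.DataFrame(columns=["locus", "chrom", "cM"]))
        chrom_lengths = self.map_.groupby("chrom")["cM"].max().to_dict()
        config = xmod.ProgenySimConfig(
            n_progeny=self.cfg.n_progeny, model=self.cfg.cross_model,
            progeny_model=self.cfg.progeny_model,
            percentiles=self.cfg.percentiles,
            rng_seed=self.seeds["cross"],
        )
        observed = self.records_.groupby("accession")["value"].mean()
        records = xmod.simulate_crosses(matrix, loci_map, crosses, observed,
                                        config, chrom_lengths)
        qio.write_tsv(records, self._record("cross_records.tsv"))
        mg_grp = self.mg_.map(xmod.mg_group)
        group_max = observed.groupby(mg_grp.reindex(observed.index)).max()
        summary = xmod.summarize_potentials(records, observed.mean(),
                                            group_max.to_dict())
        qio.write_tsv(summary, self._record("cross_potentials.tsv"))
        tops = []
        for scope in list(group_max.index) + ["within", "between", "entire"]:
            top = xmod.rank_optimal(records, scope, self.cfg.top_k)
            top.insert(0, "scope", scope)
            tops.append(top)
        qio.write_tsv(pd.concat(tops, ignore_index=True),
                      self._record("optimal_crosses.tsv"))

    def stage_genes(self):
        matrix = self._need("matrix_", "genes")
        model = self._need("model_", "genes")
        if self.cfg.genes_gff3 is None:
            raise MissingDependencyError("genes", "no GFF3 annotation path")
        db = gmod.load_annotation(self.cfg.genes_gff3)
        qtl_table = pd.DataFrame(
            {"qtl": [l.name for l in model.loci],
             "chrom": [l.chrom for l in model.loci],
             "start": [l.start for l in model.loci],
             "end": [l.end for l in model.loci]}
        )
        scan = gmod.candidate_scan(
            db, self.qc_genotypes_, qtl_table, matrix.codes,
            pad_bp=self.cfg.pad_bp, alpha=self.cfg.gene_alpha,
            flank_bp=self.cfg.gene_flank_bp,
        )
        qio.write_tsv(scan, self._record("gene_tests.tsv"))
        if self.cfg.gene_categories is not None and len(scan):
            go = qio.read_tsv(self.cfg.gene_categories)
            tallies = gmod.categorize_genes(scan, go)
        else:
            tallies = pd.DataFrame(columns=["category", "n_genes"])
        qio.write_tsv(tallies, self._record("gene_categories_tally.tsv"))

    # -- driver ----------------------------------------------------------

    def run(self) -> dict:
        executed = []
        for stage in ALL_STAGES:
            if stage not in self.cfg.stages:
                continue
            method = getattr(self, f"stage_{stage}", None)
            if stage == "report":
                continue  # reporting happens after the manifest
            try:
                method()
                executed.append(stage)
            except StageError:
                self._write_error(stage, "missing dependency")
                raise
            except Exception as exc:  # halt with machine-readable report
                self._write_error(stage, str(exc))
                raise StageError(stage, str(exc)) from exc
        manifest = {
            "config": dataclasses.asdict(self.cfg),
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "stage_seeds": self.seeds,
            "stages_executed": executed,
            "files": {name: _sha256(p) for name, p in
                      sorted(self.outputs.items()) if os.path.exists(p)},
        }
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        if "report" in self.cfg.stages:
            make_report(self.dir)
        return manifest

    def _write_error(self, stage: str, message: str):
        with open(self.path("error.json"), "w") as fh:
            json.dump({"stage": stage, "error": message}, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the provenance manifest."""
    return PipelineRun(config).run()


def _md_table(df: pd.DataFrame, max_rows: int = 30) -> str:
    if df.empty:
        return "_(empty)_\n"
    show = df.head(max_rows)
    out = "| " + " | ".join(map(str, show.columns)) + " |\n"
    out += "|" + "---|" * len(show.columns) + "\n"
    for _, row in show.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, float) else str(v) for v in row]
        out += "| " + " | ".join(cells) + " |\n"
    if len(df) > max_rows:
        out += f"\n_{len(df) - max_rows} more rows in the stage output._\n"
    return out


def make_report(run_dir: str) -> str:
    """Markdown summary assembled from stage outputs (no recomputation)."""
    sections = []
    sections.append("# Pipeline report\n")
    manifest_path = os.path.join(run_dir, "manifest.json")
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        sections.append(
            f"Config hash `{manifest['config_hash']}`, seed "
            f"{manifest['seed']}.\n"
        )
    blocks = [
        ("Maturity-group summary", "mg_summary.tsv"),
        ("Variance components", "variance_components.json"),
        ("Detected QTLs", "qtl_table.tsv"),
        ("QTL contribution classes", "qtl_classes.tsv"),
        ("Allele changes between MG groups", "allele_changes.tsv"),
        ("Cross-potential summary", "cross_potentials.tsv"),
        ("Optimal crosses", "optimal_crosses.tsv"),
        ("Candidate-gene category tally", "gene_categories_tally.tsv"),
    ]
    for title, name in blocks:
        path = os.path.join(run_dir, name)
        if not os.path.exists(path):
            raise FileNotFoundError(f"incomplete run: {name} missing")
        sections.append(f"\n## {title}\n")
        if name.endswith(".json"):
            with open(path) as fh:
                data = json.load(fh)
            sections.append("```json\n" + json.dumps(data, indent=2) + "\n```\n")
        else:
            df = pd.read_csv(path, sep="\t")
            if name == "qtl_table.tsv" and df.empty:
                sections.append("Zero loci detected.\n")
            else:
                sections.append(_md_table(df))
    report = "".join(sections)
    with open(os.path.join(run_dir, "report.md"), "w") as fh:
        fh.write(report)
    return report
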