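"""GSC structure covariates and the restricted two-stage multi-locus scan."""

import numpy as np
import pandas as pd
import pytest

from qtlallele import gwas, phenotype, snpldb
from qtlallele.datatypes import SnpldbMarker, SnpldbSet
from qtlallele.gwas import (QtlLocus, QtlModel, RtmGwas, build_matrix,
                            classify_contribution, compute_gsc)
from qtlallele.simulate import SimulationConfig, generate_population


def marker_from_codes(mid, codes, chrom="Chr01", start=100):
    codes = np.asarray(codes, dtype=np.int32)
    n_alleles = codes.max() + 1
    freq = np.array([np.mean(codes == i) for i in range(n_alleles)])
    return SnpldbMarker(
        id=mid, chrom=chrom, start=start, end=start + 10,
        snp_ids=[f"{mid}_s"], haplotypes=[str(i) for i in range(n_alleles)],
        frequencies=freq, codes=codes,
    )


class TestGsc:
    def test_identical_accessions(self):
        m = [marker_from_codes(f"m{i}", [0, 0, 0]) for i in range(3)]
        cov = compute_gsc(SnpldbSet(m, ["a", "b", "c"]))
        assert np.allclose(cov.gsc, 1.0)
        assert np.allclose(np.diag(cov.gsc), 1.0)

    def test_fully_distinct_accessions(self):
        m = [marker_from_codes(f"m{i}", [0, 1, 2]) for i in range(4)]
        cov = compute_gsc(SnpldbSet(m, ["a", "b", "c"]))
        off = cov.gsc[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_half_shared_markers(self):
        codes = [[0, 0], [0, 0], [0, 1], [0, 1]]
        m = [marker_from_codes(f"m{i}", c) for i, c in enumerate(codes)]
        cov = compute_gsc(SnpldbSet(m, ["a", "b"]))
        assert cov.gsc[0, 1] == pytest.approx(0.5)
        assert cov.gsc == pytest.approx(cov.gsc.T)

    def test_eigenvalues_descending(self, small_snpldbs):
        cov = compute_gsc(small_snpldbs)
        assert (np.diff(cov.eigenvalues) <= 1e-9).all()


def _phenotypes_from_values(values, accessions, envs=("E1", "E2"), noise=0.0,
                            seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for e in envs:
        for a, v in zip(accessions, values):
            rows.append((a, e, 1, v + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["accession", "environment",
                                       "replication", "value"])


class TestStage1:
    def test_strong_marker_preselected(self, small_snpldbs):
        rng = np.random.default_rng(0)
        m = small_snpldbs.markers[3]
        effect = np.arange(m.n_alleles, dtype=float)  # well-separated alleles
        values = 40 + effect[m.codes] + rng.normal(0, 0.5, m.codes.size)
        records = _phenotypes_from_values(values, small_snpldbs.accessions,
                                          noise=0.2)
        # few structure covariates: a 16-marker GSC would otherwise absorb
        # the single-marker signal into its eigenvectors
        scan = gwas.stage1_scan(small_snpldbs, records, alpha=0.05,
                                n_eigenvectors=2)
        assert scan.loc[3, "selected"]
        assert scan.loc[3, "p"] < 1e-10

    def test_null_preselection_rate_modest(self, small_snpldbs):
        rng = np.random.default_rng(5)
        values = rng.normal(40, 1, len(small_snpldbs.accessions))
        records = _phenotypes_from_values(values, small_snpldbs.accessions,
                                          noise=0.3, seed=6)
        scan = gwas.stage1_scan(small_snpldbs, records, alpha=0.05)
        # 16 markers under the null: expect ~5% hits, allow binomial spread
        assert scan["selected"].sum() <= 5


class TestStage2:
    def test_single_planted_qtl_recovered_with_correct_sign(self):
        cfg = SimulationConfig(n_accessions=300, n_chromosomes=2,
                               n_blocks_per_chrom=6, n_qtls=1,
                               qtl_effect_sd=0.6, target_h2=0.8,
                               target_h2_gei=0.05, rng_seed=21)
        study = generate_population(cfg)
        gm, _ = snpldb.filter_snps(study.genotypes)
        sets = snpldb.assemble_snpldb(snpldb.impute_missing(gm))
        est = RtmGwas().fit(sets, study.phenotypes, h2_cap=0.85)
        model = est.model_
        assert model.n_loci >= 1
        truth_start = int(study.truth["start"].iloc[0])
        hits = [l for l in model.loci
                if l.chrom == study.truth["chrom"].iloc[0]
                and l.start <= truth_start <= l.end + 1000]
        assert hits, "planted locus not among detections"
        locus = hits[0]
        # per-accession true allele effect at the planted QTL, rebuilt from
        # the unfiltered genotypes over the block span
        snp_mask = ((study.genotypes.snps["chrom"] == locus.chrom)
                    & (study.genotypes.snps["pos"] >= truth_start)
                    & (study.genotypes.snps["pos"]
                       <= int(study.truth["end"].iloc[0]))).to_numpy()
        haps = study.genotypes.calls[snp_mask] // 2
        strings = ["".join(map(str, haps[:, a]))
                   for a in range(haps.shape[1])]
        truth_eff = dict(zip(study.truth["haplotype"], study.truth["effect"]))
        true_per_acc = np.array([truth_eff[s] for s in strings])
        by_id = {m.id: m for m in sets.markers}
        est_per_acc = locus.effects[by_id[locus.marker_id].codes]
        # estimated allele ordering must track the true one
        assert np.corrcoef(est_per_acc, true_per_acc)[0, 1] > 0.9
        best = int(np.argmax(locus.effects))
        worst = int(np.argmin(locus.effects))
        carriers_best = by_id[locus.marker_id].codes == best
        carriers_worst = by_id[locus.marker_id].codes == worst
        assert (true_per_acc[carriers_best].mean()
                > true_per_acc[carriers_worst].mean())

    def test_zero_cap_forbids_any_term(self, small_snpldbs, small_study):
        est = RtmGwas().fit(small_snpldbs, small_study.phenotypes, h2_cap=0.0)
        assert est.model_.n_loci == 0
        assert est.model_.total_r2 == 0.0

    def test_total_r2_never_exceeds_cap(self, small_snpldbs, small_study):
        for cap in (0.10, 0.30, 0.85):
            est = RtmGwas().fit(small_snpldbs, small_study.phenotypes,
                                h2_cap=cap)
            assert est.model_.total_r2 <= cap + 1e-12

    def test_permutation_destroys_detections(self, small_snpldbs,
                                             small_study):
        # permuting accession labels severs marker-phenotype links; the
        # permuted phenotype keeps its heritable between-accession spread,
        # whose cross-environment residual correlation leaves the stepwise
        # scan a little anti-conservative, so a stray locus or two can
        # survive — detections must still collapse relative to the real fit
        baseline = RtmGwas().fit(small_snpldbs, small_study.phenotypes,
                                 h2_cap=0.85).model_.n_loci
        counts = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            perm = small_study.phenotypes.copy()
            accs = perm["accession"].unique()
            mapping = dict(zip(accs, rng.permutation(accs)))
            perm["accession"] = perm["accession"].map(mapping)
            est = RtmGwas().fit(small_snpldbs, perm, h2_cap=0.85)
            counts.append(est.model_.n_loci)
        assert baseline >= 4
        assert np.median(counts) <= 2
        assert max(counts) < baseline

    def test_locus_effects_frequency_centred(self, small_snpldbs,
                                             small_study):
        est = RtmGwas().fit(small_snpldbs, small_study.phenotypes,
                            h2_cap=0.85)
        assert est.model_.n_loci > 0
        for l in est.model_.loci:
            assert abs(l.frequencies @ l.effects) < 1e-9
        # per-locus R2 sums to the joint model R2
        r2_sum = sum(l.r2_main + l.r2_qei for l in est.model_.loci)
        assert r2_sum == pytest.approx(est.model_.total_r2, rel=1e-6)


def toy_model(r2s):
    loci = [
        QtlLocus(
            name=f"q-{i}", marker_id=f"m{i}", chrom="Chr01", start=i * 100,
            end=i * 100 + 10, alleles=["0", "1"],
            frequencies=np.array([0.5, 0.5]),
            effects=np.array([-0.5, 0.5]), qei_effects=None,
            has_main=True, has_qei=False, r2_main=r2 / 100, r2_qei=0.0,
            p_model=1e-6, p_main=1e-6, p_qei=np.nan,
        )
        for i, r2 in enumerate(r2s)
    ]
    return QtlModel(loci=loci, intercept=40.0,
                    total_r2=sum(r2s) / 100, h2_cap=0.83)


class TestClassification:
    def test_threshold_splits_lc_sc(self):
        out = classify_contribution(toy_model([2.32, 0.99]), 1.0)
        assert out.set_index("qtl")["class"].to_dict() == {"q-0": "LC",
                                                           "q-1": "SC"}

    def test_empty_model(self):
        out = classify_contribution(toy_model([]), 1.0)
        assert len(out) == 0


@pytest.fixture(scope="module")
def fitted(small_snpldbs, small_study):
    return RtmGwas().fit(small_snpldbs, small_study.phenotypes, h2_cap=0.85)


class TestAlleleMatrix:
    def test_dimensions(self, fitted, small_snpldbs):
        mat = build_matrix(fitted.model_, small_snpldbs)
        assert mat.effects.shape == (fitted.model_.n_loci,
                                     len(small_snpldbs.accessions))

    def test_prediction_consistency(self, fitted, small_snpldbs):
        mat = build_matrix(fitted.model_, small_snpldbs)
        direct = fitted.predict(small_snpldbs)
        assert np.allclose(direct,
                           mat.intercept + mat.effects.sum(axis=0))

    def test_entries_are_allele_effects(self, fitted, small_snpldbs):
        mat = build_matrix(fitted.model_, small_snpldbs)
        by_id = {m.id: m for m in small_snpldbs.markers}
        for r, l in enumerate(fitted.model_.loci):
            codes = by_id[l.marker_id].codes
            assert np.allclose(mat.effects[r], l.effects[codes])

    def test_predictions_correlate_with_true_genetic_values(
            self, fitted, small_snpldbs, small_study):
        pred = fitted.predict(small_snpldbs)
        true = small_study.genetic_values.loc[
            small_snpldbs.accessions].to_numpy()
        assert np.corrcoef(pred, true)[0, 1] > 0.6
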