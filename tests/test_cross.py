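"""Cross enumeration, progeny simulation and potential prediction."""

import numpy as np
import pandas as pd
import pytest

from qtlallele.cross import (CrossSimulator, ProgenySimConfig, cross_potential,
                             enumerate_crosses, locus_map_positions, mg_group,
                             predict_value, rank_optimal,
                             recombination_potential, simulate_crosses,
                             simulate_progeny, summarize_potentials,
                             transgressive_potential)
from qtlallele.datatypes import QtlAlleleMatrix


def two_locus_matrix(effects1=(-1.0, 1.0), effects2=(-1.0, 1.0),
                     intercept=40.0, chroms=("c1", "c2")):
    eff = {"L1": np.array(effects1), "L2": np.array(effects2)}
    codes = np.array([[0, 1], [0, 1]], dtype=np.int32)
    values = np.stack([eff["L1"][codes[0]], eff["L2"][codes[1]]])
    mat = QtlAlleleMatrix(["L1", "L2"], ["P1", "P2"], values, codes,
                          intercept, eff)
    lmap = pd.DataFrame({"locus": ["L1", "L2"], "chrom": list(chroms),
                         "cM": [10.0, 30.0]})
    return mat, lmap


class TestEnumeration:
    def test_pair_count_formula(self):
        for n in (2, 5, 30):
            accs = [f"a{i}" for i in range(n)]
            mg = pd.Series("I", index=accs)
            assert len(enumerate_crosses(accs, mg)) == n * (n - 1) // 2

    def test_group_collapse_and_kind(self):
        accs = ["a", "b", "c", "d"]
        mg = pd.Series(["I", "III", "0", "00"], index=accs)
        df = enumerate_crosses(accs, mg)
        ab = df[(df.p1 == "a") & (df.p2 == "b")].iloc[0]
        assert ab.kind == "within" and ab.group1 == "I + II + III"
        ac = df[(df.p1 == "a") & (df.p2 == "c")].iloc[0]
        assert ac.kind == "between"

    def test_group_filter(self):
        accs = ["a", "b", "c"]
        mg = pd.Series(["I", "0", "0"], index=accs)
        df = enumerate_crosses(accs, mg, group_filter={"0"})
        assert len(df) == 1 and set(df[["p1", "p2"]].iloc[0]) == {"b", "c"}
        with pytest.raises(ValueError):
            enumerate_crosses(accs, mg, group_filter={"00"})

    def test_mg_group_labels(self):
        assert mg_group("II") == "I + II + III"
        assert mg_group("000") == "000"


class TestProgenySimulation:
    def test_identical_parents_identical_progeny(self):
        mat, lmap = two_locus_matrix()
        mat.codes[:, 1] = mat.codes[:, 0]
        cfg = ProgenySimConfig(n_progeny=50, rng_seed=1)
        rec = cross_potential(0, 1, mat, lmap, cfg)
        assert rec["sd"] == 0.0
        assert rec["p95"] == rec["min"] == rec["max"]

    def test_cosegregation_at_same_map_position(self):
        lmap = pd.DataFrame({"locus": ["L1", "L2"], "chrom": ["c1", "c1"],
                             "cM": [25.0, 25.0]})
        cfg = ProgenySimConfig(n_progeny=500, rng_seed=3)
        rng = np.random.default_rng(0)
        codes = simulate_progeny(np.array([0, 0]), np.array([1, 1]), lmap,
                                 cfg, rng, {"c1": 100.0})
        assert (codes[:, 0] == codes[:, 1]).all()

    def test_recombinant_fraction_matches_haldane(self):
        # 20 cM interval: r = (1 - exp(-0.4))/2 = 0.1648
        lmap = pd.DataFrame({"locus": ["L1", "L2"], "chrom": ["c1", "c1"],
                             "cM": [40.0, 60.0]})
        cfg = ProgenySimConfig(n_progeny=20000, rng_seed=4)
        rng = np.random.default_rng(11)
        codes = simulate_progeny(np.array([0, 0]), np.array([1, 1]), lmap,
                                 cfg, rng, {"c1": 120.0})
        rf = np.mean(codes[:, 0] != codes[:, 1])
        expect = 0.5 * (1 - np.exp(-0.4))
        se = np.sqrt(expect * (1 - expect) / 20000)
        assert abs(rf - expect) < 3 * se

    def test_ril_model_inflates_recombination(self):
        lmap = pd.DataFrame({"locus": ["L1", "L2"], "chrom": ["c1", "c1"],
                             "cM": [40.0, 60.0]})
        r = 0.5 * (1 - np.exp(-0.4))
        big_r = 2 * r / (1 + 2 * r)
        cfg = ProgenySimConfig(n_progeny=20000, progeny_model="ril",
                               rng_seed=4)
        rng = np.random.default_rng(12)
        codes = simulate_progeny(np.array([0, 0]), np.array([1, 1]), lmap,
                                 cfg, rng, {"c1": 120.0})
        rf = np.mean(codes[:, 0] != codes[:, 1])
        se = np.sqrt(big_r * (1 - big_r) / 20000)
        assert abs(rf - big_r) < 3 * se

    def test_progeny_allele_frequency_balanced(self):
        mat, lmap = two_locus_matrix()
        cfg = ProgenySimConfig(n_progeny=2000, rng_seed=9)
        sim = CrossSimulator(mat, lmap, cfg)
        rng = np.random.default_rng(2)
        codes = simulate_progeny(np.array([0, 0]), np.array([1, 1]), lmap,
                                 cfg, rng, {"c1": 100, "c2": 100})
        for l in range(2):
            f = codes[:, l].mean()
            assert abs(f - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_linkage_and_independent_agree_for_unlinked_loci(self):
        mat, lmap = two_locus_matrix()  # loci on different chromosomes
        base = dict(n_progeny=4000, rng_seed=6)
        lk = cross_potential(0, 1, mat, lmap,
                             ProgenySimConfig(model="linkage", **base))
        ind = cross_potential(0, 1, mat, lmap,
                              ProgenySimConfig(model="independent", **base))
        assert lk["mean"] == pytest.approx(ind["mean"], abs=0.15)
        assert lk["p95"] == pytest.approx(ind["p95"], abs=0.2)


class TestPrediction:
    def test_progeny_identical_to_parent_scores_parent_value(self):
        mat, _ = two_locus_matrix()
        codes = np.array([[0, 0], [1, 1]], dtype=np.int32)
        vals = predict_value(codes, mat)
        expected = mat.predicted_values()
        assert vals == pytest.approx(expected)

    def test_all_zero_effects_yield_intercept(self):
        mat, _ = two_locus_matrix(effects1=(0, 0), effects2=(0, 0))
        codes = np.array([[0, 1], [1, 0]], dtype=np.int32)
        assert predict_value(codes, mat) == pytest.approx([40.0, 40.0])

    def test_four_progeny_enumeration(self):
        mat, _ = two_locus_matrix(effects1=(-1, 1), effects2=(-0.5, 0.5))
        codes = np.array([[0, 0], [0, 1], [1, 0], [1, 1]]).T
        vals = predict_value(np.array(codes.T), mat)
        assert sorted(vals) == pytest.approx([38.5, 39.5, 40.5, 41.5])

    def test_unknown_allele_rejected(self):
        mat, _ = two_locus_matrix()
        with pytest.raises(ValueError, match="unknown allele"):
            predict_value(np.array([[0, 5]]), mat)


class TestPercentiles:
    def test_order_statistic_interpolation_rule(self):
        vals = np.arange(1.0, 101.0)
        cfg = ProgenySimConfig(n_progeny=100, rng_seed=0)
        from qtlallele.cross import _summaries
        s = _summaries(vals, (90, 95, 99))
        assert s["p95"] == pytest.approx(95.05)
        assert s["p90"] == pytest.approx(90.1)

    def test_independent_p95_matches_enumeration(self):
        # 2 unlinked loci, effects +/-1: progeny values 38, 40, 40, 42
        # equally likely; the top atom (25%) far exceeds the upper 5%, so
        # the large-sample P95 equals the maximum, 42
        mat, lmap = two_locus_matrix()
        cfg = ProgenySimConfig(n_progeny=2000, model="independent",
                               rng_seed=13)
        rec = cross_potential(0, 1, mat, lmap, cfg)
        assert rec["p95"] == pytest.approx(42.0)
        assert rec["min"] == pytest.approx(38.0)
        assert rec["mean"] == pytest.approx(40.0, abs=3 * 1.42 / np.sqrt(2000))


class TestReports:
    def make_records(self):
        rows = [
            ("a", "b", "G1", "G1", "within", 40, 41, 43.0, 44.0, 45.0),
            ("a", "c", "G1", "G2", "between", 40, 42, 44.0, 45.0, 46.0),
            ("b", "c", "G1", "G2", "between", 41, 42, 42.0, 43.0, 44.0),
        ]
        return pd.DataFrame(rows, columns=["p1", "p2", "group1", "group2",
                                           "kind", "y1", "y2", "p90", "p95",
                                           "p99"])

    def test_potential_arithmetic(self):
        assert recombination_potential(43.29, 40.77) == pytest.approx(2.52)
        assert transgressive_potential(50.00, 46.07) == pytest.approx(3.93)

    def test_scope_summary(self):
        rec = self.make_records()
        out = summarize_potentials(rec, population_mean=41.0,
                                   group_max={"G1": 41.0, "G2": 42.0})
        ent = out.set_index("scope").loc["entire"]
        assert ent["n_crosses"] == 3
        assert ent["mean_p95"] == pytest.approx(44.0)
        assert ent["recombination_potential"] == pytest.approx(3.0)
        assert ent["transgressive_potential"] == pytest.approx(45.0 - 42.0)
        assert ent["n_superior"] == 3
        win = out.set_index("scope").loc["G1"]
        assert win["n_crosses"] == 1 and win["check_max"] == 41.0

    def test_missing_group_max_rejected(self):
        with pytest.raises(ValueError, match="missing observed maxima"):
            summarize_potentials(self.make_records(), 41.0, {"G1": 41.0})

    def test_ranking_and_tie_break(self):
        rec = self.make_records()
        top = rank_optimal(rec, "entire", top_k=2)
        assert top.iloc[0]["p95"] == 45.0
        assert len(top) == 2
        # permuting the input leaves the ranking unchanged
        perm = rec.sample(frac=1.0, random_state=5)
        top2 = rank_optimal(perm, "entire", top_k=2)
        pd.testing.assert_frame_equal(top, top2)
        # top_k beyond available returns everything
        assert len(rank_optimal(rec, "entire", top_k=50)) == 3

    def test_percentile_ordering_invariant(self):
        mat, lmap = two_locus_matrix()
        rec = cross_potential(0, 1, mat, lmap,
                              ProgenySimConfig(n_progeny=400, rng_seed=2))
        assert (rec["min"] <= rec["p90"] <= rec["p95"] <= rec["p99"]
                <= rec["max"])

    def test_p95_bounded_by_best_parental_combination(self):
        mat, lmap = two_locus_matrix(effects1=(-0.7, 0.7),
                                     effects2=(-0.3, 0.9))
        rec = cross_potential(0, 1, mat, lmap,
                              ProgenySimConfig(n_progeny=2000, rng_seed=8))
        upper = 40.0 + 0.7 + 0.9
        assert rec["p95"] <= upper + 1e-9


class TestDeterminism:
    def test_result_independent_of_enumeration_order(self):
        mat, lmap = two_locus_matrix()
        cfg = ProgenySimConfig(n_progeny=300, rng_seed=7)
        a = cross_potential(0, 1, mat, lmap, cfg)
        b = cross_potential(1, 0, mat, lmap, cfg)
        assert a == b

    def test_simulate_crosses_reproducible(self):
        mat, lmap = two_locus_matrix()
        crosses = pd.DataFrame([{"p1": "P1", "p2": "P2", "group1": "G",
                                 "group2": "G", "kind": "within"}])
        observed = pd.Series({"P1": 39.0, "P2": 41.0})
        cfg = ProgenySimConfig(n_progeny=300, rng_seed=7)
        r1 = simulate_crosses(mat, lmap, crosses, observed, cfg)
        r2 = simulate_crosses(mat, lmap, crosses, observed, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.iloc[0]["y1"] == 39.0


class TestMapPositions:
    def test_interpolation_from_snp_map(self):
        gmap = pd.DataFrame({"chrom": ["c1", "c1"], "pos": [0, 1000],
                             "cM": [0.0, 10.0]})
        loci = pd.DataFrame({"locus": ["q"], "chrom": ["c1"], "pos": [500]})
        out = locus_map_positions(loci, gmap)
        assert out["cM"].iloc[0] == pytest.approx(5.0)

    def test_unmapped_chromosome_rejected(self):
        gmap = pd.DataFrame({"chrom": ["c1"], "pos": [0], "cM": [0.0]})
        loci = pd.DataFrame({"locus": ["q"], "chrom": ["c9"], "pos": [5]})
        with pytest.raises(ValueError, match="no map"):
            locus_map_positions(loci, gmap)
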