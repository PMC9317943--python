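"""In-silico single-cross simulation and breeding-potential prediction.

Every unordered pair of accessions is a candidate cross.  For each cross,
homozygous progenies are simulated from the parents' QTL alleles under
either a linkage model — crossover counts per chromosome drawn from a
Poisson distribution with the chromosome map length (in Morgans) as the
mean, crossover positions uniform on the genetic map, and the progeny
genome built as a doubled F1 gamete — or an independent model where every
locus segregates freely.  Progeny genotypic values are the model intercept
plus the sum of allele main effects, and each cross is summarised by
percentiles of its progeny-value distribution.  The 95th percentile (P95)
is the cross's recombination-potential score:

    recombination potential  = mean P95 - population mean
    transgressive potential  = max P95 - best observed accession value

and a cross is "superior" when its P95 exceeds the maximum observed value
of its scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import QtlAlleleMatrix

#: the late maturity classes pooled into one "old" group when classifying
#: crosses as within- or between-group
OLD_MG_POOL = ("I", "II", "III")


def mg_group(label: str) -> str:
    """Collapse maturity groups into the cross-design grouping."""
    return "I + II + III" if label in OLD_MG_POOL else str(label)


@dataclass
class ProgenySimConfig:
    """Settings of the progeny simulation.

    ``progeny_model='doubled_gamete'`` doubles a single recombinant F1
    gamete (a doubled-haploid population); ``'ril'`` emulates repeated
    selfing from F2, which inflates effective recombination between
    adjacent loci to R = 2r/(1+2r).
    """

    n_progeny: int = 2000
    model: str = "linkage"            # 'linkage' | 'independent'
    progeny_model: str = "doubled_gamete"  # 'doubled_gamete' | 'ril'
    percentiles: tuple[float, ...] = (90.0, 95.0, 99.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.model not in ("linkage", "independent"):
            raise ValueError("model must be 'linkage' or 'independent'")
        if self.progeny_model not in ("doubled_gamete", "ril"):
            raise ValueError("progeny_model must be 'doubled_gamete' or 'ril'")
        if self.n_progeny < 20:
            warnings.warn("n_progeny < 20: percentile estimates unreliable")


def enumerate_crosses(accessions: list[str], mg_labels: pd.Series,
                      group_filter: set[str] | None = None) -> pd.DataFrame:
    """All unordered parent pairs with their group classification.

    ``group_filter`` restricts the parent pool to the named (collapsed)
    groups.  Returns columns p1, p2, group1, group2, kind
    (within/between).
    """
    groups = {a: mg_group(mg_labels[a]) for a in accessions}
    pool = [a for a in accessions
            if group_filter is None or groups[a] in group_filter]
    if len(pool) < 2:
        raise ValueError("fewer than two accessions after filtering")
    rows = [
        {"p1": a, "p2": b, "group1": groups[a], "group2": groups[b],
         "kind": "within" if groups[a] == groups[b] else "between"}
        for a, b in combinations(pool, 2)
    ]
    return pd.DataFrame(rows)


def locus_map_positions(loci: pd.DataFrame, genetic_map: pd.DataFrame
                        ) -> pd.DataFrame:
    """Interpolate per-locus cM positions from a per-SNP genetic map.

    ``loci`` needs columns locus, chrom, pos (bp); the map needs chrom,
    pos, cM.  Loci on chromosomes absent from the map raise.
    """
    out = []
    by_chrom = {c: g.sort_values("pos") for c, g in genetic_map.groupby("chrom")}
    for _, row in loci.iterrows():
        g = by_chrom.get(row["chrom"])
        if g is None:
            raise ValueError(f"no map for chromosome {row['chrom']}")
        cm = float(np.interp(row["pos"], g["pos"], g["cM"]))
        out.append({"locus": row["locus"], "chrom": row["chrom"], "cM": cm})
    return pd.DataFrame(out)


def _gamete_origins(rng: np.random.Generator, cms: np.ndarray,
                    chrom_len: float, n: int, ril: bool) -> np.ndarray:
    """Parental origin (0/1) at each locus for n gametes on one chromosome.

    Crossover counts are Poisson with mean chrom_len/100 (the map length
    in Morgans); positions are uniform on the map; the gamete alternates
    parental segments from a fair-coin starting phase.  Under the RIL
    model the origins are redrawn as a Markov chain with the inflated
    per-interval recombination R = 2r/(1+2r).
    """
    k = cms.size
    if ril:
        order = np.argsort(cms, kind="stable")
        d = np.diff(cms[order])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        big_r = 2.0 * r / (1.0 + 2.0 * r)
        orig = np.empty((n, k), dtype=np.int8)
        first = rng.integers(0, 2, size=n)
        switches = rng.random((n, k - 1)) < big_r if k > 1 else np.zeros((n, 0), bool)
        path = np.concatenate([first[:, None], switches.astype(np.int8)], axis=1)
        orig[:, order] = np.cumsum(path, axis=1) % 2
        return orig
    # crossover counts in disjoint map intervals are independent Poisson,
    # so the process restricted to the loci is simulated exactly from the
    # interval counts up to each locus (counts distal to the last locus
    # cannot affect any genotype)
    order = np.argsort(cms, kind="stable")
    gaps = np.diff(np.concatenate([[0.0], cms[order]])) / 100.0
    counts = rng.poisson(lam=gaps, size=(n, k))
    phase = rng.integers(0, 2, size=n)
    orig = np.empty((n, k), dtype=np.int8)
    orig[:, order] = (phase[:, None] + counts.cumsum(axis=1)) % 2
    return orig


def simulate_progeny(parent_a: np.ndarray, parent_b: np.ndarray,
                     loci_map: pd.DataFrame, config: ProgenySimConfig,
                     rng: np.random.Generator,
                     chrom_lengths: Mapping[str, float] | None = None
                     ) -> np.ndarray:
    """Progeny allele codes at the detected loci, shape (n_progeny, n_loci).

    Parents are homozygous, so a progeny carries either parent's allele at
    each locus; the linkage model correlates neighbouring loci through the
    shared gamete.
    """
    n_loci = len(parent_a)
    if loci_map.shape[0] != n_loci:
        raise ValueError("one map row per locus required")
    origins = np.empty((config.n_progeny, n_loci), dtype=np.int8)
    if config.model == "independent":
        origins[:] = rng.integers(0, 2, size=origins.shape)
    else:
        if loci_map["cM"].isna().any():
            raise ValueError("every locus needs a cM position under linkage")
        for chrom in loci_map["chrom"].unique():
            idx = np.flatnonzero((loci_map["chrom"] == chrom).to_numpy())
            cms = loci_map["cM"].to_numpy()[idx]
            length = (chrom_lengths[chrom] if chrom_lengths is not None
                      else max(float(cms.max()) + 1.0, 1.0))
            origins[:, idx] = _gamete_origins(
                rng, cms, length, config.n_progeny,
                ril=config.progeny_model == "ril",
            )
    return np.where(origins == 0, parent_a[None, :], parent_b[None, :])


def predict_value(progeny_codes: np.ndarray, matrix: QtlAlleleMatrix
                  ) -> np.ndarray:
    """Genotypic value per progeny: intercept + sum of allele effects."""
    vals = np.full(progeny_codes.shape[0], matrix.intercept)
    for l, locus in enumerate(matrix.locus_ids):
        eff = matrix.allele_effects[locus]
        codes = progeny_codes[:, l]
        if codes.max() >= len(eff):
            raise ValueError(f"unknown allele at {locus}")
        vals = vals + eff[codes]
    return vals


class CrossSimulator:
    """Vectorised progeny simulation over many crosses.

    Precomputes per-locus effect lookups and per-chromosome map layouts
    once, so scoring one cross costs a handful of array operations.  Each
    cross draws from an RNG stream keyed by (seed, sorted parent indices),
    making results independent of enumeration order.
    """

    def __init__(self, matrix: QtlAlleleMatrix, loci_map: pd.DataFrame,
                 config: ProgenySimConfig,
                 chrom_lengths: Mapping[str, float] | None = None):
        self.matrix = matrix
        self.config = config
        loci_map = loci_map.reset_index(drop=True)
        n_loci = len(matrix.locus_ids)
        if len(loci_map) != n_loci:
            raise ValueError("one map row per locus required")
        max_a = max((len(matrix.allele_effects[l]) for l in matrix.locus_ids),
                    default=1)
        self._eff = np.zeros((n_loci, max_a))
        for r, l in enumerate(matrix.locus_ids):
            e = matrix.allele_effects[l]
            self._eff[r, :len(e)] = e
        self._codes = matrix.codes
        self._cm = loci_map["cM"].to_numpy(dtype=float) if n_loci else \
            np.empty(0)
        self._chrom_idx = []
        if config.model == "linkage" and n_loci:
            if np.isnan(self._cm).any():
                raise ValueError("every locus needs a cM position under linkage")
            for chrom, grp in loci_map.groupby("chrom", sort=False):
                idx = grp.index.to_numpy()
                length = (chrom_lengths[chrom] if chrom_lengths is not None
                          else max(float(self._cm[idx].max()) + 1.0, 1.0))
                self._chrom_idx.append((idx, float(length)))

    def progeny_values(self, i1: int, i2: int) -> np.ndarray:
        a, b = sorted((int(i1), int(i2)))
        rng = np.random.default_rng([self.config.rng_seed, a, b])
        n = self.config.n_progeny
        pa = self._codes[:, a]
        pb = self._codes[:, b]
        eff_a = self._eff[np.arange(pa.size), pa] if pa.size else np.empty(0)
        eff_b = self._eff[np.arange(pb.size), pb] if pb.size else np.empty(0)
        seg = pa != pb
        base = self.matrix.intercept + eff_a[~seg].sum()
        if not seg.any():
            return np.full(n, base)
        vals = np.full(n, base + eff_b[seg].sum())
        delta = eff_a - eff_b
        if self.config.model == "independent":
            idx = np.flatnonzero(seg)
            origins = rng.integers(0, 2, size=(n, idx.size))
            return vals + (origins == 0) @ delta[idx]
        ril = self.config.progeny_model == "ril"
        for idx, length in self._chrom_idx:
            sub = idx[seg[idx]]
            if sub.size == 0:
                continue
            origins = _gamete_origins(rng, self._cm[sub], length, n, ril)
            vals = vals + (origins == 0) @ delta[sub]
        return vals

    def score(self, i1: int, i2: int) -> dict[str, float]:
        return _summaries(self.progeny_values(i1, i2),
                          self.config.percentiles)


def _summaries(values: np.ndarray, percentiles) -> dict[str, float]:
    out = {"mean": float(values.mean()), "sd": float(values.std(ddof=1))
           if values.size > 1 else 0.0,
           "min": float(values.min()), "max": float(values.max())}
    # linear interpolation of order statistics: position 1 + (n-1) q
    pcts = np.percentile(values, list(percentiles), method="linear")
    for q, v in zip(percentiles, pcts):
        out[f"p{q:g}"] = float(v)
    return out


def cross_potential(i1: int, i2: int, matrix: QtlAlleleMatrix,
                    loci_map: pd.DataFrame, config: ProgenySimConfig,
                    chrom_lengths: Mapping[str, float] | None = None
                    ) -> dict[str, float]:
    """Progeny-value distribution summary of one cross.

    The RNG stream is derived from (seed, sorted parent indices) so the
    result does not depend on enumeration order.
    """
    sim = CrossSimulator(matrix, loci_map, config, chrom_lengths)
    return sim.score(i1, i2)


def simulate_crosses(matrix: QtlAlleleMatrix, loci_map: pd.DataFrame,
                     crosses: pd.DataFrame, observed: pd.Series,
                     config: ProgenySimConfig,
                     chrom_lengths: Mapping[str, float] | None = None
                     ) -> pd.DataFrame:
    """Score every cross in ``crosses``; returns one record per cross.

    ``observed`` maps accession to its observed trait value (Y1/Y2
    columns of the report).
    """
    index = {a: i for i, a in enumerate(matrix.accessions)}
    sim = CrossSimulator(matrix, loci_map, config, chrom_lengths)
    rows = []
    for rec in crosses.itertuples(index=False):
        s = sim.score(index[rec.p1], index[rec.p2])
        row = {"p1": rec.p1, "p2": rec.p2, "group1": rec.group1,
               "group2": rec.group2, "kind": rec.kind,
               "y1": float(observed[rec.p1]), "y2": float(observed[rec.p2])}
        row.update(s)
        rows.append(row)
    return pd.DataFrame(rows)


def recombination_potential(mean_p95: float, population_mean: float) -> float:
    return mean_p95 - population_mean


def transgressive_potential(max_p95: float, max_observed: float) -> float:
    return max_p95 - max_observed


def summarize_potentials(records: pd.DataFrame, population_mean: float,
                         group_max: Mapping[str, float],
                         score: str = "p95") -> pd.DataFrame:
    """Scope-level summary of cross potentials.

    Scopes: each within-group set, each between-group pair, all within,
    all between, and the entire set.  Per scope: the observed-maximum
    check, cross count, mean/min/max of the percentile score, superior
    crosses (score above the check), and the recombination /
    transgressive potentials.
    """
    if records.empty:
        raise ValueError("no cross records")
    missing = ({*records["group1"], *records["group2"]} - set(group_max))
    if missing:
        raise ValueError(f"missing observed maxima for groups: {missing}")

    overall_max = max(group_max.values())
    scopes: list[tuple[str, pd.DataFrame, float]] = []
    for g in sorted(set(records["group1"]) | set(records["group2"])):
        sub = records[(records["group1"] == g) & (records["group2"] == g)]
        if len(sub):
            scopes.append((g, sub, group_max[g]))
    pairs = records[records["kind"] == "between"]
    for (g1, g2), sub in pairs.groupby(
        pairs.apply(lambda r: tuple(sorted((r["group1"], r["group2"]))), axis=1)
    ):
        scopes.append((f"{g1} vs. {g2}", sub, max(group_max[g1], group_max[g2])))
    scopes.append(("within", records[records["kind"] == "within"], overall_max))
    scopes.append(("between", records[records["kind"] == "between"], overall_max))
    scopes.append(("entire", records, overall_max))

    rows = []
    for name, sub, check in scopes:
        if sub.empty:
            continue
        vals = sub[score]
        rows.append(
            {
                "scope": name, "check_max": check, "n_crosses": len(sub),
                f"mean_{score}": vals.mean(), f"min_{score}": vals.min(),
                f"max_{score}": vals.max(),
                "n_superior": int((vals > check).sum()),
                "recombination_potential": recombination_potential(
                    vals.mean(), population_mean),
                "max_recombination_potential": recombination_potential(
                    vals.max(), population_mean),
                "transgressive_potential": transgressive_potential(
                    vals.max(), check),
            }
        )
    return pd.DataFrame(rows)


def rank_optimal(records: pd.DataFrame, scope: str = "entire",
                 top_k: int = 5, score: str = "p95") -> pd.DataFrame:
    """Top-k crosses of a scope, ranked by the percentile score.

    Ties break by P99, then lexically by parent ids; permutation of the
    input order cannot change the ranking.
    """
    if scope == "entire":
        sub = records
    elif scope in ("within", "between"):
        sub = records[records["kind"] == scope]
    else:
        sub = records[(records["group1"] == scope) & (records["group2"] == scope)]
    cols = ["p1", "p2", "y1", "y2", "mean", "sd", "p90", "p95", "p99"]
    cols = [c for c in cols if c in records.columns]
    sub = sub.sort_values(
        by=[score, "p99", "p1", "p2"] if "p99" in sub.columns
        else [score, "p1", "p2"],
        ascending=[False, False, True, True] if "p99" in sub.columns
        else [False, True, True],
        kind="stable",
    )
    return sub.head(top_k)[cols].reset_index(drop=True)
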