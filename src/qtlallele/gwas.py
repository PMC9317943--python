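"""Restricted two-stage multi-locus association scan on SNPLDB markers.

Stage 1 preselects markers by a single-locus joint F-test of allele main
and allele-by-environment (QEI) terms against a covariate-only model; the
covariates are the top eigenvectors of the genetic similarity coefficient
(GSC) matrix, which absorb population structure.  Stage 2 runs
forward-backward stepwise multi-locus regression over the preselected
markers, entering main-effect and QEI term groups separately, and stops
either when no candidate reaches the entry significance level or when the
next term would push the model's explained phenotypic variance past the
trait heritability — the "restriction" that keeps total QTL contribution
credible.  Allele effects are reported as frequency-weighted zero-mean
deviations, so the model intercept is the population mean and genotypic
values are additive over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import QtlAlleleMatrix, SnpldbSet


@dataclass
class StructureCovariates:
    """GSC matrix with its eigen-decomposition (eigenvalues descending)."""

    gsc: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.eigenvectors[:, :k]


@dataclass
class QtlLocus:
    """One detected locus with its allele system."""

    name: str
    marker_id: str
    chrom: str
    start: int
    end: int
    alleles: list[str]
    frequencies: np.ndarray
    effects: np.ndarray            # centred main effects, one per allele
    qei_effects: np.ndarray | None  # (n_alleles, n_env) or None
    has_main: bool
    has_qei: bool
    r2_main: float
    r2_qei: float
    p_model: float
    p_main: float
    p_qei: float

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class QtlModel:
    """Fitted multi-locus QTL-allele model."""

    loci: list[QtlLocus]
    intercept: float
    total_r2: float
    h2_cap: float
    environments: list[str] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def table(self) -> pd.DataFrame:
        """Per-locus report: allele count, -log10 p, R2 (%) by component."""
        columns = ["qtl", "marker", "chrom", "start", "end", "n_alleles",
                   "neg_log10_p_model", "neg_log10_p_main",
                   "neg_log10_p_qei", "r2_main_pct", "r2_qei_pct"]
        rows = []
        for l in self.loci:
            rows.append(
                {
                    "qtl": l.name, "marker": l.marker_id, "chrom": l.chrom,
                    "start": l.start, "end": l.end, "n_alleles": l.n_alleles,
                    "neg_log10_p_model": -np.log10(max(l.p_model, 1e-300)),
                    "neg_log10_p_main": (-np.log10(max(l.p_main, 1e-300))
                                         if l.has_main else np.nan),
                    "neg_log10_p_qei": (-np.log10(max(l.p_qei, 1e-300))
                                        if l.has_qei else np.nan),
                    "r2_main_pct": 100 * l.r2_main,
                    "r2_qei_pct": 100 * l.r2_qei,
                }
            )
        return pd.DataFrame(rows, columns=columns)


def env_means(records: pd.DataFrame) -> pd.DataFrame:
    """Accession x environment phenotype means from plot-level records."""
    return records.groupby(["accession", "environment"], as_index=False)[
        "value"
    ].mean()


def compute_gsc(snpldbs: SnpldbSet) -> StructureCovariates:
    """Genetic similarity coefficients: the fraction of markers at which
    two accessions carry the same SNPLDB allele."""
    codes = snpldbs.code_matrix()
    if codes.shape[0] < 1 or codes.shape[1] < 2:
        raise ValueError("need >= 1 marker and >= 2 accessions")
    n = codes.shape[1]
    gsc = np.zeros((n, n))
    for chunk in np.array_split(codes, max(1, codes.shape[0] // 256)):
        gsc += (chunk[:, :, None] == chunk[:, None, :]).sum(axis=0)
    gsc /= codes.shape[0]
    lam, vec = np.linalg.eigh(gsc)
    order = np.argsort(lam)[::-1]
    return StructureCovariates(gsc, lam[order], vec[:, order])


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank via least squares."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    return float(np.sum((y - X @ beta) ** 2)), int(rank)


class RtmGwas(BaseEstimator):
    """Restricted two-stage multi-locus GWAS estimator.

    Parameters
    ----------
    alpha1
        Significance level of the stage-1 single-locus preselection.
    alpha2
        Entry/stay level of the stage-2 stepwise regression.
    n_eigenvectors
        GSC eigenvectors used as structure covariates.
    h2_cap
        Upper bound (fraction) on the model's total explained phenotypic
        variance; when None it must be supplied to :meth:`fit`.
    include_qei
        Whether allele-by-environment terms are candidate effects.
    qei_pool
        'all' retests QEI terms of every preselected marker even if its
        main effect never enters; 'main_only' restricts QEI candidates to
        markers whose main effect is already in the model.

    Attributes (after fit)
    ----------------------
    model_ : QtlModel
    preselection_ : pd.DataFrame  (stage-1 marker, F, p, selected flag)
    covariates_ : StructureCovariates
    """

    def __init__(self, alpha1: float = 0.05, alpha2: float = 0.01,
                 n_eigenvectors: int = 10, h2_cap: float | None = None,
                 include_qei: bool = True, qei_pool: str = "all",
                 max_loci: int = 200):
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_eigenvectors = n_eigenvectors
        self.h2_cap = h2_cap
        self.include_qei = include_qei
        self.qei_pool = qei_pool
        self.max_loci = max_loci

    # -- design-matrix helpers -------------------------------------------

    def _prepare(self, snpldbs: SnpldbSet, means: pd.DataFrame):
        accs = list(snpldbs.accessions)
        envs = sorted(means["environment"].unique())
        wide = means.pivot(index="accession", columns="environment",
                           values="value").reindex(accs)
        if wide.isna().any().any():
            raise ValueError("phenotype means missing for some accessions")
        n, nt = len(accs), len(envs)
        y = wide[envs].to_numpy().T.reshape(-1)  # env-major rows
        self._n, self._nt = n, nt
        self._envs = envs
        self._y = y
        self._ss_tot = float(np.sum((y - y.mean()) ** 2))
        cov = self.covariates_.top(min(self.n_eigenvectors, n))
        base = [np.ones((nt * n, 1))]
        for i in range(1, nt):
            col = np.zeros((nt, n)); col[i] = 1
            base.append(col.reshape(-1, 1))
        base.append(np.tile(cov, (nt, 1)))
        self._X0 = np.hstack(base)
        self._env_dummies = np.vstack(
            [np.repeat((np.arange(nt) == i).astype(float), n) for i in
             range(1, nt)]
        ).T if nt > 1 else np.zeros((nt * n, 0))

    def _main_cols(self, m) -> np.ndarray:
        """Allele indicator columns (reference = most frequent allele)."""
        a = m.n_alleles
        if a < 2:
            return np.zeros((self._nt * self._n, 0))
        dummies = np.zeros((self._n, a - 1))
        for j in range(1, a):
            dummies[m.codes == j, j - 1] = 1.0
        return np.tile(dummies, (self._nt, 1))

    def _qei_cols(self, m) -> np.ndarray:
        main = self._main_cols(m)
        if main.shape[1] == 0 or self._env_dummies.shape[1] == 0:
            return np.zeros((self._nt * self._n, 0))
        return np.hstack(
            [main * self._env_dummies[:, [e]]
             for e in range(self._env_dummies.shape[1])]
        )

    # -- stages ----------------------------------------------------------

    def stage1(self, snpldbs: SnpldbSet) -> pd.DataFrame:
        """Single-locus joint F-test (main + QEI) per marker."""
        rss0, rank0 = _rss(self._X0, self._y)
        n_obs = self._y.size
        rows = []
        for m in snpldbs.markers:
            cols = [self._main_cols(m)]
            if self.include_qei:
                cols.append(self._qei_cols(m))
            X = np.hstack([self._X0] + cols)
            rss1, rank1 = _rss(X, self._y)
            df1 = rank1 - rank0
            df2 = n_obs - rank1
            if df1 <= 0 or df2 <= 0:
                warnings.warn(f"marker {m.id} collinear with covariates; skipped")
                rows.append({"marker": m.id, "F": np.nan, "p": np.nan,
                             "selected": False})
                continue
            F = ((rss0 - rss1) / df1) / (rss1 / df2)
            p = float(stats.f.sf(F, df1, df2))
            rows.append({"marker": m.id, "F": float(F), "p": p,
                         "selected": p <= self.alpha1})
        return pd.DataFrame(rows)

    def _partial_f(self, X_base, rss_base, rank_base, cols):
        X = np.hstack([X_base, cols])
        rss1, rank1 = _rss(X, self._y)
        df1 = rank1 - rank_base
        df2 = self._y.size - rank1
        if df1 <= 0 or df2 <= 0:
            return np.nan, np.nan, rss1, rank1
        F = ((rss_base - rss1) / df1) / (rss1 / df2)
        return float(F), float(stats.f.sf(F, df1, df2)), rss1, rank1

    def stage2(self, snpldbs: SnpldbSet, preselected: list[int],
               h2_cap: float) -> list[tuple[str, int]]:
        """Forward-backward stepwise selection of (kind, marker index) terms.

        Returns the selected term groups in entry order.  The forward step
        refuses any term that would lift total model R2 above ``h2_cap``
        and stops there.
        """
        markers = snpldbs.markers
        coord = {i: (markers[i].chrom, markers[i].start) for i in preselected}
        cand: list[tuple[str, int]] = [("main", i) for i in preselected]
        if self.include_qei and self.qei_pool == "all":
            cand += [("qei", i) for i in preselected]
        col_of = {}
        for kind, i in set(cand) | {("qei", i) for i in preselected}:
            col_of[(kind, i)] = (self._main_cols(markers[i]) if kind == "main"
                                 else self._qei_cols(markers[i]))

        selected: list[tuple[str, int]] = []
        rss_cov, _ = _rss(self._X0, self._y)

        def model_X(terms):
            return np.hstack([self._X0] + [col_of[t] for t in terms]) \
                if terms else self._X0

        while len(selected) < self.max_loci:
            X_cur = model_X(selected)
            rss_cur, rank_cur = _rss(X_cur, self._y)
            pool = [t for t in cand if t not in selected]
            if self.include_qei and self.qei_pool == "main_only":
                pool += [("qei", i) for kind, i in selected if kind == "main"
                         and ("qei", i) not in selected]
            best = None
            for t in pool:
                if col_of[t].shape[1] == 0:
                    continue
                F, p, rss1, _ = self._partial_f(X_cur, rss_cur, rank_cur,
                                                col_of[t])
                if not np.isfinite(F):
                    continue
                key = (p, -F, coord[t[1]])
                if p <= self.alpha2 and (best is None or key < best[0]):
                    best = (key, t, rss1)
            if best is None:
                break
            _, term, rss_new = best
            r2_new = (rss_cov - rss_new) / self._ss_tot
            if r2_new > h2_cap:
                break
            selected.append(term)
            assert (rss_cov - rss_new) / self._ss_tot <= h2_cap + 1e-12
            # backward elimination at the stay level
            changed = True
            while changed and len(selected) > 1:
                changed = False
                worst = None
                for t in selected:
                    others = [u for u in selected if u != t]
                    X_o = model_X(others)
                    rss_o, rank_o = _rss(X_o, self._y)
                    F, p, _, _ = self._partial_f(X_o, rss_o, rank_o, col_of[t])
                    if np.isfinite(p) and p > self.alpha2 and (
                        worst is None or p > worst[0]
                    ):
                        worst = (p, t)
                if worst is not None:
                    selected.remove(worst[1])
                    changed = True
        return selected

    # -- fitting ---------------------------------------------------------

    def fit(self, snpldbs: SnpldbSet, phenotype_means: pd.DataFrame,
            h2_cap: float | None = None) -> "RtmGwas":
        """Run both stages and assemble the QTL-allele model.

        ``phenotype_means`` holds accession x environment means (columns
        accession, environment, value); plot-level records may be passed
        and are averaged.
        """
        means = env_means(phenotype_means)
        cap = h2_cap if h2_cap is not None else self.h2_cap
        if cap is None:
            cap = 1.0
        if not 0 <= cap <= 1:
            raise ValueError("h2_cap must lie in [0, 1]")
        self.covariates_ = compute_gsc(snpldbs)
        self._prepare(snpldbs, means)

        scan = self.stage1(snpldbs)
        self.preselection_ = scan
        pre = [i for i, sel in enumerate(scan["selected"]) if sel]
        terms = self.stage2(snpldbs, pre, cap) if pre else []
        self.model_ = self._finalize(snpldbs, terms, cap)
        return self

    def _finalize(self, snpldbs: SnpldbSet, terms: list[tuple[str, int]],
                  cap: float) -> QtlModel:
        markers = snpldbs.markers
        loci_idx = sorted({i for _, i in terms},
                          key=lambda i: (markers[i].chrom, markers[i].start))
        col_of = {t: (self._main_cols(markers[t[1]]) if t[0] == "main"
                      else self._qei_cols(markers[t[1]])) for t in terms}
        X_full = np.hstack([self._X0] + [col_of[t] for t in terms]) \
            if terms else self._X0
        beta = np.linalg.pinv(X_full) @ self._y
        rss_full, rank_full = _rss(X_full, self._y)
        rss_cov, _ = _rss(self._X0, self._y)
        total_r2 = (rss_cov - rss_full) / self._ss_tot if terms else 0.0

        # sequential SS in selection order (telescoping to the joint delta)
        seq_ss: dict[tuple[str, int], float] = {}
        prev_rss = rss_cov
        X_seq = self._X0
        for t in terms:
            X_seq = np.hstack([X_seq, col_of[t]])
            rss_t, _ = _rss(X_seq, self._y)
            seq_ss[t] = prev_rss - rss_t
            prev_rss = rss_t
        seq_total = sum(seq_ss.values())
        scale = ((rss_cov - rss_full) / seq_total) if seq_total > 0 else 0.0

        # per-term coefficient slices of the joint fit
        offs = self._X0.shape[1]
        coef_of = {}
        for t in terms:
            w = col_of[t].shape[1]
            coef_of[t] = beta[offs:offs + w]
            offs += w

        nt = self._nt
        loci = []
        for q, i in enumerate(loci_idx):
            m = markers[i]
            has_main = ("main", i) in terms
            has_qei = ("qei", i) in terms
            a = m.n_alleles
            raw = np.zeros(a)
            if has_main:
                raw[1:] = coef_of[("main", i)]
            eff = raw - m.frequencies @ raw
            qei = None
            if has_qei:
                qc = coef_of[("qei", i)].reshape(nt - 1, a - 1)
                qei = np.zeros((a, nt))
                qei[1:, 1:] = qc.T
                qei -= (m.frequencies @ qei)  # centre per environment
            p_main = p_qei = np.nan
            own = [t for t in terms if t[1] == i]
            X_wo, rss_wo, rank_wo = self._drop_fit(terms, own, col_of)
            own_cols = np.hstack([col_of[t] for t in own])
            _, p_model, _, _ = self._partial_f(X_wo, rss_wo, rank_wo, own_cols)
            if has_main:
                X_o, rss_o, rank_o = self._drop_fit(terms, [("main", i)], col_of)
                _, p_main, _, _ = self._partial_f(X_o, rss_o, rank_o,
                                                  col_of[("main", i)])
            if has_qei:
                X_o, rss_o, rank_o = self._drop_fit(terms, [("qei", i)], col_of)
                _, p_qei, _, _ = self._partial_f(X_o, rss_o, rank_o,
                                                 col_of[("qei", i)])
            loci.append(
                QtlLocus(
                    name=f"q{m.chrom}-{sum(1 for j in loci_idx[:q + 1] if markers[j].chrom == m.chrom)}",
                    marker_id=m.id, chrom=m.chrom, start=m.start, end=m.end,
                    alleles=list(m.haplotypes),
                    frequencies=m.frequencies.copy(), effects=eff,
                    qei_effects=qei, has_main=has_main, has_qei=has_qei,
                    r2_main=scale * seq_ss.get(("main", i), 0.0) / self._ss_tot,
                    r2_qei=scale * seq_ss.get(("qei", i), 0.0) / self._ss_tot,
                    p_model=p_model, p_main=p_main, p_qei=p_qei,
                )
            )
        intercept = float(self._y.mean())
        return QtlModel(loci=loci, intercept=intercept,
                        total_r2=float(total_r2), h2_cap=cap,
                        environments=list(self._envs))

    def _drop_fit(self, terms, dropped, col_of):
        keep = [t for t in terms if t not in dropped]
        X = np.hstack([self._X0] + [col_of[t] for t in keep]) if keep \
            else self._X0
        rss, rank = _rss(X, self._y)
        return X, rss, rank

    def predict(self, snpldbs: SnpldbSet) -> np.ndarray:
        """Predicted genotypic value per accession (intercept + allele
        effects summed over detected loci)."""
        matrix = build_matrix(self.model_, snpldbs)
        return matrix.predicted_values()


def stage1_scan(snpldbs: SnpldbSet, phenotype_means: pd.DataFrame,
                alpha: float = 0.05, n_eigenvectors: int = 10,
                include_qei: bool = True) -> pd.DataFrame:
    g = RtmGwas(alpha1=alpha, n_eigenvectors=n_eigenvectors,
                include_qei=include_qei)
    g.covariates_ = compute_gsc(snpldbs)
    g._prepare(snpldbs, env_means(phenotype_means))
    return g.stage1(snpldbs)


def classify_contribution(model: QtlModel, threshold_pct: float = 1.0
                          ) -> pd.DataFrame:
    """Label main-effect loci LC (R2 >= threshold) or SC (below)."""
    rows = []
    for l in model.loci:
        if not l.has_main:
            continue
        r2 = 100 * l.r2_main
        rows.append({"qtl": l.name, "r2_main_pct": r2,
                     "n_alleles": l.n_alleles,
                     "class": "LC" if r2 >= threshold_pct else "SC"})
    return pd.DataFrame(rows, columns=["qtl", "r2_main_pct", "n_alleles",
                                       "class"])


def build_matrix(model: QtlModel, snpldbs: SnpldbSet) -> QtlAlleleMatrix:
    """QTL-allele matrix: per-locus allele main effect carried by each
    accession, plus the companion allele-code matrix."""
    by_id = {m.id: m for m in snpldbs.markers}
    effects = np.zeros((model.n_loci, len(snpldbs.accessions)))
    codes = np.zeros_like(effects, dtype=np.int32)
    allele_effects = {}
    for r, l in enumerate(model.loci):
        m = by_id.get(l.marker_id)
        if m is None:
            raise KeyError(f"marker {l.marker_id} absent from SNPLDB set")
        if m.codes.max() >= len(l.effects):
            raise ValueError(f"accession carries unknown allele at {l.name}")
        codes[r] = m.codes
        effects[r] = l.effects[m.codes]
        allele_effects[l.name] = l.effects
    return QtlAlleleMatrix(
        [l.name for l in model.loci], list(snpldbs.accessions), effects,
        codes, model.intercept, allele_effects,
    )
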