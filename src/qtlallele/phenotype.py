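"""Multi-environment phenotype analysis.

The trial model is a joint randomized block design over environments,

    y_ijk = mu + t_i + r_j(i) + g_k + (gt)_ik + e_ijk,

with environment ``t``, replication-within-environment ``r``, genotype
``g``, genotype-by-environment interaction ``gt`` and Gaussian error.
Variance components for genotype, GxE and error feed the entry-mean
heritabilities

    h2       = sg2 / (sg2 + s2/nr)                       (single environment)
    h2       = sg2 / (sg2 + sgt2/nt + s2/(nt*nr))        (multi-environment)
    h2_gei   = (sgt2/nt) / (sg2 + sgt2/nt + s2/(nt*nr))

and the genetic coefficient of variation GCV = 100 * sg / mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_gt2: float
    sigma_e2: float
    n_env: int
    n_rep: int
    grand_mean: float
    method: str = "reml"

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_gt2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")


class UnbalancedDesignWarning(UserWarning):
    pass


def _balanced_cube(records: pd.DataFrame):
    """Return y[env, rep, genotype] or None when the design is unbalanced."""
    piv = records.pivot_table(
        index=["environment", "replication"], columns="accession",
        values="value", aggfunc="count"
    )
    if piv.isna().any().any() or not (piv == 1).all().all():
        return None
    wide = records.pivot_table(
        index=["environment", "replication"], columns="accession", values="value"
    )
    envs = wide.index.get_level_values(0).unique()
    reps = wide.index.get_level_values(1).unique()
    y = wide.to_numpy().reshape(len(envs), len(reps), wide.shape[1])
    return y, list(envs), list(reps), list(wide.columns)


def _cell_mean_records(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Collapse to accession x environment cell means; harmonic-mean reps."""
    counts = records.groupby(["accession", "environment"])["value"].count()
    nr_eff = len(counts) / (1.0 / counts).sum()
    means = records.groupby(["accession", "environment"], as_index=False)[
        "value"
    ].mean()
    means["replication"] = 1
    return means, float(nr_eff)


def fit_joint_anova(records: pd.DataFrame) -> pd.DataFrame:
    """ANOVA table of the joint randomized block design.

    Genotype is tested against the GxE mean square and GxE against error,
    matching the expected mean squares when genotype and GxE are random.
    Requires >= 2 environments and replications; an unbalanced design
    triggers a warning and the analysis proceeds on cell means.
    """
    cube = _balanced_cube(records)
    if cube is None:
        warnings.warn(
            "unbalanced design: proceeding on accession x environment cell means",
            UnbalancedDesignWarning,
        )
        means, nr_eff = _cell_mean_records(records)
        cube = _balanced_cube(means)
        if cube is None:
            raise ValueError("cell means still unbalanced: missing cells")
    y, envs, reps, genos = cube
    nt, nr, ng = y.shape
    if nt < 2:
        raise ValueError("need >= 2 environments")
    grand = y.mean()
    m_env = y.mean(axis=(1, 2))
    m_rep = y.mean(axis=2)
    m_gen = y.mean(axis=(0, 1))
    m_ge = y.mean(axis=1)

    ss_env = nr * ng * np.sum((m_env - grand) ** 2)
    ss_rep = ng * np.sum((m_rep - m_env[:, None]) ** 2)
    ss_gen = nt * nr * np.sum((m_gen - grand) ** 2)
    ss_ge = nr * np.sum((m_ge - m_env[:, None] - m_gen[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_env - ss_rep - ss_gen - ss_ge

    df_env = nt - 1
    df_rep = nt * (nr - 1)
    df_gen = ng - 1
    df_ge = (nt - 1) * (ng - 1)
    df_tot = nt * nr * ng - 1
    df_err = df_tot - df_env - df_rep - df_gen - df_ge

    rows = []

    def _row(src, ss, df, ms_denom=None, df_denom=None):
        ms = ss / df if df > 0 else np.nan
        if ms_denom is not None and ms_denom > 0 and df > 0:
            f = ms / ms_denom
            p = stats.f.sf(f, df, df_denom)
        else:
            f, p = np.nan, np.nan
        rows.append({"source": src, "df": df, "ss": ss, "ms": ms, "F": f, "p": p})
        return ms

    ms_err = ss_err / df_err if df_err > 0 else np.nan
    ms_ge = ss_ge / df_ge
    ms_rep = ss_rep / df_rep if df_rep > 0 else np.nan
    _row("environment", ss_env, df_env, ms_rep, df_rep)
    _row("replication(environment)", ss_rep, df_rep, ms_err, df_err)
    _row("genotype", ss_gen, df_gen, ms_ge, df_ge)
    _row("genotype_x_environment", ss_ge, df_ge, ms_err, df_err)
    _row("error", ss_err, df_err)
    _row("total", ss_tot, df_tot)
    return pd.DataFrame(rows)


def _reml(y: np.ndarray, start: np.ndarray) -> np.ndarray | None:
    """REML for the balanced cube y[env, rep, genotype].

    The marginal covariance is block-diagonal by genotype with identical
    blocks V = s2*I + sg2*J + sgt2*kron(I_nt, J_nr) over the (env, rep)
    cells, so the restricted likelihood is computed from one block's
    eigendecomposition.  Fixed effects: intercept, environment and
    replication-within-environment.
    """
    nt, nr, ng = y.shape
    m = nt * nr
    # fixed-effect design over the m cells (same for every genotype)
    X = [np.ones(m)]
    for i in range(1, nt):
        col = np.zeros((nt, nr)); col[i] = 1
        X.append(col.ravel())
    for i in range(nt):
        for j in range(1, nr):
            col = np.zeros((nt, nr)); col[i, j] = 1
            X.append(col.ravel())
    X = np.column_stack(X)
    p = X.shape[1]
    J_full = np.ones((m, m))
    J_env = np.kron(np.eye(nt), np.ones((nr, nr)))
    Y = y.reshape(m, ng)

    def neg_reml(theta):
        sg2, sgt2, s2 = theta
        V = s2 * np.eye(m) + sg2 * J_full + sgt2 * J_env
        try:
            lam, Q = np.linalg.eigh(V)
        except np.linalg.LinAlgError:
            return np.inf
        if lam.min() <= 1e-12:
            return np.inf
        Vi = (Q / lam) @ Q.T
        # fixed-effect design is tiled over genotype blocks: accumulate
        XtViX = ng * (X.T @ Vi @ X)
        xty = (X.T @ Vi @ Y).sum(axis=1)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        quad = np.sum(Y * (Vi @ Y)) - xty @ np.linalg.solve(XtViX, xty)
        return 0.5 * (ng * np.log(lam).sum() + logdet_xvx + quad)

    x0 = np.maximum(start, 1e-6)
    res = optimize.minimize(
        neg_reml, x0, method="Nelder-Mead",
        bounds=[(0.0, None), (0.0, None), (1e-12, None)],
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 5000},
    )
    if not res.success or not np.isfinite(res.fun):
        return None
    return res.x


def estimate_variance_components(
    records: pd.DataFrame, method: str = "reml"
) -> VarianceComponents:
    """Genotype / GxE / error variance components.

    ``method='reml'`` (default) maximizes the restricted likelihood with
    genotype and GxE random; ``'moments'`` solves the balanced
    expected-mean-square equations.  Negative estimates are truncated at
    zero; REML non-convergence falls back to the moment solution with a
    warning.
    """
    cube = _balanced_cube(records)
    nr_eff = None
    if cube is None:
        warnings.warn(
            "unbalanced design: variance components from cell means with "
            "harmonic-mean replication", UnbalancedDesignWarning,
        )
        means, nr_eff = _cell_mean_records(records)
        cube = _balanced_cube(means)
    y, envs, reps, genos = cube
    nt, nr, ng = y.shape

    table = fit_joint_anova(records).set_index("source")
    ms_g = table.loc["genotype", "ms"]
    ms_ge = table.loc["genotype_x_environment", "ms"]
    ms_err = table.loc["error", "ms"]
    nr_use = nr_eff if nr_eff is not None else nr
    if not np.isfinite(ms_err):  # single replication: error confounded with GxE
        ms_err = 0.0
    s2 = max(ms_err, 0.0)
    sgt2 = max((ms_ge - ms_err) / nr_use, 0.0)
    sg2 = max((ms_g - ms_ge) / (nt * nr_use), 0.0)
    used = "moments"

    if method == "reml" and nr_eff is None and nr >= 2:
        est = _reml(y, np.array([sg2, sgt2, s2]))
        if est is None:
            warnings.warn("REML did not converge; method-of-moments estimates used")
        else:
            sg2, sgt2, s2 = (max(v, 0.0) for v in est)
            used = "reml"

    return VarianceComponents(
        sigma_g2=float(sg2), sigma_gt2=float(sgt2), sigma_e2=float(s2),
        n_env=int(nt), n_rep=int(round(nr_use)),
        grand_mean=float(records["value"].mean()), method=used,
    )


def heritability(vc: VarianceComponents, scope: str = "multi") -> float:
    """Entry-mean heritability, single- or multi-environment."""
    if vc.sigma_g2 == vc.sigma_gt2 == vc.sigma_e2 == 0:
        raise ValueError("heritability undefined: all variance components zero")
    if scope == "single":
        denom = vc.sigma_g2 + vc.sigma_e2 / vc.n_rep
    elif scope == "multi":
        denom = vc.sigma_g2 + vc.sigma_gt2 / vc.n_env + vc.sigma_e2 / (
            vc.n_env * vc.n_rep
        )
    else:
        raise ValueError("scope must be 'single' or 'multi'")
    return float(vc.sigma_g2 / denom)


def gei_heritability(vc: VarianceComponents) -> float:
    """GxE share of the entry-mean phenotypic variance."""
    denom = vc.sigma_g2 + vc.sigma_gt2 / vc.n_env + vc.sigma_e2 / (
        vc.n_env * vc.n_rep
    )
    if denom == 0:
        raise ValueError("undefined: all variance components zero")
    return float((vc.sigma_gt2 / vc.n_env) / denom)


def gcv(vc: VarianceComponents) -> float:
    """Genetic coefficient of variation in percent: 100 * sigma_g / mean."""
    if vc.grand_mean <= 0:
        raise ValueError("GCV requires a positive grand mean")
    return float(100.0 * np.sqrt(vc.sigma_g2) / vc.grand_mean)


def _lsd_letters(means: pd.Series, ns: pd.Series, mse: float, df_err: int,
                 alpha: float = 0.05) -> pd.Series:
    """Compact letter display from pairwise Fisher-LSD comparisons."""
    order = means.sort_values(ascending=False).index.tolist()
    tcrit = stats.t.ppf(1 - alpha / 2, df_err) if df_err > 0 else np.inf

    def differ(a, b):
        lsd = tcrit * np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        return abs(means[a] - means[b]) > lsd

    runs = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not any(
            differ(order[p], order[j + 1]) for p in range(i, j + 1)
        ):
            j += 1
        if not runs or runs[-1][1] < j:
            runs.append((i, j))
    letters = {g: "" for g in order}
    for r, (i, j) in enumerate(runs):
        ch = chr(ord("a") + r)
        for g in order[i:j + 1]:
            letters[g] += ch
    return pd.Series(letters)


def summarize_by_mg(records: pd.DataFrame, mg_labels: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-maturity-group descriptive table with 1%-wide frequency bins.

    Accession means (over environments and replications) are binned at
    integer-centred 1-unit bins; mean-separation letters come from
    Fisher's LSD on a one-way ANOVA of accession means across groups.
    """
    acc_means = records.groupby("accession")["value"].mean()
    unknown = acc_means.index.difference(mg_labels.index)
    if len(unknown):
        raise ValueError(f"accessions without MG label: {list(unknown)[:5]}")
    mg = mg_labels.loc[acc_means.index]
    groups = [g for g in mg_labels.unique() if g in set(mg)]

    samples = {g: acc_means[mg == g] for g in groups}
    ns = pd.Series({g: len(s) for g, s in samples.items()})
    gm = pd.Series({g: s.mean() for g, s in samples.items()})
    n_total = int(ns.sum())
    if len(groups) > 1 and n_total > len(groups):
        sse = sum(((s - s.mean()) ** 2).sum() for s in samples.values())
        df_err = n_total - len(groups)
        letters = _lsd_letters(gm, ns, sse / df_err, df_err, alpha)
    else:
        letters = pd.Series({g: "a" for g in groups})

    centers = range(int(np.floor(acc_means.min() + 0.5)),
                    int(np.floor(acc_means.max() + 0.5)) + 1)
    rows = []
    for g in groups:
        s = samples[g]
        binned = np.floor(s + 0.5).astype(int)
        row = {"mg": g, "n": len(s), "mean": s.mean(), "min": s.min(),
               "max": s.max(), "letter": letters[g]}
        for c in centers:
            row[f"bin_{c}"] = int((binned == c).sum())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("mg")
    assert out["n"].sum() == len(acc_means)
    return out
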