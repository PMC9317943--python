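"""Allele bookkeeping between subpopulation groups.

Given the QTL-allele matrix restricted to an "old" and a "new" group of
accessions (e.g. late versus early maturity groups), alleles at each locus
are classified as inherited (present in both), emerged (new only) or
excluded (old only), split by the sign of their estimated effect.
Fractions use the group totals the categories refer to: inherited and
emerged over the new group's allele total, excluded over the old group's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import QtlAlleleMatrix


@dataclass
class SignedCount:
    negative: int
    positive: int

    @property
    def total(self) -> int:
        return self.negative + self.positive

    def __str__(self) -> str:  # "total (neg, pos)" presentation
        return f"{self.total} ({self.negative}, {self.positive})"


@dataclass
class AlleleChangeSummary:
    """Inherited / emerged / excluded allele counts between two groups."""

    old_group: str
    new_group: str
    total_old: SignedCount
    total_new: SignedCount
    inherited: SignedCount
    emerged: SignedCount
    excluded: SignedCount
    n_qtl_inherited: int
    n_qtl_emerged: int
    n_qtl_excluded: int

    @property
    def inherited_fraction(self) -> float:
        """Share of the new group's alleles that were inherited."""
        return self.inherited.total / self.total_new.total

    @property
    def emerged_fraction(self) -> float:
        return self.emerged.total / self.total_new.total

    @property
    def excluded_fraction(self) -> float:
        """Share of the old group's alleles that were lost."""
        return self.excluded.total / self.total_old.total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, cnt, frac in [
            ("total_old", self.total_old, None),
            ("total_new", self.total_new, None),
            ("inherited", self.inherited, self.inherited_fraction),
            ("emerged", self.emerged, self.emerged_fraction),
            ("excluded", self.excluded, self.excluded_fraction),
        ]:
            rows.append({"category": cat, "total": cnt.total,
                         "negative": cnt.negative, "positive": cnt.positive,
                         "fraction": frac})
        return pd.DataFrame(rows)


def allele_presence(matrix: QtlAlleleMatrix) -> dict[str, dict[int, float]]:
    """Alleles carried by >= 1 accession per locus, mapped to their effect.

    The input is normally a group-restricted view of the population matrix
    (see :meth:`QtlAlleleMatrix.subset`).  Returns
    ``{locus: {allele_code: effect}}``.
    """
    if len(matrix.accessions) == 0:
        raise ValueError("empty accession group")
    out: dict[str, dict[int, float]] = {}
    for r, locus in enumerate(matrix.locus_ids):
        effects = matrix.allele_effects.get(locus)
        present = np.unique(matrix.codes[r])
        if effects is None:
            effects = {c: float(matrix.effects[r][matrix.codes[r] == c][0])
                       for c in present}
            out[locus] = effects
        else:
            out[locus] = {int(c): float(effects[c]) for c in present}
    return out


def _sign_split(items) -> SignedCount:
    """Effect >= 0 counts as positive (deterministic zero-tie rule)."""
    neg = sum(1 for e in items if e < 0)
    return SignedCount(negative=neg, positive=len(items) - neg)


def compare_groups(
    old_presence: dict[str, dict[int, float]],
    new_presence: dict[str, dict[int, float]],
    old_name: str = "old",
    new_name: str = "new",
) -> AlleleChangeSummary:
    """Classify alleles into inherited / emerged / excluded between groups."""
    if set(old_presence) != set(new_presence):
        raise ValueError("old and new groups cover different locus sets")
    tot_old, tot_new, inh, eme, exc = [], [], [], [], []
    q_inh = q_eme = q_exc = 0
    for locus in old_presence:
        old = old_presence[locus]
        new = new_presence[locus]
        inherited = set(old) & set(new)
        emerged = set(new) - set(old)
        excluded = set(old) - set(new)
        assert inherited | emerged == set(new)
        assert inherited | excluded == set(old)
        tot_old += [old[a] for a in old]
        tot_new += [new[a] for a in new]
        inh += [new[a] for a in inherited]
        eme += [new[a] for a in emerged]
        exc += [old[a] for a in excluded]
        q_inh += bool(inherited)
        q_eme += bool(emerged)
        q_exc += bool(excluded)
    return AlleleChangeSummary(
        old_group=old_name, new_group=new_name,
        total_old=_sign_split(tot_old), total_new=_sign_split(tot_new),
        inherited=_sign_split(inh), emerged=_sign_split(eme),
        excluded=_sign_split(exc),
        n_qtl_inherited=q_inh, n_qtl_emerged=q_eme, n_qtl_excluded=q_exc,
    )


def compare_mg_groups(
    matrix: QtlAlleleMatrix,
    mg_labels: pd.Series,
    old_groups: tuple[str, ...] = ("III", "II", "I"),
    new_groups: tuple[str, ...] = ("0", "00", "000"),
    min_count: int = 1,
) -> AlleleChangeSummary:
    """Old-vs-new maturity-group allele change on a population matrix.

    ``min_count`` raises the carrier threshold for calling an allele
    present in a group (default 1: literal presence).
    """
    labels = mg_labels.reindex(matrix.accessions)
    old_mask = labels.isin(old_groups).to_numpy()
    new_mask = labels.isin(new_groups).to_numpy()

    def presence(mask):
        sub = matrix.subset(mask)
        pres = allele_presence(sub)
        if min_count > 1:
            for r, locus in enumerate(sub.locus_ids):
                counts = pd.Series(sub.codes[r]).value_counts()
                pres[locus] = {a: e for a, e in pres[locus].items()
                               if counts.get(a, 0) >= min_count}
        return pres

    return compare_groups(
        presence(old_mask), presence(new_mask),
        old_name="+".join(old_groups), new_name="+".join(new_groups),
    )
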