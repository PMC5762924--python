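"""Trait-source merging, dataset filtering and trait-trait association.

Trait assignments for metabarcoding MOTUs are compiled from several
literature databases of unequal age; newer compilations generally cover,
update and correct older ones, so sources are merged with a
most-recent-first precedence rule. The analysis dataset is then restricted
to MOTUs with at least ``min_reads`` total reads that are defined for all
five traits, and samples left empty by those removals are dropped.
Pairwise association between categorical traits is summarised by Cramer's
V with a chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import TRAITS, TRAIT_LEVELS, ValidationError, check_nm_consistency

__all__ = ["CramerResult", "FilterReport", "merge_trait_sources", "filter_dataset", "cramers_v", "cramers_v_matrix"]


@dataclass
class CramerResult:
    """Cramer's V association between two categorical traits."""

    v: float
    chi2: float
    df: int
    p: float
    n: int
    table: pd.DataFrame = field(repr=False, default=None)


@dataclass
class FilterReport:
    """Counts of what :func:`filter_dataset` removed."""

    motus_removed_rare: int = 0
    motus_removed_undefined: int = 0
    reads_removed: int = 0
    samples_removed_empty: int = 0
    warnings: list = field(default_factory=list)


def merge_trait_sources(sources: list[pd.DataFrame], motus: list | None = None) -> pd.DataFrame:
    """Merge partial trait tables with most-recent-first precedence.

    ``sources`` is ordered most recent first; each MOTU/trait cell takes the
    value from the first source that defines it (anything other than
    ``"undefined"``/missing); remaining gaps become ``"undefined"``. The NM
    type <=> status invariant is enforced on the merged table.

    Parameters
    ----------
    sources
        Partial trait tables indexed by motu_id. Columns are any subset of
        the five traits.
    motus
        Optional explicit MOTU universe; defaults to the union of source
        indices.
    """
    if motus is None:
        ids: list = []
        seen = set()
        for src in sources:
            for m in src.index:
                if m not in seen:
                    seen.add(m)
                    ids.append(m)
        motus = ids
    merged = pd.DataFrame("undefined", index=pd.Index(motus, name="motu_id"), columns=list(TRAITS))
    for src in sources:
        for t in TRAITS:
            if t not in src.columns:
                continue
            col = src[t].reindex(merged.index)
            defined = col.notna() & (col.astype(str).str.strip() != "") & (col != "undefined")
            take = defined & (merged[t] == "undefined")
            merged.loc[take, t] = col[take]
    for t in TRAITS:
        bad = ~merged[t].isin(TRAIT_LEVELS[t])
        if bad.any():
            raise ValidationError(
                f"unknown level {merged.loc[bad, t].iloc[0]!r} for trait {t!r} "
                f"(motu {merged.index[bad][0]!r})"
            )
    check_nm_consistency(merged)
    return merged


def filter_dataset(
    rm: pd.DataFrame,
    tt: pd.DataFrame,
    min_reads: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the rare-MOTU, trait-completeness and empty-sample filters.

    Order: MOTUs with fewer than ``min_reads`` total reads are dropped
    first, then MOTUs undefined for any of the five traits, then samples
    with zero remaining reads. An empty result is reported via a warning in
    the :class:`FilterReport`, never an exception.
    """
    unknown = set(rm.columns) - set(tt.index)
    if unknown:
        raise ValidationError(f"MOTUs missing from trait table: {sorted(unknown)}")
    report = FilterReport()

    totals = rm.sum(axis=0)
    rare = totals < min_reads
    report.motus_removed_rare = int(rare.sum())
    report.reads_removed += int(totals[rare].sum())
    rm = rm.loc[:, ~rare]

    tt_sub = tt.loc[rm.columns]
    undef = (tt_sub[list(TRAITS)] == "undefined").any(axis=1)
    report.motus_removed_undefined = int(undef.sum())
    report.reads_removed += int(rm.loc[:, undef.to_numpy()].to_numpy().sum())
    rm = rm.loc[:, (~undef).to_numpy()]

    empty = rm.sum(axis=1) == 0
    report.samples_removed_empty = int(empty.sum())
    rm = rm.loc[~empty]

    tt_out = tt.loc[rm.columns].copy()
    if rm.shape[0] == 0 or rm.shape[1] == 0:
        report.warnings.append("filtering removed every sample or MOTU")
    return rm, tt_out, report


def cramers_v(
    tt: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    drop_undefined: bool = True,
) -> CramerResult:
    """Cramer's V between two traits of a trait table.

    Pearson chi-square without continuity correction on the contingency
    table of defined levels; ``V = sqrt(chi2 / (n * (min(r, c) - 1)))``,
    with p from the chi-square distribution on ``(r-1)(c-1)`` df.
    """
    sub = tt[[trait_a, trait_b]].copy()
    if drop_undefined:
        sub = sub[(sub[trait_a] != "undefined") & (sub[trait_b] != "undefined")]
    table = pd.crosstab(sub[trait_a], sub[trait_b])
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    r, c = table.shape
    if r < 2 or c < 2:
        deg = trait_a if r < 2 else trait_b
        raise ValidationError(f"trait {deg!r} has fewer than 2 observed levels")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return CramerResult(v=v, chi2=float(chi2), df=int(df), p=float(p), n=n, table=table)


def cramers_v_matrix(tt: pd.DataFrame, traits: tuple[str, ...] = TRAITS) -> pd.DataFrame:
    """All-pairs association matrix: V in the upper triangle, p in the lower.

    Pairs involving a trait with a single observed level stay NaN.
    """
    k = len(traits)
    out = pd.DataFrame(np.nan, index=list(traits), columns=list(traits))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                res = cramers_v(tt, traits[i], traits[j])
            except ValidationError:
                continue
            out.iloc[i, j] = res.v
            out.iloc[j, i] = res.p
    return out
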