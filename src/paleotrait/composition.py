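"""Per-sample and per-period mutualist-trait composition with bootstrap CIs.

For each sample the share of every trait category is computed in two
weightings: by reads (the community-weighted mean — category reads over
total sample reads) and by MOTUs (category presences over total presences).
Period-level composition is the unweighted mean of per-sample shares within
each climatic period, and uncertainty is quantified by a stratified
bootstrap that resamples samples with replacement within periods, taking
the 2.5/97.5 percentiles of the replicate distribution as the 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import PERIODS, TRAIT_LEVELS, ValidationError

__all__ = ["BootstrapCI", "sample_trait_shares", "period_trait_shares", "bootstrap_ci", "composition_table"]


def _categories(trait: str) -> list[str]:
    return [lv for lv in TRAIT_LEVELS[trait] if lv != "undefined"]


def sample_trait_shares(
    rm: pd.DataFrame,
    tt: pd.DataFrame,
    trait: str,
    weighting: str = "reads",
) -> pd.DataFrame:
    """Per-sample category shares for one trait.

    ``weighting="reads"``: category share = category read total / sample
    read total. ``weighting="motus"``: share of present MOTUs (reads > 0)
    in the category. Requires a filtered dataset (no undefined levels, no
    empty samples).

    Returns a samples x categories DataFrame whose rows sum to 1.
    """
    if weighting not in ("reads", "motus"):
        raise ValueError(f"weighting must be 'reads' or 'motus', got {weighting!r}")
    cats = _categories(trait)
    levels = tt.loc[rm.columns, trait]
    if (levels == "undefined").any():
        bad = levels.index[levels == "undefined"].tolist()
        raise ValidationError(f"undefined {trait!r} for MOTUs {bad}; filter first")
    x = rm.to_numpy(dtype=float)
    if weighting == "motus":
        x = (x > 0).astype(float)
    row_tot = x.sum(axis=1)
    if (row_tot == 0).any():
        empty = rm.index[row_tot == 0].tolist()
        raise ValidationError(f"samples with zero reads {empty}; filter first")
    ind = np.stack([(levels == c).to_numpy(dtype=float) for c in cats], axis=1)
    shares = (x @ ind) / row_tot[:, None]
    return pd.DataFrame(shares, index=rm.index, columns=cats)


def period_trait_shares(shares: pd.DataFrame, st: pd.DataFrame) -> pd.DataFrame:
    """Period composition: mean of per-sample shares, renormalised to 1.

    ``shares`` is the output of :func:`sample_trait_shares`; ``st`` maps
    sample ids to periods. Only periods present in ``st`` appear.
    """
    period = st.set_index("sample_id")["period"].reindex(shares.index)
    if period.isna().any():
        raise ValidationError(f"samples missing from sample table: {shares.index[period.isna()].tolist()}")
    out = shares.groupby(period.to_numpy()).mean()
    out = out.div(out.sum(axis=1), axis=0)
    order = [p for p in PERIODS if p in out.index]
    return out.loc[order]


@dataclass
class BootstrapCI:
    """Stratified-bootstrap percentile CIs for period trait shares."""

    point: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    B: int
    level: float = 0.95
    degenerate_periods: list = field(default_factory=list)


def bootstrap_ci(
    shares: pd.DataFrame,
    st: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapCI:
    """Stratified bootstrap CI for period-level shares.

    Each replicate resamples sample ids with replacement *within* each
    climatic period and recomputes :func:`period_trait_shares`; the CI is
    the (1-level)/2 and 1-(1-level)/2 percentiles (linear interpolation).
    Periods with a single sample yield width-0 intervals and are flagged.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    period = st.set_index("sample_id")["period"].reindex(shares.index)
    point = period_trait_shares(shares, st)
    periods = list(point.index)
    x = shares.to_numpy()
    reps = {p: np.empty((B, shares.shape[1])) for p in periods}
    degenerate = []
    for p in periods:
        idx = np.flatnonzero((period == p).to_numpy())
        if len(idx) == 1:
            degenerate.append(p)
        draws = rng.integers(0, len(idx), size=(B, len(idx)))
        boot = x[idx][draws]                  # B x n_p x k
        m = boot.mean(axis=1)
        reps[p] = m / m.sum(axis=1, keepdims=True)
    alpha = (1 - level) / 2
    lower = pd.DataFrame(
        {p: np.percentile(reps[p], 100 * alpha, axis=0) for p in periods},
        index=shares.columns,
    ).T
    upper = pd.DataFrame(
        {p: np.percentile(reps[p], 100 * (1 - alpha), axis=0) for p in periods},
        index=shares.columns,
    ).T
    return BootstrapCI(point=point, lower=lower, upper=upper, B=B, level=level,
                       degenerate_periods=degenerate)


def composition_table(
    rm: pd.DataFrame,
    tt: pd.DataFrame,
    st: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format period composition for all traits and both weightings.

    Columns: period, trait, weighting, category, point, lo, hi.
    """
    rows = []
    for trait in TRAIT_LEVELS:
        for weighting in ("reads", "motus"):
            shares = sample_trait_shares(rm, tt, trait, weighting)
            ci = bootstrap_ci(shares, st, B=B, seed=seed)
            for p in ci.point.index:
                for cat in ci.point.columns:
                    rows.append({
                        "period": p, "trait": trait, "weighting": weighting,
                        "category": cat,
                        "point": ci.point.loc[p, cat],
                        "lo": ci.lower.loc[p, cat],
                        "hi": ci.upper.loc[p, cat],
                    })
    return pd.DataFrame(rows)
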