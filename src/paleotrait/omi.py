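"""Outlying-mean-index (OMI) niche ordination and trait-on-niche models.

OMI positions each MOTU in an environmental space — here the space spanned
by standardized climatic-period indicator variables — at its
abundance-weighted mean environmental position (its *marginality*). The
squared length of that marginality vector is the species' OMI; the species'
total inertia decomposes exactly into OMI + tolerance (variance along the
marginality direction) + residual tolerance. Ordination axes are the
eigenvectors of the abundance-weighted covariance of marginalities, so the
eigenvalue sum equals the weighted mean OMI. A Monte-Carlo test permutes
the sample-to-environment assignment to ask whether the observed mean OMI
exceeds chance; Euclidean-distance PERMANOVA on the species axis scores
then asks which traits predict niche position, and Dunn's rank-based test
compares trait categories axis by axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import PERIODS, TRAITS, ValidationError
from .permanova import PermanovaResult, euclidean_distance, permanova

__all__ = [
    "OMIResult",
    "DunnResult",
    "period_env_table",
    "omi_from_env",
    "omi_analysis",
    "omi_randtest",
    "trait_niche_models",
    "dunn_test",
]


@dataclass
class OMIResult:
    """Niche ordination result.

    ``species_scores`` are marginality vectors projected on the ordination
    axes; ``stats`` holds the per-MOTU omi/tol/rtol decomposition and the
    abundance weight ``u`` (row total over grand total).
    """

    eigenvalues: np.ndarray
    species_scores: pd.DataFrame
    stats: pd.DataFrame             # omi, tol, rtol, inertia, weight
    mean_omi: float
    axes: np.ndarray | None = None  # env-space eigenvectors (columns)
    env: pd.DataFrame | None = None
    rand_p: float | None = None
    n_perm: int | None = None


def period_env_table(periods: pd.Series) -> pd.DataFrame:
    """Standardized all-level dummy environment table for the period factor.

    One indicator column per period present, centred and scaled to unit
    variance with uniform sample weights 1/n (population scaling).
    """
    levels = [p for p in PERIODS if p in set(periods)] or list(pd.unique(periods))
    if len(levels) < 2:
        raise ValidationError("need >= 2 periods for the environment table")
    cols = {}
    n = len(periods)
    for lv in levels:
        z = (periods == lv).to_numpy(dtype=float)
        z = z - z.mean()
        sd = np.sqrt((z**2).mean())
        cols[lv] = z / sd
    return pd.DataFrame(cols, index=periods.index)


def omi_from_env(rm: pd.DataFrame, Z: pd.DataFrame) -> OMIResult:
    """OMI decomposition of a read matrix against an environment table.

    ``Z`` must already be centred/standardized with uniform sample weights.
    Species profiles are ``p_ij = y_ij / y_i+``; marginality
    ``m_i = sum_j p_ij z_j``; ``omi_i = |m_i|^2``; tolerance is the
    profile-weighted variance of projections onto the marginality
    direction; residual tolerance closes the inertia identity. Ordination
    axes are eigenvectors of ``M' U M`` with ``U = diag(y_i+ / y_++)``.
    """
    y = rm.to_numpy(dtype=float).T          # species x samples
    if (y.sum(axis=1) == 0).any():
        bad = rm.columns[y.sum(axis=1) == 0].tolist()
        raise ValidationError(f"MOTUs with zero total reads {bad}; filter first")
    z = Z.to_numpy(dtype=float)             # samples x k
    P = y / y.sum(axis=1, keepdims=True)    # profiles, rows sum to 1
    M = P @ z                               # species x k marginalities
    omi = (M**2).sum(axis=1)
    # projections of each sample's environment on each species' direction
    norm = np.sqrt(omi)
    tol = np.zeros_like(omi)
    nz = norm > 0
    E = np.zeros_like(M)
    E[nz] = M[nz] / norm[nz, None]
    proj = E @ z.T                          # species x samples
    tol = (P * (proj - norm[:, None]) ** 2).sum(axis=1)
    inertia = (P * (z**2).sum(axis=1)[None, :]).sum(axis=1)
    rtol = inertia - omi - tol
    u = y.sum(axis=1) / y.sum()
    C = M.T @ (u[:, None] * M)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    scores = M @ evecs
    score_df = pd.DataFrame(scores, index=rm.columns,
                            columns=[f"axis{i+1}" for i in range(scores.shape[1])])
    st = pd.DataFrame({"omi": omi, "tol": tol, "rtol": rtol,
                       "inertia": inertia, "weight": u}, index=rm.columns)
    return OMIResult(
        eigenvalues=evals, species_scores=score_df, stats=st,
        mean_omi=float((u * omi).sum()), axes=evecs, env=Z,
    )


def _orient_axes(res: OMIResult, periods: pd.Series) -> OMIResult:
    """Fix axis signs: axis 1 negative at the post-LGM sample centroid,
    axis 2 negative at the LGM centroid (when those periods are present)."""
    z = res.env.to_numpy()
    sample_scores = z @ res.axes            # samples x k
    targets = ["post-LGM", "LGM"]
    for ax, target in enumerate(targets):
        if ax >= res.axes.shape[1] or target not in set(periods):
            continue
        centroid = sample_scores[(periods == target).to_numpy(), ax].mean()
        if centroid > 0:
            res.axes[:, ax] *= -1
            sample_scores[:, ax] *= -1
            res.species_scores.iloc[:, ax] *= -1
    return res


def omi_analysis(rm: pd.DataFrame, periods: pd.Series) -> OMIResult:
    """OMI ordination of MOTU abundance against the climatic-period factor.

    ``periods`` is aligned to the rows of ``rm``. The environment table is
    the standardized all-level period dummy matrix; axis signs follow the
    convention that the post-LGM centroid is negative on axis 1 and the LGM
    centroid negative on axis 2.
    """
    periods = periods.loc[rm.index] if set(rm.index) <= set(periods.index) else periods
    Z = period_env_table(periods)
    res = omi_from_env(rm, Z)
    return _orient_axes(res, periods)


def omi_randtest(
    rm: pd.DataFrame,
    periods: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo test of the abundance-weighted mean OMI.

    Each permutation applies one global random permutation to the
    sample-to-environment assignment (rows of the environment table) and
    recomputes the weighted mean OMI; ``p = (#{perm >= obs} + 1) /
    (n_perm + 1)``. Returns (observed mean OMI, p, permutation values).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    periods = periods.loc[rm.index] if set(rm.index) <= set(periods.index) else periods
    Z = period_env_table(periods).to_numpy()
    y = rm.to_numpy(dtype=float).T
    P = y / y.sum(axis=1, keepdims=True)
    u = y.sum(axis=1) / y.sum()

    def mean_omi(z: np.ndarray) -> float:
        M = P @ z
        return float((u * (M**2).sum(axis=1)).sum())

    obs = mean_omi(Z)
    rng = np.random.default_rng(seed)
    perm_vals = np.empty(n_perm)
    for b in range(n_perm):
        perm_vals[b] = mean_omi(Z[rng.permutation(Z.shape[0])])
    p = (np.sum(perm_vals >= obs - 1e-12) + 1) / (n_perm + 1)
    return obs, float(p), perm_vals


#: Mutualist traits (growth form is the structural covariate, not a mutualism).
MUTUALIST_TRAITS = ("myc_type", "myc_status", "n_fix", "pollination")
#: The two partially confounded mycorrhizal traits are never co-entered.
_CONFOUNDED = {"myc_type": "myc_status", "myc_status": "myc_type"}


def _covariates_for(focal: str) -> list[str]:
    """Non-confounded mutualist covariates for model (iii)."""
    excluded = {focal, _CONFOUNDED.get(focal, "")}
    covs = []
    for t in MUTUALIST_TRAITS:
        if t in excluded:
            continue
        # of the mycorrhizal pair, status is the covariate of record
        if t == "myc_type" and "myc_status" not in excluded:
            continue
        covs.append(t)
    return covs


def trait_niche_models(
    scores: pd.DataFrame,
    tt: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
) -> dict[str, dict[str, PermanovaResult]]:
    """Euclidean-distance PERMANOVA of niche scores on traits, three ways.

    For each trait: (i) alone; for mutualist traits additionally (ii) after
    growth form and (iii) after growth form plus the non-confounded
    mutualist traits, with the focal trait entered last (sequential SS).
    Mycorrhizal type and status are never entered into the same model.
    Aliased terms are dropped by :func:`permanova` with an error naming
    them; callers see that error as a warning entry in the result dict.
    """
    X = scores.iloc[:, :n_axes]
    d = euclidean_distance(X)
    tt = tt.loc[scores.index]
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, PermanovaResult]] = {}
    for trait in TRAITS:
        models: dict[str, PermanovaResult] = {}
        models["univariate"] = permanova(
            d, tt[[trait]], [trait], n_perm=n_perm, seed=int(rng.integers(2**31)))
        if trait in MUTUALIST_TRAITS:
            models["after_growth_form"] = permanova(
                d, tt[["growth_form", trait]], ["growth_form", trait],
                n_perm=n_perm, seed=int(rng.integers(2**31)), on_aliased="zero")
            covs = _covariates_for(trait)
            terms = ["growth_form", *covs, trait]
            models["after_growth_form_and_traits"] = permanova(
                d, tt[terms], terms, n_perm=n_perm, seed=int(rng.integers(2**31)),
                on_aliased="zero")
        out[trait] = models
    return out


@dataclass
class DunnResult:
    """Dunn's rank-based multiple-comparison test."""

    pairwise: pd.DataFrame          # catA, catB, z, p, p_adjusted
    kw_statistic: float
    tie_correction: float


def dunn_test(values: pd.Series, groups: pd.Series, adjust: str = "none") -> DunnResult:
    """Dunn's test on one score axis across trait categories.

    Pooled mid-ranks; ``z_ab = (Rbar_a - Rbar_b) /
    sqrt((N(N+1)/12 - T)(1/n_a + 1/n_b))`` with tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values.
    """
    groups = groups.loc[values.index] if set(values.index) <= set(groups.index) else groups
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    N = len(v)
    ranks = stats.rankdata(v)
    _, counts = np.unique(v, return_counts=True)
    T = float(((counts**3 - counts).sum()) / (12 * (N - 1)))
    var_base = N * (N + 1) / 12 - T
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ra, rb = ranks[g == a], ranks[g == b]
        denom = var_base * (1 / len(ra) + 1 / len(rb))
        if denom <= 0:          # all values tied
            z = 0.0
        else:
            z = (ra.mean() - rb.mean()) / np.sqrt(denom)
        p = float(np.clip(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
        rows.append({"catA": a, "catB": b, "z": z, "p": p})
    pw = pd.DataFrame(rows)
    if adjust == "holm":
        from .permanova import _holm
        pw["p_adjusted"] = _holm(pw["p"].to_numpy())
    else:
        pw["p_adjusted"] = pw["p"]
    if len(counts) == 1:        # every value tied: no rank variation at all
        kw = 0.0
    else:
        kw = stats.kruskal(*[v[g == lv] for lv in levels]).statistic
    return DunnResult(pairwise=pw, kw_statistic=float(kw), tie_correction=T)
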