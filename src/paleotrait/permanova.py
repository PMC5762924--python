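"""Permutational multivariate ANOVA on distance matrices.

Implements the adonis-style partition: squared distances are
Gower-double-centred into an inner-product matrix G, and sequential
(Type-I) sums of squares for an ordered series of model terms are obtained
from nested hat matrices, ``SS_k = tr(H_k G) - tr(H_{k-1} G)``. The
pseudo-F for each term is tested by freely permuting observations
(equivalently, jointly relabelling the rows and columns of the distance
matrix). Pairwise one-factor contrasts with a compact letter display are
provided for factor terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import ValidationError

__all__ = [
    "PermanovaResult",
    "bray_curtis",
    "euclidean_distance",
    "gower_center",
    "permanova",
    "pairwise_permanova",
    "compact_letters",
    "residual_distances",
]


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus optional pairwise contrasts."""

    terms: pd.DataFrame          # name, df, SS, pseudo_F, R2, p
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    seed: int | None = None
    pairwise: pd.DataFrame | None = None
    letters: dict | None = None

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("name").loc[name]


def bray_curtis(rm: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance between sample rows of an abundance table.

    ``d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)``.
    """
    x = np.asarray(rm, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    zero = x.sum(axis=1) == 0
    if zero.any():
        labels = list(rm.index[zero]) if isinstance(rm, pd.DataFrame) else list(np.flatnonzero(zero))
        raise ValidationError(f"all-zero rows for samples {labels}")
    d = squareform(pdist(x, metric="braycurtis"))
    idx = rm.index if isinstance(rm, pd.DataFrame) else pd.RangeIndex(len(x))
    return pd.DataFrame(d, index=idx, columns=idx)


def euclidean_distance(x: pd.DataFrame) -> pd.DataFrame:
    d = squareform(pdist(np.asarray(x, dtype=float), metric="euclidean"))
    idx = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(len(d))
    return pd.DataFrame(d, index=idx, columns=idx)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower double-centring: ``G = C (-1/2 D*D) C`` with ``C = I - 11'/n``."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d * d
    n = d.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _design_matrices(design: pd.DataFrame, terms: list[str],
                     on_aliased: str = "error") -> tuple[list[np.ndarray], list[int], list[str]]:
    """Cumulative design matrices (intercept first) and per-term df.

    ``on_aliased="error"`` raises on a term adding no rank;
    ``on_aliased="zero"`` keeps it with df = 0 (zero SS) and a warning.
    """
    n = len(design)
    X = np.ones((n, 1))
    mats = [X]
    dfs: list[int] = []
    kept: list[str] = []
    rank_prev = 1
    for name in terms:
        col = design[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = pd.unique(col)
            if len(levels) < 2:
                raise ValidationError(f"factor {name!r} has fewer than 2 levels")
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        else:
            dummies = col.to_numpy(dtype=float)[:, None]
        X = np.hstack([mats[-1], dummies])
        rank = np.linalg.matrix_rank(X)
        df = rank - rank_prev
        if df == 0:
            if on_aliased == "error":
                raise ValidationError(f"term {name!r} is aliased with earlier terms")
            warnings.warn(f"term {name!r} is aliased with earlier terms; df = 0")
            X = mats[-1]
        rank_prev = rank
        mats.append(X)
        dfs.append(df)
        kept.append(name)
    return mats, dfs, kept


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(
    d: pd.DataFrame,
    design: pd.DataFrame | pd.Series,
    terms: list[str] | None = None,
    n_perm: int | str = 999,
    seed: int | None = None,
    on_aliased: str = "error",
) -> PermanovaResult:
    """Sequential PERMANOVA of a distance matrix on an ordered term list.

    Parameters
    ----------
    d
        Square symmetric distance matrix (DataFrame labelled by sample).
    design
        Per-sample covariate table aligned to ``d`` (a bare Series is
        treated as a single factor named after the Series or ``"factor"``).
    terms
        Ordered model terms (column names of ``design``); defaults to all
        columns in order. Sums of squares are sequential in this order.
    n_perm
        Number of free permutations, or ``"exact"`` to enumerate all n!
        permutations (n <= 9).

    p-values are ``(#{permuted F >= observed} + 1) / (n_perm + 1)``, with
    ties counted as >= (conservative).
    """
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "factor")
    if terms is None:
        terms = list(design.columns)
    labels = d.index
    if not labels.equals(d.columns):
        raise ValidationError("distance matrix rows/columns disagree")
    design = design.loc[labels] if set(labels) <= set(design.index) else design
    if len(design) != len(labels):
        raise ValidationError("design and distance matrix are not aligned")

    dmat = d.to_numpy(dtype=float)
    n = dmat.shape[0]
    G = gower_center(dmat)
    total_ss = float(np.trace(G))

    mats, dfs, names = _design_matrices(design.reset_index(drop=True), terms, on_aliased)
    hats = [_hat(X) for X in mats]  # hats[0] is the intercept-only hat
    df_model_total = sum(dfs)
    residual_df = n - 1 - df_model_total
    if residual_df <= 0:
        raise ValidationError("no residual degrees of freedom")
    df_arr = np.array(dfs, dtype=float)
    testable = df_arr > 0

    def seq_ss(Gp: np.ndarray) -> np.ndarray:
        tr = np.array([float(np.sum(H * Gp)) for H in hats])
        return np.diff(tr)

    ss = seq_ss(G)
    resid_ss = total_ss - float(np.sum(hats[-1] * G))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(testable, (ss / np.where(testable, df_arr, 1.0)) / (resid_ss / residual_df), np.nan)

    if n_perm == "exact":
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        perms = list(itertools.permutations(range(n)))[1:]
        counts = np.zeros(len(ss))
        for p in perms:
            idx = np.array(p)
            Gp = G[np.ix_(idx, idx)]
            ssp = seq_ss(Gp)
            rssp = total_ss - float(np.sum(hats[-1] * Gp))
            with np.errstate(divide="ignore", invalid="ignore"):
                Fp = (ssp / np.where(testable, df_arr, 1.0)) / (rssp / residual_df)
            counts += np.where(testable, Fp >= F - 1e-12, 0)
        pvals = np.where(testable, (counts + 1) / (len(perms) + 1), np.nan)
        n_perm_eff = len(perms)
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(len(ss))
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            ssp = seq_ss(Gp)
            rssp = total_ss - float(np.sum(hats[-1] * Gp))
            with np.errstate(divide="ignore", invalid="ignore"):
                Fp = (ssp / np.where(testable, df_arr, 1.0)) / (rssp / residual_df)
            counts += np.where(testable, Fp >= F - 1e-12, 0)
        pvals = np.where(testable, (counts + 1) / (int(n_perm) + 1), np.nan)
        n_perm_eff = int(n_perm)

    table = pd.DataFrame({
        "name": names,
        "df": dfs,
        "SS": ss,
        "pseudo_F": F,
        "R2": ss / total_ss,
        "p": pvals,
    })
    return PermanovaResult(
        terms=table, residual_df=residual_df, residual_ss=resid_ss,
        total_ss=total_ss, n_perm=n_perm_eff, seed=seed,
    )


def pairwise_permanova(
    d: pd.DataFrame,
    factor: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> tuple[pd.DataFrame, dict]:
    """All level pairs of ``factor`` tested on subset distance matrices.

    Returns the pairwise table (groupA, groupB, R2, p, p_adjusted) and a
    compact letter display in which levels whose pairwise adjusted p >=
    ``alpha`` share a letter. Levels with fewer than 2 samples are skipped
    with a warning.
    """
    factor = factor.loc[d.index] if set(d.index) <= set(factor.index) else factor
    levels = list(pd.unique(factor))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(levels, 2):
        mask = factor.isin([a, b]).to_numpy()
        if (factor == a).sum() < 2 or (factor == b).sum() < 2:
            warnings.warn(f"level pair ({a}, {b}) skipped: fewer than 2 samples in a level")
            continue
        sub = d.loc[mask, mask]
        subf = factor[mask].reset_index(drop=True).rename("group")
        res = permanova(sub, subf, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append({
            "groupA": a, "groupB": b,
            "R2": float(res.terms["R2"].iloc[0]),
            "p": float(res.terms["p"].iloc[0]),
        })
    pw = pd.DataFrame(rows)
    if len(pw):
        if adjust == "holm":
            pw["p_adjusted"] = _holm(pw["p"].to_numpy())
        elif adjust == "none":
            pw["p_adjusted"] = pw["p"]
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    letters = compact_letters(levels, pw, alpha=alpha)
    return pw, letters


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def compact_letters(levels: list, pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from pairwise p-values.

    Levels connected by a non-significant contrast (adjusted p >= alpha)
    share at least one letter; maximal cliques of the "not different" graph
    define the letter groups.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    if len(pairwise):
        pcol = "p_adjusted" if "p_adjusted" in pairwise.columns else "p"
        for _, row in pairwise.iterrows():
            if row[pcol] >= alpha:
                g.add_edge(row["groupA"], row["groupB"])
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(levels.index(x) for x in c))
    letters: dict = {lv: "" for lv in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lv in clique:
            letters[lv] += ch
    return {lv: "".join(sorted(set(s))) for lv, s in letters.items()}


def residual_distances(d: pd.DataFrame, design: pd.DataFrame | pd.Series,
                       terms: list[str] | None = None) -> pd.DataFrame:
    """Pairwise distances of the residual after projecting out model terms.

    The Gower matrix G of ``d`` is projected onto the orthocomplement of
    the design's hat matrix, ``R = (I-H) G (I-H)``; residual squared
    distances are re-expressed as ``R_ii + R_jj - 2 R_ij`` (clipped at 0).
    This is the distance-based-redundancy-analysis residual matrix used for
    the spatial correlograms.
    """
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "factor")
    if terms is None:
        terms = list(design.columns)
    design = design.loc[d.index] if set(d.index) <= set(design.index) else design
    G = gower_center(d.to_numpy(dtype=float))
    mats, _, _ = _design_matrices(design.reset_index(drop=True), terms)
    H = _hat(mats[-1])
    n = G.shape[0]
    Q = np.eye(n) - H
    R = Q @ G @ Q
    diag = np.diag(R)
    d2 = np.clip(diag[:, None] + diag[None, :] - 2 * R, 0, None)
    np.fill_diagonal(d2, 0.0)
    return pd.DataFrame(np.sqrt(d2), index=d.index, columns=d.columns)


def oneway_f_permutations(G: np.ndarray, groups: np.ndarray, n_perm: int,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Fast one-way pseudo-F and permutation p from a precomputed G.

    Used by the simulation helpers; identical statistic to
    :func:`permanova` with a single factor term.
    """
    n = G.shape[0]
    levels, inv = np.unique(groups, return_inverse=True)
    k = len(levels)
    total = float(np.trace(G))

    def f_of(perm_inv: np.ndarray) -> float:
        # tr(H G) for the factor + intercept hat equals sum over groups of
        # mean of the within-group block of G.
        s = 0.0
        for g in range(k):
            idx = np.flatnonzero(perm_inv == g)
            s += G[np.ix_(idx, idx)].sum() / len(idx)
        between = s - G.sum() / n
        within = total - s
        return (between / (k - 1)) / (within / (n - k))

    f_obs = f_of(inv)
    count = 0
    for _ in range(n_perm):
        count += f_of(rng.permutation(inv)) >= f_obs - 1e-12
    return f_obs, (count + 1) / (n_perm + 1)
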