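"""Grafting MOTUs onto a backbone supertree and PGLS with Pagel's lambda.

Metabarcoding MOTUs often correspond to species groups rather than single
species. Each MOTU is therefore represented on the phylogeny either by
relabelling the backbone tip of its single component species, or by
attaching a new terminal branch at the node of the lowest taxonomic rank
(genus, tribe, subfamily, family) containing all its component taxa; the
pendant branch length equals the attachment node's height so the grafted
tree stays ultrametric. Backbone species that do not represent a MOTU are
pruned afterwards.

Trait-niche relationships on the resulting tree are modelled by
generalized least squares in which the phylogenetic covariance is scaled
by Pagel's lambda (off-diagonal shared branch lengths multiplied by
lambda), with lambda co-estimated by maximum likelihood on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .io_core import ValidationError

__all__ = [
    "GraftReport",
    "PGLSResult",
    "read_newick",
    "write_newick",
    "node_heights",
    "tree_height",
    "is_ultrametric",
    "phylo_covariance",
    "graft_motus",
    "pgls_lambda",
    "category_niche_means",
]

RANKS = ("genus", "tribe", "subfamily", "family")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def node_heights(tree: dendropy.Tree) -> dict:
    """Height (max distance to a descendant leaf) of every node."""
    heights: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = max(
                heights[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return heights


def tree_height(tree: dendropy.Tree) -> float:
    return node_heights(tree)[tree.seed_node]


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    return max(depths) - min(depths) <= tol


@dataclass
class GraftReport:
    relabelled: list = field(default_factory=list)
    grafted: dict = field(default_factory=dict)      # motu -> rank used
    unplaceable: list = field(default_factory=list)
    pruned: int = 0


def _lowest_containing_rank(members: list, taxonomy: pd.DataFrame) -> tuple[str, str] | None:
    """Lowest rank whose value is shared by every member taxon."""
    known = [m for m in members if m in taxonomy.index]
    if len(known) != len(members) or not known:
        return None
    for rank in RANKS:
        vals = taxonomy.loc[known, rank].dropna().unique()
        if len(vals) == 1 and len(taxonomy.loc[known, rank].dropna()) == len(known):
            return rank, vals[0]
    return None


def graft_motus(
    backbone: dendropy.Tree,
    taxonomy: pd.DataFrame,
    motu_defs: dict[str, list[str]],
) -> tuple[dendropy.Tree, GraftReport]:
    """Place MOTUs on a backbone species tree and prune redundant species.

    Parameters
    ----------
    backbone
        Ultrametric species-level tree; tip labels are species names.
    taxonomy
        Species-indexed table with columns genus, tribe, subfamily, family.
    motu_defs
        MOTU id -> list of component species names.

    Single-species MOTUs whose species is a backbone tip are relabelled in
    place; multi-species MOTUs gain a new tip at the MRCA of the backbone
    members of the lowest containing rank (the node's parent when the MRCA
    is itself a leaf), with pendant length equal to that node's height.
    MOTUs with no resolvable containing rank are listed as unplaceable,
    never silently dropped.
    """
    tree = backbone.clone(depth=1)
    tree.is_rooted = True
    report = GraftReport()
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    heights = node_heights(tree)

    relabel: list[tuple[str, object]] = []
    attach: list[tuple[str, object]] = []
    for motu, members in motu_defs.items():
        members = list(members)
        if len(members) == 1 and members[0] in leaves:
            relabel.append((motu, leaves[members[0]]))
            continue
        found = _lowest_containing_rank(members, taxonomy)
        if found is None:
            report.unplaceable.append(motu)
            continue
        rank, value = found
        rank_species = [s for s in taxonomy.index[taxonomy[rank] == value] if s in leaves]
        if not rank_species:
            report.unplaceable.append(motu)
            continue
        if len(rank_species) == 1:
            node = leaves[rank_species[0]].parent_node
        else:
            node = tree.mrca(taxa=[leaves[s].taxon for s in rank_species])
        attach.append((motu, node))
        report.grafted[motu] = rank

    ns = tree.taxon_namespace
    for motu, node in attach:
        taxon = dendropy.Taxon(label=motu)
        ns.add_taxon(taxon)
        node.new_child(taxon=taxon, edge_length=heights[node])
    for motu, leaf in relabel:
        leaf.taxon.label = motu
        report.relabelled.append(motu)

    keep = set(report.relabelled) | set(report.grafted)
    drop = [leaf.taxon for leaf in tree.leaf_node_iter() if leaf.taxon.label not in keep]
    report.pruned = len(drop)
    if drop:
        tree.prune_taxa(drop, suppress_unifurcations=True)
    return tree, report


def phylo_covariance(tree: dendropy.Tree, labels: list | None = None) -> pd.DataFrame:
    """Brownian covariance matrix: C_ij = root distance of the MRCA of i, j."""
    leaves = list(tree.leaf_node_iter())
    order = {leaf.taxon.label: k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    depth: dict = {tree.seed_node: 0.0}
    tips_below: dict = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [order[node.taxon.label]]
            C[tips_below[node][0], tips_below[node][0]] = depth[node]
        else:
            children = [tips_below[c] for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    C[np.ix_(ia, ib)] = depth[node]
                    C[np.ix_(ib, ia)] = depth[node]
            tips_below[node] = [i for ch in children for i in ch]
    names = [leaf.taxon.label for leaf in leaves]
    df = pd.DataFrame(C, index=names, columns=names)
    if labels is not None:
        missing = set(labels) - set(names)
        if missing:
            raise ValidationError(f"tips missing from tree: {sorted(missing)}")
        df = df.loc[labels, labels]
    return df


@dataclass
class PGLSResult:
    beta: pd.Series
    se: pd.Series
    lambda_hat: float
    loglik: float
    n: int
    at_bound: bool = False
    lambda_unidentifiable: bool = False

    def loglik_at(self, lam: float) -> float:
        return self._profile(lam)  # set after fitting

    _profile: object = field(default=None, repr=False)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def pgls_lambda(
    y: pd.Series,
    X: pd.DataFrame | np.ndarray,
    tree: dendropy.Tree,
    lambda_fixed: float | None = None,
) -> PGLSResult:
    """Phylogenetic GLS with ML-estimated Pagel's lambda.

    ``X`` is a numeric design matrix aligned to ``y`` (build factor designs
    with :func:`trait_design`). The covariance is
    ``V(lambda) = lambda * C`` off-diagonal with the diagonal of C kept,
    where C is the shared-branch-length matrix of the tree. Lambda is found
    by bounded ML on [0, 1] (profile likelihood, tolerance 1e-6); on a star
    tree lambda is unidentifiable and reported at the lower bound with a
    flag. Coefficient SEs use the unbiased residual variance
    ``r' V^-1 r / (n - p)``.
    """
    labels = list(y.index)
    C = phylo_covariance(tree, labels).to_numpy()
    Xd = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xd.ndim == 1:
        Xd = Xd[:, None]
    n, p = Xd.shape
    if np.linalg.matrix_rank(Xd) < p:
        raise ValidationError("rank-deficient design matrix")
    yv = y.to_numpy(dtype=float)

    def fit_at(lam: float):
        V = _lambda_cov(C, lam)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            # near-singular covariance (e.g. vanishing cherry branches):
            # regularise minimally; if still singular the point is excluded
            jitter = 1e-10 * float(np.trace(V)) / n
            try:
                L = np.linalg.cholesky(V + jitter * np.eye(n))
            except np.linalg.LinAlgError:
                return None, np.inf, -np.inf, None
        Wx = linalg.solve_triangular(L, Xd, lower=True)
        Wy = linalg.solve_triangular(L, yv, lower=True)
        beta, *_ = np.linalg.lstsq(Wx, Wy, rcond=None)
        r = Wy - Wx @ beta
        rss = float(r @ r)
        sigma2_ml = rss / n
        logdet = 2 * np.log(np.diag(L)).sum()
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
        return beta, rss, ll, Wx

    offdiag = C - np.diag(np.diag(C))
    star = np.abs(offdiag).max() <= 1e-12 * max(1.0, np.abs(np.diag(C)).max())

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
        at_bound = lam_hat in (0.0, 1.0)
    elif star:
        lam_hat, at_bound = 0.0, True
    else:
        neg = lambda lam: -fit_at(lam)[2]
        res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        candidates = [(fit_at(l)[2], l) for l in (0.0, float(res.x), 1.0)]
        ll_best, lam_hat = max(candidates)
        at_bound = lam_hat in (0.0, 1.0)

    beta, rss, ll, Wx = fit_at(lam_hat)
    dof = max(n - p, 1)
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(Wx.T @ Wx)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"b{i}" for i in range(p)]
    result = PGLSResult(
        beta=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
        lambda_hat=float(lam_hat), loglik=float(ll), n=n,
        at_bound=at_bound, lambda_unidentifiable=star,
    )
    result._profile = lambda lam: fit_at(lam)[2]
    return result


def trait_design(categories: pd.Series, cell_means: bool = True) -> pd.DataFrame:
    """Design matrix for a categorical predictor (cell-means by default)."""
    d = pd.get_dummies(categories, drop_first=not cell_means).astype(float)
    if not cell_means:
        d.insert(0, "intercept", 1.0)
    return d


def category_niche_means(
    scores: pd.Series,
    categories: pd.Series,
    tree: dendropy.Tree,
) -> tuple[pd.DataFrame, float]:
    """Per-category mean niche score, with and without phylogeny.

    Non-phylogenetic means are arithmetic means with SE = sd/sqrt(n)
    (NaN and flagged when n = 1); phylogenetic means are the cell-means GLS
    coefficients under the ML-lambda covariance. Returns the table and the
    fitted lambda.
    """
    categories = categories.loc[scores.index]
    X = trait_design(categories, cell_means=True)
    fit = pgls_lambda(scores, X, tree)
    rows = []
    for cat in X.columns:
        vals = scores[categories == cat]
        n = len(vals)
        rows.append({
            "category": cat, "n": n,
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "mean_pgls": float(fit.beta[cat]),
            "se_pgls": float(fit.se[cat]),
            "n1_flag": n == 1,
        })
    return pd.DataFrame(rows), fit.lambda_hat
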