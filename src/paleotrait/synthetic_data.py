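"""Synthetic datasets with the statistical structure of the permafrost study.

The published analysis rests on a 216-sample x 131-MOTU read table spread
over three climatic periods (145 pre-LGM, 32 LGM, 39 post-LGM samples) and
21 sites, with heavily skewed read counts, correlated categorical traits
and period-dependent composition shifts. The generator reproduces that
structure so every downstream statistic can be exercised and calibrated
against known generative truth:

* trait categories drawn to match the published marginal frequencies, with
  trait-trait correlation induced by conditioning mycorrhizal type,
  status, N-fixation and pollination on growth form (woody MOTUs biased
  towards ECM/ERM and wind pollination; no N-fixers among NM MOTUs);
* optional phylogenetic conservatism: growth form follows quantile bins of
  a Brownian character simulated on a Yule tree over the MOTUs;
* per-sample counts from a Dirichlet-multinomial around period- and
  site-specific expected profiles (small concentration = the
  overdispersion typical of metabarcoding read tables);
* lognormal per-sample read depths;
* spatially autocorrelated site effects from an exponential-covariance
  Gaussian process over 21 site locations.

The returned truth record contains the exact per-period expected trait
shares implied by the generative weights, so estimator bias and CI
coverage can be checked analytically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .io_core import PERIODS, TRAITS, TRAIT_LEVELS, ValidationError, validate_trait_table
from .phylo import node_heights, phylo_covariance

__all__ = ["SimConfig", "SyntheticDataset", "simulate_dataset", "simulate_tree",
           "simulate_backbone", "taxonomy_from_tree"]


#: Published trait-category counts out of 131 MOTUs; marginals are counts/131.
PAPER_TRAIT_COUNTS: dict[str, dict[str, int]] = {
    "growth_form": {"forb": 86, "graminoid": 28, "dwarf_shrub": 11, "tree_shrub": 6},
    "myc_type": {"AM": 86, "ECM": 7, "ERM": 10, "NM": 28},
    "myc_status": {"FM": 58, "OM": 45, "NM": 28},
    "n_fix": {"fixer": 9, "nonfixer": 122},
    "pollination": {"insect": 87, "wind": 44},
}

#: Default log-fold period effects (pre-LGM, LGM, post-LGM) per category,
#: matching the direction of the reported composition shifts: AM/forb/OM
#: decline towards the post-LGM, ECM/NM/woody/wind increase, N-fixers dip
#: in the LGM.
DEFAULT_PERIOD_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "growth_form": {"forb": (0.3, 0.1, -0.5), "graminoid": (-0.1, 0.0, 0.2),
                    "tree_shrub": (-0.4, -0.3, 0.6)},
    "myc_type": {"AM": (0.4, 0.0, -0.6), "ECM": (-0.4, 0.2, 0.6),
                 "NM": (-0.2, 0.2, 0.4)},
    "myc_status": {"OM": (0.3, -0.2, -0.3), "FM": (-0.2, 0.3, 0.1)},
    "n_fix": {"fixer": (0.0, -0.6, 0.4)},
    "pollination": {"wind": (-0.1, 0.0, 0.3)},
}


def _marginals_from_counts(counts: Mapping[str, Mapping[str, int]]) -> dict[str, dict[str, float]]:
    out = {}
    for t, cc in counts.items():
        tot = sum(cc.values())
        out[t] = {c: v / tot for c, v in cc.items()}
    return out


@dataclass
class SimConfig:
    """Generative parameters; defaults are the study's structure."""

    n_samples_per_period: tuple[int, int, int] = (145, 32, 39)
    n_motus: int = 131
    trait_marginals: dict = field(default_factory=lambda: _marginals_from_counts(PAPER_TRAIT_COUNTS))
    period_effects: dict = field(default_factory=lambda: {t: dict(v) for t, v in DEFAULT_PERIOD_EFFECTS.items()})
    #: optional exact per-period target shares, e.g. {"myc_type": {"AM": (0.8, 0.6, 0.4)}};
    #: overrides period_effects for those categories (ignores site effects,
    #: so combine with spatial_sill=0 when exactness matters).
    target_shares: dict = field(default_factory=dict)
    overdispersion: float = 0.3          # Dirichlet concentration multiplier
    reads_mu: float = 8.9                # lognormal log-mean of per-sample depth
    reads_sigma: float = 1.5
    n_sites: int = 21
    spatial_range_km: float = 200.0
    spatial_sill: float = 0.25
    trait_conservatism: float = 0.5      # Pagel-lambda of the growth-form character
    base_sigma: float = 1.2              # lognormal sd of baseline MOTU abundance
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.n_samples_per_period):
            raise ValidationError("each period needs >= 1 sample")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion concentration must be > 0")
        for t, probs in self.trait_marginals.items():
            s = sum(probs.values())
            if not np.isclose(s, 1.0, atol=1e-8):
                raise ValidationError(f"marginals for {t!r} sum to {s}, not 1")
        nm = self.trait_marginals.get("myc_type", {}).get("NM", 0.0)
        fix = self.trait_marginals.get("n_fix", {}).get("fixer", 0.0)
        if nm >= 1.0 and fix > 0:
            raise ValidationError("infeasible marginals: N-fixers forced onto NM MOTUs")


@dataclass
class SyntheticDataset:
    read_matrix: pd.DataFrame
    samples: pd.DataFrame
    traits: pd.DataFrame
    phylogeny: dendropy.Tree
    taxonomy: pd.DataFrame
    truth: dict


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    trait_lambda: float = 1.0,
    seed: int | None = None,
    labels: list | None = None,
) -> tuple[dendropy.Tree, pd.Series]:
    """Yule tree plus a continuous character under lambda-scaled Brownian motion.

    The pure-birth tree is ultrametric with all extant tips contemporaneous;
    the character is multivariate normal with covariance
    ``lambda * C`` off-diagonal (diagonal kept), C the shared branch-length
    matrix. Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if not 0.0 <= trait_lambda <= 1.0:
        raise ValidationError("trait_lambda must lie in [0, 1]")
    pyrng = random.Random(None if seed is None else int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng,
    )
    if labels is None:
        labels = [f"motu{i+1}" for i in range(n_tips)]
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lab
    C = phylo_covariance(tree).to_numpy()
    V = trait_lambda * C
    np.fill_diagonal(V, np.diag(C))
    rng = np.random.default_rng(None if seed is None else int(seed))
    x = np.linalg.cholesky(V + 1e-12 * np.eye(n_tips)) @ rng.standard_normal(n_tips)
    tip_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    return tree, pd.Series(x, index=tip_order)


def _counts_for_marginals(probs: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items to categories."""
    cats = list(probs)
    raw = np.array([probs[c] * n for c in cats])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(raw - base)[::-1]
    for k in range(rem):
        base[order[k]] += 1
    return dict(zip(cats, base))


# Conditional P(myc_type | growth form): woody MOTUs biased to ECM/ERM,
# herbs to AM/NM; the mixture over default growth-form marginals
# approximately reproduces the published type marginals.
_TYPE_GIVEN_FORM = {
    "forb":       {"AM": 0.75, "ECM": 0.01, "ERM": 0.02, "NM": 0.22},
    "graminoid":  {"AM": 0.60, "ECM": 0.03, "ERM": 0.02, "NM": 0.35},
    "dwarf_shrub": {"AM": 0.15, "ECM": 0.20, "ERM": 0.60, "NM": 0.05},
    "tree_shrub": {"AM": 0.20, "ECM": 0.60, "ERM": 0.10, "NM": 0.10},
}
_WIND_GIVEN_FORM = {"forb": 0.15, "graminoid": 0.95, "dwarf_shrub": 0.30, "tree_shrub": 0.60}


def _simulate_traits(cfg: SimConfig, rng: np.random.Generator,
                     tree: dendropy.Tree, char: pd.Series) -> pd.DataFrame:
    motus = list(char.index)
    n = len(motus)
    gf_probs = cfg.trait_marginals["growth_form"]
    counts = _counts_for_marginals(gf_probs, n)
    # conservatism: order MOTUs by the Brownian character and fill categories
    # woody-to-herb along it, so categories cluster on the tree
    order = np.argsort(char.to_numpy())
    gf = np.empty(n, dtype=object)
    pos = 0
    for cat in ("tree_shrub", "dwarf_shrub", "graminoid", "forb"):
        k = counts.get(cat, 0)
        gf[order[pos:pos + k]] = cat
        pos += k
    tt = pd.DataFrame(index=pd.Index(motus, name="motu_id"))
    tt["growth_form"] = gf

    types = []
    for form in gf:
        probs = _TYPE_GIVEN_FORM[form]
        types.append(rng.choice(list(probs), p=list(probs.values())))
    tt["myc_type"] = types

    status_probs = cfg.trait_marginals["myc_status"]
    fm = status_probs.get("FM", 0.0)
    om = status_probs.get("OM", 0.0)
    p_fm = fm / (fm + om) if fm + om > 0 else 0.5
    tt["myc_status"] = [
        "NM" if t == "NM" else ("FM" if rng.random() < p_fm else "OM")
        for t in tt["myc_type"]
    ]

    # N-fixers only among mycorrhizal MOTUs (the published table has no NM fixer)
    p_fix = cfg.trait_marginals["n_fix"].get("fixer", 0.0)
    p_nm = sum(
        gf_probs[f] * _TYPE_GIVEN_FORM[f]["NM"] for f in gf_probs
    )
    p_fix_given_myc = min(1.0, p_fix / max(1e-12, 1 - p_nm))
    tt["n_fix"] = [
        "nonfixer" if t == "NM" else ("fixer" if rng.random() < p_fix_given_myc else "nonfixer")
        for t in tt["myc_type"]
    ]
    tt["pollination"] = [
        "wind" if rng.random() < _WIND_GIVEN_FORM[f] else "insect" for f in gf
    ]
    return validate_trait_table(tt, normalize=False)


def taxonomy_from_tree(tree: dendropy.Tree,
                       fractions: tuple = (0.25, 0.45, 0.65, 0.85)) -> pd.DataFrame:
    """Synthetic rank table from clades of an ultrametric tree.

    For each rank (genus, tribe, subfamily, family) the tree is cut at the
    given fraction of its height; every maximal clade below the cut is one
    taxon of that rank, so ranks are nested and monophyletic by
    construction.
    """
    heights = node_heights(tree)
    total = heights[tree.seed_node]
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    out = pd.DataFrame(index=pd.Index(leaves, name="species"))
    for rank, frac in zip(("genus", "tribe", "subfamily", "family"), fractions):
        cut = frac * total
        labels: dict[str, str] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if heights[node] <= cut and (parent is None or heights[parent] > cut):
                counter += 1
                name = f"{rank}{counter}"
                for leaf in node.leaf_iter():
                    labels[leaf.taxon.label] = name
        out[rank] = [labels[s] for s in leaves]
    return out


def _site_effects(cfg: SimConfig, rng: np.random.Generator):
    lat = rng.uniform(62.0, 71.0, cfg.n_sites)
    lon = rng.uniform(100.0, 179.0, cfg.n_sites)
    from .spatial import haversine_matrix  # local import to avoid a cycle

    coords = pd.DataFrame({"sample_id": range(cfg.n_sites), "latitude": lat, "longitude": lon})
    d = haversine_matrix(coords).to_numpy()
    if cfg.spatial_sill > 0:
        cov = cfg.spatial_sill * np.exp(-d / cfg.spatial_range_km)
        g = np.linalg.cholesky(cov + 1e-10 * np.eye(cfg.n_sites)) @ rng.standard_normal(cfg.n_sites)
    else:
        g = np.zeros(cfg.n_sites)
    return lat, lon, g, d


_AGE_RANGES = {"pre-LGM": (25.5, 50.0), "LGM": (15.5, 25.0), "post-LGM": (0.0, 15.0)}


def simulate_dataset(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset; bit-identical for identical configs."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    tree, char = simulate_tree(cfg.n_motus, trait_lambda=cfg.trait_conservatism,
                               seed=int(rng.integers(2**31)))
    tt = _simulate_traits(cfg, rng, tree, char)
    motus = list(tt.index)
    taxonomy = taxonomy_from_tree(tree)

    base = rng.lognormal(0.0, cfg.base_sigma, cfg.n_motus)
    # period-specific expected weights from trait effects
    logw = np.tile(np.log(base)[:, None], (1, 3))
    for trait, effects in cfg.period_effects.items():
        for cat, shifts in effects.items():
            mask = (tt[trait] == cat).to_numpy()
            logw[mask] += np.asarray(shifts)[None, :]
    w = np.exp(logw)

    # exact-share overrides: scale one category's weights per period so its
    # expected read-weighted share matches the target
    for trait, targets in cfg.target_shares.items():
        for cat, shares in targets.items():
            mask = (tt[trait] == cat).to_numpy()
            if not mask.any() or mask.all():
                raise ValidationError(f"cannot target share for {trait}={cat}")
            for p in range(3):
                s = shares[p]
                a = w[mask, p].sum()
                b = w[~mask, p].sum()
                w[mask, p] *= (s / (1 - s)) * (b / a)
    w = w / w.sum(axis=0, keepdims=True)

    lat_s, lon_s, g, _ = _site_effects(cfg, rng)
    loading = rng.standard_normal(cfg.n_motus)

    n_per = cfg.n_samples_per_period
    periods = np.repeat(list(PERIODS), n_per)
    n_samples = len(periods)
    site_of = rng.integers(0, cfg.n_sites, n_samples)
    ages = np.array([rng.uniform(*_AGE_RANGES[p]) for p in periods])
    depth = np.maximum(1, np.round(rng.lognormal(cfg.reads_mu, cfg.reads_sigma, n_samples))).astype(np.int64)

    counts = np.zeros((n_samples, cfg.n_motus), dtype=np.int64)
    expected_share_w = np.zeros((n_samples, cfg.n_motus))
    pidx = {p: k for k, p in enumerate(PERIODS)}
    for j in range(n_samples):
        wj = w[:, pidx[periods[j]]] * np.exp(g[site_of[j]] * loading)
        wj = wj / wj.sum()
        expected_share_w[j] = wj
        alpha = cfg.overdispersion * cfg.n_motus * wj
        pi = rng.dirichlet(alpha)
        counts[j] = rng.multinomial(depth[j], pi)

    sample_ids = [f"s{j+1:03d}" for j in range(n_samples)]
    rm = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=motus)
    st = pd.DataFrame({
        "sample_id": sample_ids,
        "site_id": [f"site{k+1}" for k in site_of],
        "latitude": np.clip(lat_s[site_of] + rng.normal(0, 0.1, n_samples), -90, 90),
        "longitude": np.clip(lon_s[site_of] + rng.normal(0, 0.1, n_samples), -180, 180),
        "age": ages,
        "period": periods,
    })

    # analytic expected period shares (mean over samples of exact per-sample
    # expected category shares, matching the period estimator)
    expected = {}
    for trait in TRAITS:
        cats = [c for c in TRAIT_LEVELS[trait] if c != "undefined"]
        ind = np.stack([(tt[trait] == c).to_numpy(dtype=float) for c in cats], axis=1)
        per_sample = expected_share_w @ ind
        df = pd.DataFrame(per_sample, index=sample_ids, columns=cats)
        expected[trait] = df.groupby(periods).mean().reindex(list(PERIODS))
    truth = {
        "config": cfg,
        "base_abundance": pd.Series(base, index=motus),
        "period_weights": pd.DataFrame(w, index=motus, columns=list(PERIODS)),
        "site_effects": pd.Series(g, index=[f"site{k+1}" for k in range(cfg.n_sites)]),
        "site_coords": pd.DataFrame({"latitude": lat_s, "longitude": lon_s},
                                    index=[f"site{k+1}" for k in range(cfg.n_sites)]),
        "motu_loading": pd.Series(loading, index=motus),
        "expected_period_shares": expected,
        "trait_character": char,
    }
    return SyntheticDataset(read_matrix=rm, samples=st, traits=tt,
                            phylogeny=tree, taxonomy=taxonomy, truth=truth)


def simulate_backbone(
    n_species: int = 26,
    n_genus: int = 75,
    n_tribe: int = 7,
    n_subfamily: int = 5,
    n_family: int = 18,
    n_redundant: int = 10,
    depth: float = 5.0,
) -> tuple[dendropy.Tree, pd.DataFrame, dict[str, list[str]]]:
    """Deterministic backbone tree + taxonomy + MOTU definitions.

    Builds an ultrametric species tree (total depth ``depth``) whose
    structure supports the requested number of MOTUs placeable at each
    level: single-species matches, and species pairs whose lowest shared
    rank is genus, tribe, subfamily or family respectively, plus
    ``n_redundant`` species that represent no MOTU and must be pruned.
    """
    parts: list[str] = []
    tax_rows: list[dict] = []
    motu_defs: dict[str, list[str]] = {}
    counter = {"sp": 0}

    def new_species(genus, tribe, subfamily, family) -> str:
        counter["sp"] += 1
        s = f"sp{counter['sp']:04d}"
        tax_rows.append({"species": s, "genus": genus, "tribe": tribe,
                         "subfamily": subfamily, "family": family})
        return s

    def pair_subtree(join_height: float, ranks_a, ranks_b) -> tuple[str, str, str]:
        a = new_species(*ranks_a)
        b = new_species(*ranks_b)
        sub = f"({a}:{join_height},{b}:{join_height}):{depth - join_height}"
        return sub, a, b

    motu_n = 0
    for i in range(n_species):
        s = new_species(f"Eg{i}", f"Et{i}", f"Es{i}", f"Ef{i}")
        parts.append(f"{s}:{depth}")
        motu_n += 1
        motu_defs[f"motu{motu_n:03d}"] = [s]
    for i in range(n_genus):
        r = (f"Gg{i}", f"Gt{i}", f"Gs{i}", f"Gf{i}")
        sub, a, b = pair_subtree(1.0, r, r)
        parts.append(sub)
        motu_n += 1
        motu_defs[f"motu{motu_n:03d}"] = [a, b]
    for i in range(n_tribe):
        sub, a, b = pair_subtree(
            2.0, (f"Tg{i}a", f"Tt{i}", f"Ts{i}", f"Tf{i}"),
            (f"Tg{i}b", f"Tt{i}", f"Ts{i}", f"Tf{i}"))
        parts.append(sub)
        motu_n += 1
        motu_defs[f"motu{motu_n:03d}"] = [a, b]
    for i in range(n_subfamily):
        sub, a, b = pair_subtree(
            3.0, (f"Sg{i}a", f"St{i}a", f"Ss{i}", f"Sf{i}"),
            (f"Sg{i}b", f"St{i}b", f"Ss{i}", f"Sf{i}"))
        parts.append(sub)
        motu_n += 1
        motu_defs[f"motu{motu_n:03d}"] = [a, b]
    for i in range(n_family):
        sub, a, b = pair_subtree(
            4.0, (f"Fg{i}a", f"Ft{i}a", f"Fs{i}a", f"Ff{i}"),
            (f"Fg{i}b", f"Ft{i}b", f"Fs{i}b", f"Ff{i}"))
        parts.append(sub)
        motu_n += 1
        motu_defs[f"motu{motu_n:03d}"] = [a, b]
    for i in range(n_redundant):
        s = new_species(f"Rg{i}", f"Rt{i}", f"Rs{i}", f"Rf{i}")
        parts.append(f"{s}:{depth}")

    newick = "(" + ",".join(parts) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    taxonomy = pd.DataFrame(tax_rows).set_index("species")
    return tree, taxonomy, motu_defs
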