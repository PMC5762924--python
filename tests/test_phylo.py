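import numpy as np
import pandas as pd
import pytest

from paleotrait.phylo import (
    category_niche_means,
    graft_motus,
    is_ultrametric,
    node_heights,
    pgls_lambda,
    phylo_covariance,
    read_newick,
    trait_design,
    tree_height,
    write_newick,
)
from paleotrait.synthetic_data import simulate_backbone, simulate_tree

import dendropy


def _small_backbone():
    """Four species: two congeners (genus G1) plus two singletons."""
    nwk = "((a1:1,a2:1):3,(b1:2.5,c1:2.5):1.5);"
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    taxonomy = pd.DataFrame({
        "genus": ["G1", "G1", "G2", "G3"],
        "tribe": ["T1", "T1", "T1", "T2"],
        "subfamily": ["S1", "S1", "S1", "S2"],
        "family": ["F1", "F1", "F1", "F1"],
    }, index=pd.Index(["a1", "a2", "b1", "c1"], name="species"))
    return tree, taxonomy


class TestGrafting:
    def test_single_species_relabelled(self):
        tree, tax = _small_backbone()
        grafted, rep = graft_motus(tree, tax, {"motuX": ["b1"], "mA": ["a1"],
                                               "mA2": ["a2"], "mC": ["c1"]})
        assert rep.relabelled == ["motuX", "mA", "mA2", "mC"]
        assert len(grafted.leaf_nodes()) == 4  # tip count unchanged
        labels = {l.taxon.label for l in grafted.leaf_node_iter()}
        assert "motuX" in labels and "b1" not in labels

    def test_congener_motu_attached_at_genus_mrca(self):
        tree, tax = _small_backbone()
        grafted, rep = graft_motus(tree, tax, {"motuG": ["a1", "a2"], "mB": ["b1"], "mC": ["c1"]})
        assert rep.grafted == {"motuG": "genus"}
        assert is_ultrametric(grafted, tol=1e-6)
        # pendant branch = genus-node height, so the new tip reaches the crown
        assert tree_height(grafted) == pytest.approx(4.0)

    def test_family_level_motu_and_pruning(self):
        tree, tax = _small_backbone()
        grafted, rep = graft_motus(tree, tax, {"motuF": ["b1", "c1"]})
        # b1/c1 share only family F1 -> attach at root MRCA, prune all species
        assert rep.grafted == {"motuF": "family"}
        assert [l.taxon.label for l in grafted.leaf_node_iter()] == ["motuF"]

    def test_unplaceable_reported_not_dropped(self):
        tree, tax = _small_backbone()
        grafted, rep = graft_motus(tree, tax, {"motuZ": ["zz1", "zz2"], "mB": ["b1"]})
        assert rep.unplaceable == ["motuZ"]
        assert rep.relabelled == ["mB"]

    def test_published_attachment_counts_yield_131_tips(self):
        tree, tax, defs = simulate_backbone()  # 26+75+7+5+18 MOTUs
        grafted, rep = graft_motus(tree, tax, defs)
        assert len(grafted.leaf_nodes()) == 131
        assert not rep.unplaceable
        assert is_ultrametric(grafted, tol=1e-6)
        assert tree_height(grafted) == pytest.approx(tree_height(tree))

    def test_newick_round_trip(self, tmp_path):
        tree, tax, defs = simulate_backbone(4, 3, 1, 1, 1, n_redundant=2)
        grafted, _ = graft_motus(tree, tax, defs)
        path = tmp_path / "t.nwk"
        write_newick(grafted, path)
        back = read_newick(path)
        assert {l.taxon.label for l in back.leaf_node_iter()} == \
               {l.taxon.label for l in grafted.leaf_node_iter()}


class TestPglsLambda:
    def test_star_tree_reduces_to_ols(self):
        n = 20
        nwk = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=n), index=[f"t{i}" for i in range(n)])
        x = rng.normal(size=n)
        X = pd.DataFrame({"intercept": 1.0, "x": x}, index=y.index)
        fit = pgls_lambda(y, X, tree)
        assert fit.lambda_unidentifiable and fit.lambda_hat == 0.0
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-9)

    def test_lambda_zero_fixed_equals_ols(self):
        tree, y = simulate_tree(40, trait_lambda=1.0, seed=5)
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=40)}, index=y.index)
        fit = pgls_lambda(y, X, tree, lambda_fixed=0.0)
        # lambda = 0 keeps only the diagonal; with contemporaneous tips the
        # covariance is proportional to I, i.e. ordinary least squares
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-9)

    def test_loglik_peaks_at_estimate(self):
        tree, y = simulate_tree(60, trait_lambda=0.7, seed=9)
        X = pd.DataFrame({"intercept": np.ones(60)}, index=y.index)
        fit = pgls_lambda(y, X, tree)
        for lam in (0.0, 0.5, 1.0):
            assert fit.loglik >= fit._profile(lam) - 1e-6

    @pytest.mark.parametrize("lam_true,band", [(1.0, (0.85, 1.0)), (0.0, (0.0, 0.15))])
    def test_lambda_recovery_small(self, lam_true, band):
        """Average ML lambda over a handful of replicates lands near truth
        (the full-scale recovery check lives in the acceptance suite)."""
        fits = []
        for s in range(10):
            tree, y = simulate_tree(100, trait_lambda=lam_true, seed=1000 + s)
            X = pd.DataFrame({"intercept": np.ones(100)}, index=y.index)
            fits.append(pgls_lambda(y, X, tree).lambda_hat)
        assert band[0] <= np.mean(fits) <= band[1]


class TestCategoryMeans:
    def test_lambda_zero_matches_arithmetic_means(self):
        tree, y = simulate_tree(30, trait_lambda=0.0, seed=3)
        rng = np.random.default_rng(2)
        cats = pd.Series(rng.choice(["u", "v"], 30), index=y.index)
        X = trait_design(cats)
        fit = pgls_lambda(y, X, tree, lambda_fixed=0.0)
        for cat in ("u", "v"):
            assert fit.beta[cat] == pytest.approx(y[cats == cat].mean(), abs=1e-9)

    def test_identical_category_values_zero_difference(self):
        tree, y = simulate_tree(20, trait_lambda=0.5, seed=4)
        y[:] = 1.5
        cats = pd.Series(["u"] * 10 + ["v"] * 10, index=y.index)
        tbl, _ = category_niche_means(y, cats, tree)
        means = tbl.set_index("category")
        assert means.loc["u", "mean"] == pytest.approx(means.loc["v", "mean"])
        assert means.loc["u", "mean_pgls"] == pytest.approx(means.loc["v", "mean_pgls"], abs=1e-6)

    def test_singleton_category_flagged(self):
        tree, y = simulate_tree(10, trait_lambda=0.5, seed=6)
        cats = pd.Series(["solo"] + ["rest"] * 9, index=y.index)
        tbl, _ = category_niche_means(y, cats, tree)
        row = tbl.set_index("category").loc["solo"]
        assert row["n1_flag"] and np.isnan(row["se"])

    def test_phylo_se_not_smaller_for_conserved_traits(self):
        """Phylogenetically clustered data carry less independent information,
        so GLS standard errors should rarely undercut the naive ones."""
        wins = 0
        n_sims = 20
        for s in range(n_sims):
            tree, y = simulate_tree(60, trait_lambda=1.0, seed=2000 + s)
            rng = np.random.default_rng(s)
            cats = pd.Series(rng.choice(["u", "v"], 60), index=y.index)
            tbl, _ = category_niche_means(y, cats, tree)
            if (tbl["se_pgls"] >= tbl["se"] - 1e-9).all():
                wins += 1
        assert wins / n_sims >= 0.9
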