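import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleotrait.io_core import ValidationError
from paleotrait.permanova import (
    bray_curtis,
    compact_letters,
    euclidean_distance,
    gower_center,
    pairwise_permanova,
    permanova,
    residual_distances,
)


class TestBrayCurtis:
    def test_hand_formula(self):
        rm = pd.DataFrame([[2, 0, 1], [1, 1, 1]], index=["a", "b"])
        d = bray_curtis(rm)
        assert d.loc["a", "b"] == pytest.approx(2 / 6)

    def test_identical_rows_zero_and_disjoint_one(self):
        rm = pd.DataFrame([[3, 1], [3, 1], [0, 5]], index=["a", "b", "c"])
        rm2 = pd.DataFrame([[3, 0], [0, 5]], index=["x", "y"])
        assert bray_curtis(rm).loc["a", "b"] == pytest.approx(0.0)
        assert bray_curtis(rm2).loc["x", "y"] == pytest.approx(1.0)

    def test_all_zero_row_named(self):
        rm = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            bray_curtis(rm)


@pytest.fixture()
def hand_example():
    """1-D Euclidean data, groups {0,1} vs {3,4}."""
    x = pd.DataFrame({"v": [0.0, 1.0, 3.0, 4.0]}, index=list("abcd"))
    g = pd.Series(["A", "A", "B", "B"], index=list("abcd"), name="grp")
    return euclidean_distance(x), g


class TestPermanova:
    def test_hand_partition_and_exact_p(self, hand_example):
        d, g = hand_example
        res = permanova(d, g, n_perm="exact")
        term = res.terms.iloc[0]
        assert res.total_ss == pytest.approx(10.0)
        assert term["SS"] == pytest.approx(9.0)
        assert term["pseudo_F"] == pytest.approx(18.0)
        assert term["R2"] == pytest.approx(0.9)
        assert term["p"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_classical_anova_f(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=24)
        grp = np.repeat(list("ABC"), 8)
        d = euclidean_distance(pd.DataFrame({"y": y}))
        res = permanova(d, pd.Series(grp, name="g"), n_perm=9, seed=0)
        f_classic = stats.f_oneway(*[y[grp == lv] for lv in "ABC"]).statistic
        assert res.terms["pseudo_F"].iloc[0] == pytest.approx(f_classic, abs=1e-9)

    def test_matches_scikit_bio_oneway(self):
        """Independent oracle: skbio's PERMANOVA statistic on the same data."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        rng = np.random.default_rng(5)
        x = rng.poisson(5.0, size=(15, 6)) + 1
        grp = rng.choice(["u", "v", "w"], 15)
        d = bray_curtis(pd.DataFrame(x, index=[f"s{i}" for i in range(15)]))
        mine = permanova(d, pd.Series(grp, index=d.index, name="g"), n_perm=99, seed=0)
        theirs = sk_permanova(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                              grouping=list(grp), permutations=99)
        assert mine.terms["pseudo_F"].iloc[0] == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_trace_identity_and_r2_closure(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 4))
        d = euclidean_distance(pd.DataFrame(x))
        G = gower_center(d.to_numpy())
        n = 12
        ss_from_d = (d.to_numpy() ** 2).sum() / (2 * n)
        assert np.trace(G) == pytest.approx(ss_from_d, abs=1e-9)
        g = pd.Series(rng.choice(["A", "B", "C"], n), name="g")
        res = permanova(d, g, n_perm=9, seed=0)
        assert res.terms["R2"].sum() + res.residual_ss / res.total_ss == pytest.approx(1.0, abs=1e-12)

    def test_p_invariant_to_label_order(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(14, 3))
        idx = [f"s{i}" for i in range(14)]
        d = euclidean_distance(pd.DataFrame(x, index=idx))
        g = pd.Series(rng.choice(["A", "B"], 14), index=idx, name="g")
        res1 = permanova(d, g, n_perm=199, seed=3)
        order = list(rng.permutation(idx))
        res2 = permanova(d.loc[order, order], g.loc[order], n_perm=199, seed=3)
        assert res1.terms["pseudo_F"].iloc[0] == pytest.approx(res2.terms["pseudo_F"].iloc[0], abs=1e-9)
        assert abs(res1.terms["p"].iloc[0] - res2.terms["p"].iloc[0]) <= 0.05

    def test_sequential_terms_covariate_then_factor(self):
        rng = np.random.default_rng(11)
        n = 20
        cov = rng.normal(size=n)
        grp = rng.choice(["A", "B"], n)
        y = 2 * cov + rng.normal(size=n)
        d = euclidean_distance(pd.DataFrame({"y": y}))
        design = pd.DataFrame({"cov": cov, "grp": grp})
        res = permanova(d, design, ["cov", "grp"], n_perm=99, seed=0)
        assert list(res.terms["name"]) == ["cov", "grp"]
        assert res.terms["SS"].iloc[0] > res.terms["SS"].iloc[1]
        assert res.residual_df == n - 1 - 2

    def test_aliased_term_rejected(self):
        g = pd.Series(["A", "A", "B", "B"], name="g")
        design = pd.DataFrame({"g": g, "same": g.to_numpy()})
        d = euclidean_distance(pd.DataFrame({"v": [0.0, 1, 3, 4]}))
        with pytest.raises(ValidationError, match="same"):
            permanova(d, design, ["g", "same"], n_perm=9, seed=0)


class TestPairwise:
    def _groups(self, rng, centres, n_per=8, spread=0.3):
        rows, labels = [], []
        for name, c in centres.items():
            rows.append(rng.normal(c, spread, size=(n_per, 2)))
            labels += [name] * n_per
        x = pd.DataFrame(np.vstack(rows), index=[f"s{i}" for i in range(len(labels))])
        return euclidean_distance(x), pd.Series(labels, index=x.index, name="g")

    def test_three_distinct_groups_get_distinct_letters(self, rng):
        d, g = self._groups(rng, {"A": (0, 0), "B": (10, 0), "C": (0, 10)})
        _, letters = pairwise_permanova(d, g, n_perm=199, seed=0)
        assert len({letters[k] for k in "ABC"}) == 3

    def test_overlapping_pair_shares_letter(self, rng):
        d, g = self._groups(rng, {"A": (0, 0), "B": (0.05, 0), "C": (50, 50)})
        _, letters = pairwise_permanova(d, g, n_perm=199, seed=0)
        assert set(letters["A"]) & set(letters["B"])
        assert not set(letters["A"]) & set(letters["C"])

    def test_identical_groups_share_one_letter(self):
        letters = compact_letters(["A", "B", "C"], pd.DataFrame(
            {"groupA": ["A", "A", "B"], "groupB": ["B", "C", "C"], "p": [0.9, 0.8, 0.7]}))
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_residual_distances_remove_group_effect(self, rng):
        d, g = self._groups(rng, {"A": (0, 0), "B": (30, 0)})
        resid = residual_distances(d, g)
        res = permanova(resid, g, n_perm=99, seed=0)
        assert res.terms["R2"].iloc[0] < 1e-6
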