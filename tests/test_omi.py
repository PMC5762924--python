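import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleotrait.omi import (
    dunn_test,
    omi_analysis,
    omi_from_env,
    omi_randtest,
    period_env_table,
    trait_niche_models,
)

from conftest import toy_trait_table


class TestOmiDecomposition:
    def test_point_species_hand_example(self):
        """Two periods, standardized dummy z = (1,1,-1,-1); a species found
        only in sample 1 sits at marginality 1, so OMI = 1."""
        Z = pd.DataFrame({"z": [1.0, 1.0, -1.0, -1.0]}, index=list("abcd"))
        rm = pd.DataFrame({"pt": [5, 0, 0, 0], "unif": [1, 1, 1, 1]}, index=list("abcd"))
        res = omi_from_env(rm, Z)
        assert res.stats.loc["pt", "omi"] == pytest.approx(1.0)
        assert res.stats.loc["unif", "omi"] == pytest.approx(0.0)

    def test_uniform_profile_zero_marginality(self, filtered):
        rm, _, _, periods = filtered
        rm = rm.copy()
        rm["flat"] = 3  # constant across samples
        res = omi_analysis(rm, periods)
        assert res.stats.loc["flat", "omi"] == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identities_random_fixture(self, rng):
        rm = pd.DataFrame(rng.poisson(4.0, size=(10, 6)) + 1,
                          index=[f"s{i}" for i in range(10)])
        periods = pd.Series(rng.choice(["pre-LGM", "LGM", "post-LGM"], 10), index=rm.index)
        res = omi_analysis(rm, periods)
        st = res.stats
        assert np.allclose(st["inertia"], st["omi"] + st["tol"] + st["rtol"], atol=1e-9)
        assert res.eigenvalues.sum() == pytest.approx((st["weight"] * st["omi"]).sum(), abs=1e-9)

    def test_rank_two_environment(self, filtered):
        rm, _, _, periods = filtered
        res = omi_analysis(rm, periods)
        assert (res.eigenvalues[2:] <= 1e-10).all()

    def test_axis_orientation_contract(self):
        """On data whose dominant gradient separates the post-LGM from the
        earlier periods, a MOTU confined to post-LGM samples takes the most
        negative axis-1 score."""
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(30)]
        periods = pd.Series(np.repeat(["pre-LGM", "LGM", "post-LGM"], 10), index=idx)
        early = (periods != "post-LGM").to_numpy()
        rm = pd.DataFrame(index=idx)
        for k in range(6):   # shared by pre-LGM and LGM
            rm[f"early{k}"] = np.where(early, 20, 1) + rng.poisson(1.0, 30)
        for k in range(6):   # post-LGM specialists, one strictly confined
            rm[f"late{k}"] = np.where(early, 1, 20) + rng.poisson(1.0, 30)
        rm["postonly"] = np.where(early, 0, 50)
        res = omi_analysis(rm, periods)
        s1 = res.species_scores["axis1"]
        assert s1["postonly"] < 0
        assert s1["postonly"] == pytest.approx(s1.min())

    def test_scores_stable_under_motu_order(self, filtered):
        rm, _, _, periods = filtered
        res1 = omi_analysis(rm, periods)
        cols = list(rm.columns)[::-1]
        res2 = omi_analysis(rm[cols], periods)
        pd.testing.assert_frame_equal(
            res1.species_scores.loc[cols], res2.species_scores, atol=1e-9, rtol=0)


class TestRandTest:
    def test_structured_data_hits_p_floor(self):
        rng = np.random.default_rng(0)
        n = 30
        periods = pd.Series(np.repeat(["pre-LGM", "LGM", "post-LGM"], 10),
                            index=[f"s{i}" for i in range(n)])
        block = np.kron(np.eye(3), np.ones((10, 4))) * 20
        rm = pd.DataFrame(block + rng.poisson(0.5, block.shape), index=periods.index)
        rm = rm.loc[:, rm.sum(axis=0) > 0]
        _, p, _ = omi_randtest(rm, periods, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_two_sample_brute_force(self):
        """With n = 2 the permutation space has 2 elements; p matches exhaustive enumeration."""
        periods = pd.Series(["LGM", "post-LGM"], index=["a", "b"])
        rm = pd.DataFrame({"m1": [5, 1], "m2": [1, 5]}, index=["a", "b"])
        Z = period_env_table(periods).to_numpy()
        y = rm.to_numpy(dtype=float).T
        P = y / y.sum(axis=1, keepdims=True)
        u = y.sum(axis=1) / y.sum()
        vals = []
        for perm in itertools.permutations(range(2)):
            M = P @ Z[list(perm)]
            vals.append(float((u * (M**2).sum(axis=1)).sum()))
        obs = vals[0]
        expected = (sum(v >= obs - 1e-12 for v in vals[1:]) + 1) / 2
        # both orderings of a swapped 2-sample environment give equal mean OMI
        _, p, perm_vals = omi_randtest(rm, periods, n_perm=1, seed=0)
        assert p == pytest.approx(expected)

    def test_n_perm_contract(self, filtered):
        rm, _, _, periods = filtered
        with pytest.raises(ValueError):
            omi_randtest(rm, periods, n_perm=0)


class TestTraitNicheModels:
    def test_confounded_trait_adds_nothing_after_growth_form(self, rng):
        """A trait identical to growth form has zero added SS in model (ii)."""
        n = 40
        tt = toy_trait_table()
        motus = [f"m{i}" for i in range(n)]
        gf = rng.choice(["forb", "graminoid"], n)
        table = pd.DataFrame({
            "growth_form": gf,
            "myc_type": np.where(gf == "forb", "AM", "NM"),   # == growth form
            "myc_status": np.where(gf == "forb", "FM", "NM"),
            "n_fix": rng.choice(["fixer", "nonfixer"], n),
            "pollination": rng.choice(["insect", "wind"], n),
        }, index=pd.Index(motus, name="motu_id"))
        scores = pd.DataFrame(rng.normal(size=(n, 2)), index=motus,
                              columns=["axis1", "axis2"])
        models = trait_niche_models(scores, table, n_perm=49, seed=0)
        term = models["myc_type"]["after_growth_form"].term("myc_type")
        assert term["R2"] == pytest.approx(0.0, abs=1e-9)

    def test_status_detected_after_growth_form(self, rng):
        """Power check: a status effect independent of growth form stays
        significant in the fully adjusted model."""
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            r = np.random.default_rng(s)
            n = 60
            motus = [f"m{i}" for i in range(n)]
            gf = r.choice(["forb", "graminoid"], n)
            status = r.choice(["OM", "FM"], n)
            table = pd.DataFrame({
                "growth_form": gf,
                "myc_type": r.choice(["AM", "ECM"], n),
                "myc_status": status,
                "n_fix": r.choice(["fixer", "nonfixer"], n),
                "pollination": r.choice(["insect", "wind"], n),
            }, index=pd.Index(motus, name="motu_id"))
            axis1 = 1.5 * (status == "OM") + r.normal(size=n)
            scores = pd.DataFrame({"axis1": axis1, "axis2": r.normal(size=n)}, index=motus)
            models = trait_niche_models(scores, table, n_perm=99, seed=s)
            p = models["myc_status"]["after_growth_form_and_traits"].term("myc_status")["p"]
            hits += p <= 0.05
        assert hits / n_sims >= 0.8

    def test_confounded_pair_never_co_entered(self, filtered):
        rm, tt, _, periods = filtered
        scores = omi_analysis(rm, periods).species_scores
        models = trait_niche_models(scores, tt.loc[scores.index], n_perm=9, seed=0)
        for focal in ("myc_type", "myc_status"):
            names = list(models[focal]["after_growth_form_and_traits"].terms["name"])
            other = "myc_status" if focal == "myc_type" else "myc_type"
            assert other not in names
            assert names[-1] == focal


class TestDunn:
    def test_hand_example_no_ties(self):
        v = pd.Series([1.0, 2, 3, 4, 5, 6])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        res = dunn_test(v, g)
        z = res.pairwise["z"].iloc[0]
        assert abs(z) == pytest.approx(3 / np.sqrt(3.5 * (2 / 3)), rel=1e-9)

    def test_identical_groups(self):
        v = pd.Series([1.0, 1, 1, 1])
        g = pd.Series(["a", "a", "b", "b"])
        res = dunn_test(v, g)
        assert res.pairwise["z"].iloc[0] == 0.0
        assert res.pairwise["p"].iloc[0] == 1.0

    def test_ties_match_brute_force(self):
        v = pd.Series([1.0, 1, 2, 2, 3, 3])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = dunn_test(v, g)
        # independent recomputation with mid-ranks and the tie correction
        ranks = stats.rankdata(v)
        N = 6
        _, counts = np.unique(v, return_counts=True)
        T = (counts**3 - counts).sum() / (12 * (N - 1))
        ra, rb = ranks[:3].mean(), ranks[3:].mean()
        z = (ra - rb) / np.sqrt((N * (N + 1) / 12 - T) * (2 / 3))
        assert res.pairwise["z"].iloc[0] == pytest.approx(z, rel=1e-12)

    def test_antisymmetric_z(self):
        """Reversing the order in which groups are encountered flips the
        pair (a, b) -> (b, a) and negates z."""
        v = pd.Series([1.0, 2, 3, 7, 8, 9])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        order = [3, 4, 5, 0, 1, 2]
        r1 = dunn_test(v, g).pairwise.iloc[0]
        r2 = dunn_test(v.iloc[order].reset_index(drop=True),
                       g.iloc[order].reset_index(drop=True)).pairwise.iloc[0]
        assert (r1["catA"], r1["catB"]) == ("a", "b")
        assert (r2["catA"], r2["catB"]) == ("b", "a")
        assert r1["z"] == pytest.approx(-r2["z"])
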