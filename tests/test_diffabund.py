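"""LEfSe-style screen and Spearman-network unit tests, with brute-force
oracles for the rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ch4rumen import diffabund as da
from ch4rumen.community import ASVTable
from ch4rumen.simulate import CommunitySimSpec, simulate_asv_table


def brute_force_h(a, b):
    """Independent tie-corrected Kruskal-Wallis H (group-wise formula)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    h = 0.0
    for grp in (ranks[: len(a)], ranks[len(a):]):
        h += grp.sum() ** 2 / grp.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = pd.Series(pooled).value_counts().to_numpy()
    return h / (1 - ((ties ** 3 - ties).sum() / (n ** 3 - n)))


class TestKruskalWallis:
    def test_identical_constants(self):
        res = da.kruskal_wallis_test([5, 5, 5], [5, 5, 5])
        assert (res.h, res.p) == (0.0, 1.0)

    def test_hand_ranks_and_exact_enumeration(self):
        res = da.kruskal_wallis_test([1, 2, 3], [4, 5, 6], exact=True)
        assert res.h == pytest.approx(3.857142857142854)
        assert res.p == pytest.approx(0.1)  # 2 of the 20 splits reach H

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tie_corrected_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 8).astype(float)  # tie-heavy
        b = rng.integers(0, 4, 9).astype(float)
        res = da.kruskal_wallis_test(a, b, exact=False)
        assert res.h == pytest.approx(brute_force_h(a, b))
        scipy_res = stats.kruskal(a, b)
        assert res.h == pytest.approx(scipy_res.statistic)
        assert res.p == pytest.approx(scipy_res.pvalue)

    def test_exact_agrees_with_asymptotic_decision(self):
        """Well-separated groups: both routes call it significant at 0.05;
        and the exact p equals full-enumeration frequency by construction."""
        a, b = [1.0, 2, 3, 4, 5], [11.0, 12, 13, 14, 15]
        exact = da.kruskal_wallis_test(a, b, exact=True)
        asym = da.kruskal_wallis_test(a, b, exact=False)
        assert exact.p < 0.05 and asym.p < 0.05
        assert exact.p == pytest.approx(2 / 252)  # only the 2 extreme splits


class TestLdaEffectSize:
    @staticmethod
    def _norm_table(rng, n=20, p=5):
        x = pd.DataFrame(rng.uniform(10, 100, (n, p)),
                         columns=[f"f{i}" for i in range(p)])
        return da.per_million(x)

    def test_identical_feature_scores_zero(self, rng):
        # f0 constant across every sample -> raw mean difference 0 and a
        # zero discriminant weight -> effect 0, clamped score 0
        rest = rng.uniform(10, 100, (20, 4))
        x = pd.DataFrame(np.column_stack([np.full(20, 2e5), rest]),
                         columns=[f"f{i}" for i in range(5)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=x.index)
        scores = da.lda_effect_size(x, groups)
        assert scores.effect["f0"] == pytest.approx(0.0, abs=1e-9)
        assert scores.score["f0"] == 0.0

    def test_single_feature_degenerates_to_mean_difference(self):
        x = pd.DataFrame({"f": [1e5] * 6 + [1e3] * 6})
        groups = pd.Series(["A"] * 6 + ["B"] * 6)
        scores = da.lda_effect_size(x, groups)
        assert scores.score["f"] == pytest.approx(np.log10(9.9e4), abs=1e-6)
        assert scores.side["f"] == "A"

    def test_depth_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 200, (16, 10)))
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=counts.index)
        s1 = da.lda_effect_size(da.per_million(counts), groups)
        s2 = da.lda_effect_size(da.per_million(counts * 2), groups)
        assert np.allclose(s1.score, s2.score)

    def test_effect_clamped_at_one(self):
        x = pd.DataFrame({"f1": [10.0, 10, 10, 10.001, 10, 10],
                          "f2": [5.0, 6, 7, 5, 6, 7]})
        groups = pd.Series(["A"] * 3 + ["B"] * 3)
        scores = da.lda_effect_size(x, groups)
        assert scores.score["f1"] == 0.0  # effect < 1 clamps to log10(1)

    def test_bootstrap_deterministic_under_seed(self, rng):
        counts = pd.DataFrame(rng.integers(0, 200, (18, 8)))
        groups = pd.Series(["A"] * 9 + ["B"] * 9, index=counts.index)
        x = da.per_million(counts)
        a = da.lda_effect_size(x, groups, bootstrap=30, seed=4)
        b = da.lda_effect_size(x, groups, bootstrap=30, seed=4)
        assert np.allclose(a.score, b.score)


class TestLefseScreen:
    def test_spiked_genus_recovered_with_side(self):
        spec = CommunitySimSpec(seed=11, spiked_taxa=((2, 3.0),))
        table, truth = simulate_asv_table(spec)
        eff = table_eff = da.lefse_screen(table, seed=0)
        genus = eff[eff["rank"] == "genus"].set_index("feature")
        spiked_genus = "Genus002"
        assert genus.loc[spiked_genus, "pass"]
        assert genus.loc[spiked_genus, "side"] == "HME"

    def test_null_table_mostly_empty(self):
        table, _ = simulate_asv_table(CommunitySimSpec(seed=21))
        eff = da.lefse_screen(table, seed=0)
        assert eff["pass"].sum() <= 2  # a single rank-level false call at most

    def test_q_at_least_p_and_monotone(self, tiny_table):
        table, _ = simulate_asv_table(CommunitySimSpec(seed=5, n_taxa=40))
        eff = da.lefse_screen(table, ranks=("genus",), seed=0)
        assert (eff["q"] >= eff["p"] - 1e-12).all()
        srt = eff.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_deterministic_byte_identical(self):
        table, _ = simulate_asv_table(CommunitySimSpec(seed=8))
        a = da.lefse_screen(table, seed=0)
        b = da.lefse_screen(table, seed=0)
        pd.testing.assert_frame_equal(a, b)

    def test_default_thresholds(self):
        import inspect

        sig = inspect.signature(da.lefse_screen)
        assert sig.parameters["lda_min"].default == 3.0
        assert sig.parameters["alpha"].default == 0.05


class TestSpearmanNetwork:
    @staticmethod
    def _table(values, groups=("LME", "LME", "LME", "HME", "HME", "HME")):
        counts = pd.DataFrame(values)
        return ASVTable(counts=counts,
                        groups=pd.Series(list(groups), index=counts.index))

    def test_monotone_pairs(self, rng):
        n = 12
        base = rng.integers(50, 100, (n, 10))
        base[:, 0] = np.arange(n) + 1
        base[:, 1] = (np.arange(n) + 1) * 3  # increasing with col 0
        base[:, 2] = (n - np.arange(n)) * 2  # decreasing
        t = ASVTable(counts=pd.DataFrame(base),
                     groups=pd.Series(["G"] * n))
        net = da.spearman_network(t, top_k=10)["G"]
        # relative-abundance transform of monotone raw counts need not stay
        # monotone, so test on the raw columns via the oracle below instead
        assert net.rho.shape == (10, 10)
        assert np.allclose(net.rho, net.rho.T, equal_nan=True)
        assert np.allclose(np.diag(net.rho), 1.0)

    def test_rho_matches_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 15).astype(float)
        y = rng.integers(0, 5, 15).astype(float)
        rho = stats.spearmanr(x, y).statistic
        mx, my = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(mx, my)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_top_k_selected_by_group_mean_abundance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 10, (8, 12)),
                              columns=[f"g{i}" for i in range(12)])
        counts.loc[:3, "g11"] = 5000  # dominant in LME only
        counts.loc[4:, "g11"] = 1  # and rarest in HME
        t = ASVTable(counts=counts,
                     groups=pd.Series(["LME"] * 4 + ["HME"] * 4, index=counts.index))
        nets = da.spearman_network(t, top_k=3)
        assert "g11" in nets["LME"].taxa
        assert "g11" not in nets["HME"].taxa

    def test_constant_taxon_gives_nan(self):
        counts = pd.DataFrame({
            "c": [7, 7, 7, 7, 7, 7],
            "u": [1, 2, 3, 4, 5, 6],
            "v": [2, 3, 1, 5, 4, 6],
        })
        # make 'c' constant in relative abundance too: equal row totals
        counts["pad"] = 20 - counts.sum(axis=1)
        t = self._table(counts)
        net = da.spearman_network(t, top_k=4)["LME"]
        assert np.isnan(net.rho.loc["c", "u"])
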