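"""Diversity, ordination and PERMANOVA unit tests, with scikit-bio as the
independent cross-check where it implements the same quantity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from ch4rumen import community as cm


def _dm_from_points(pts):
    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(len(pts))])


class TestFilterAndVenn:
    def test_low_count_filter(self, tiny_table):
        # totals: a1=7, a2=2, a3=6, a4=20, a5=3
        out = cm.filter_low_count_asvs(tiny_table, min_total=5)
        assert set(out.feature_ids) == {"a1", "a3", "a4"}
        assert out.sample_ids == tiny_table.sample_ids

    def test_filter_identity_when_all_pass(self, tiny_table):
        out = cm.filter_low_count_asvs(tiny_table, min_total=1)
        assert out.feature_ids == tiny_table.feature_ids

    def test_filter_all_dropped_errors(self, tiny_table):
        with pytest.raises(ValueError):
            cm.filter_low_count_asvs(tiny_table, min_total=10**6)

    def test_venn_partition_counts(self, tiny_table):
        # a1+a2 only in LME, a5 only in HME, a3+a4 shared
        v = cm.venn_partition(tiny_table)
        assert (v.unique_a, v.unique_b, v.shared) == (2, 1, 2)
        assert v.shared_percent == 40  # 2/5

    @pytest.mark.parametrize(
        "ua,ub,sh,expected", [(4814, 4243, 3451, 28), (2, 1, 3, 50), (5, 5, 0, 0)]
    )
    def test_shared_percent_arithmetic(self, ua, ub, sh, expected):
        assert cm.shared_percent(ua, ub, sh) == expected


class TestAlphaDiversity:
    def test_uniform_community(self):
        a = cm.alpha_diversity([25, 25, 25, 25])
        assert a.observed == 4
        assert a.simpson == pytest.approx(0.75)
        assert a.pielou == pytest.approx(1.0)

    def test_single_taxon(self):
        a = cm.alpha_diversity([10])
        assert (a.observed, a.simpson) == (1, 0.0)
        assert a.pielou is None

    def test_hand_formulas_123(self):
        a = cm.alpha_diversity([1, 2, 3])
        assert a.simpson == pytest.approx(1 - 14 / 36)
        assert a.chao1 == pytest.approx(3.0)  # F1=1 -> F1(F1-1) term vanishes

    def test_against_skbio(self, rng):
        counts = rng.integers(0, 50, size=30)
        counts[0] = 1  # ensure a singleton
        a = cm.alpha_diversity(counts)
        assert a.chao1 == pytest.approx(skbio_alpha.chao1(counts, bias_corrected=True))
        assert a.shannon == pytest.approx(skbio_alpha.shannon(counts, base=np.e))
        assert a.simpson == pytest.approx(skbio_alpha.simpson(counts))
        assert a.observed == skbio_alpha.sobs(counts)

    def test_scale_invariance_of_proportional_indices(self, rng):
        counts = rng.integers(1, 30, size=20)
        a, b = cm.alpha_diversity(counts), cm.alpha_diversity(counts * 10)
        assert a.simpson == pytest.approx(b.simpson)
        assert a.pielou == pytest.approx(b.pielou)

    def test_chao1_at_least_observed(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 6, size=40)
            if counts.sum() == 0:
                continue
            a = cm.alpha_diversity(counts)
            assert a.chao1 >= a.observed - 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            cm.alpha_diversity([0, 0, 0])


class TestRarefaction:
    def test_full_sample_gives_observed(self):
        counts = [5, 3, 2]
        assert cm.rarefaction_expected_richness(counts, 10) == pytest.approx(3.0)

    def test_single_draw(self):
        assert cm.rarefaction_expected_richness([5, 5], 1) == pytest.approx(1.0)

    def test_binomial_arithmetic(self):
        # 2 * (1 - C(5,2)/C(10,2)) = 14/9
        assert cm.rarefaction_expected_richness([5, 5], 2) == pytest.approx(14 / 9)

    def test_matches_monte_carlo(self, rng):
        counts = np.array([10, 5, 2, 1])
        n = 6
        pool = np.repeat(np.arange(4), counts)
        sims = [len(np.unique(rng.choice(pool, n, replace=False))) for _ in range(4000)]
        assert cm.rarefaction_expected_richness(counts, n) == pytest.approx(
            np.mean(sims), abs=0.05
        )

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            cm.rarefaction_expected_richness([2, 2], 5)


class TestBetaDiversity:
    def test_bray_curtis_worked_examples(self):
        t = cm.ASVTable(counts=pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [1, 1, 0], [2, 0, 0]],
            index=["a", "b", "c", "d"], columns=["x", "y", "z"]))
        dm = cm.bray_curtis(t)
        assert dm["a", "b"] == pytest.approx(0.5)  # 1 - 2*1/4
        assert dm["a", "c"] == pytest.approx(0.0)
        assert dm["b", "d"] == pytest.approx(1.0)  # disjoint

    def test_bray_curtis_range_and_symmetry(self, rng):
        t = cm.ASVTable(counts=pd.DataFrame(rng.integers(0, 100, (6, 15))))
        d = cm.bray_curtis(t).data
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)

    def test_unifrac_worked_example(self):
        t = cm.ASVTable(counts=pd.DataFrame(
            [[1, 0, 0], [0, 1, 0]], index=["s1", "s2"], columns=["A", "B", "C"]))
        dm = cm.unweighted_unifrac(t, "((A:1,B:1):1,C:2);")
        assert dm["s1", "s2"] == pytest.approx(2 / 3)

    def test_unifrac_identical_and_disjoint(self):
        t = cm.ASVTable(counts=pd.DataFrame(
            [[1, 1, 0], [2, 3, 0], [0, 0, 5]],
            index=["s1", "s2", "s3"], columns=["A", "B", "C"]))
        dm = cm.unweighted_unifrac(t, "((A:1,B:1):1,C:2);")
        assert dm["s1", "s2"] == pytest.approx(0.0)  # same presence set
        assert dm["s1", "s3"] == pytest.approx(1.0)  # disjoint subtrees

    def test_unifrac_missing_tips_listed(self):
        t = cm.ASVTable(counts=pd.DataFrame(
            [[1, 1]], index=["s1"], columns=["A", "Zmissing"]))
        with pytest.raises(ValueError, match="Zmissing"):
            cm.unweighted_unifrac(t, "((A:1,B:1):1,C:2);")


class TestPcoa:
    def test_planted_configuration_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        res = cm.pcoa(_dm_from_points(pts))
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy()[:, :2])
        assert disparity < 1e-8

    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [5, 0]])
        res = cm.pcoa(_dm_from_points(pts))
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_identical_points_all_zero_eigenvalues(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = cm.pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_fractions_non_increasing_and_bounded(self, rng):
        res = cm.pcoa(_dm_from_points(rng.normal(size=(10, 4))))
        frac = res.proportion_explained
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.max() <= 1.0 + 1e-12

    def test_matches_skbio_coordinates(self, rng):
        dm = _dm_from_points(rng.normal(size=(9, 3)))
        ours = cm.pcoa(dm).coordinates.to_numpy()[:, :3]
        theirs = skbio_pcoa(dm).samples.to_numpy()[:, :3]
        _, _, disparity = procrustes(theirs, ours)
        assert disparity < 1e-10

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cm.pcoa(DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"]))


class TestNmds:
    def test_embeddable_distances_near_zero_stress(self, rng):
        res = cm.nmds(_dm_from_points(rng.normal(size=(10, 2))), seed=0)
        assert res.stress < 0.01

    def test_simplex_into_plane_has_positive_stress(self):
        dm = DistanceMatrix(1 - np.eye(6), ids=list("abcdef"))
        res = cm.nmds(dm, seed=0)
        assert 0 < res.stress <= 1

    def test_deterministic_under_seed(self, rng):
        dm = _dm_from_points(rng.normal(size=(8, 3)))
        a, b = cm.nmds(dm, seed=3), cm.nmds(dm, seed=3)
        assert np.allclose(a.coordinates, b.coordinates)
        assert a.stress == b.stress


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = cm.permanova(dm, ["g1", "g1", "g2", "g2"], exact=True)
        assert res.r2 == pytest.approx(1.0)

    def test_exact_enumeration_3plus3(self, rng):
        dm = _dm_from_points(rng.normal(size=(6, 3)))
        res = cm.permanova(dm, list("AAABBB"), exact=True)
        assert res.n_perm == 20
        assert res.p in {k / 20 for k in range(1, 21)}

    def test_sampled_close_to_exact(self, rng):
        dm = _dm_from_points(np.r_[rng.normal(0, 1, (4, 2)), rng.normal(1.2, 1, (4, 2))])
        groups = list("AAAABBBB")
        exact = cm.permanova(dm, groups, exact=True)
        sampled = cm.permanova(dm, groups, n_perm=999, seed=0)
        assert abs(sampled.p - exact.p) <= 0.02

    def test_f_matches_skbio(self, rng):
        dm = _dm_from_points(rng.normal(size=(12, 4)))
        groups = ["A"] * 6 + ["B"] * 6
        ours = cm.permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=groups, permutations=99)
        assert ours.f == pytest.approx(theirs["test statistic"])

    def test_null_p_roughly_uniform(self, rng):
        """Shuffled labels on structureless distances: p should not pile up
        at small values."""
        dm = _dm_from_points(rng.normal(size=(10, 5)))
        ps = [cm.permanova(dm, list(rng.permutation(["A"] * 5 + ["B"] * 5)),
                           n_perm=99, seed=i).p for i in range(40)]
        assert np.mean(np.asarray(ps) <= 0.10) < 0.35

    def test_degenerate_all_zero(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = cm.permanova(dm, ["A", "A", "B", "B"])
        assert res.p == 1.0


class TestAggregateByRank:
    def test_phylum_sums(self, tiny_table):
        agg = cm.aggregate_by_rank(tiny_table, "phylum")
        assert agg.counts.loc["L2", "Firmicutes"] == 6  # a1 + a2
        assert agg.counts.loc["L2", "Bacteroidetes"] == 5  # a3 + a4

    def test_unassigned_pools_to_unclassified(self, tiny_table):
        agg = cm.aggregate_by_rank(tiny_table, "genus")
        # a4 (truncated lineage) and a5 (empty) both land in unclassified
        assert agg.counts.loc["H2", cm.UNCLASSIFIED] == 5 + 2

    def test_conserves_sample_totals(self, tiny_table):
        for rank in cm.RANKS:
            agg = cm.aggregate_by_rank(tiny_table, rank)
            assert (agg.counts.sum(axis=1) == tiny_table.counts.sum(axis=1)).all()


class TestLineageParsing:
    @pytest.mark.parametrize(
        "s,phylum,genus",
        [
            ("k__Bacteria; p__Firmicutes", "Firmicutes", cm.UNCLASSIFIED),
            ("k__Bacteria;p__;c__", cm.UNCLASSIFIED, cm.UNCLASSIFIED),
            ("", cm.UNCLASSIFIED, cm.UNCLASSIFIED),
            ("k__B; p__P; c__C; o__O; f__F; g__G", "P", "G"),
        ],
    )
    def test_parse(self, s, phylum, genus):
        out = cm.parse_lineage(s)
        assert out["phylum"] == phylum
        assert out["genus"] == genus

    def test_round_trip_canonical(self):
        s = "k__Bacteria; p__Firmicutes; c__Clostridia; o__; f__; g__Prevotella"
        assert cm.format_lineage(cm.parse_lineage(s)) == s
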