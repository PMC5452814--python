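"""Diversity metrics, ordination, and permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from conftest import anosim_exact_p, anosim_r_oracle, euclidean_dm
from seabiome import diversity as dv
from seabiome import synth
from seabiome._errors import DomainError
from seabiome.containers import OtuTable


class TestRarefy:
    def test_sum_and_support_constraints(self):
        table = OtuTable(["a", "b"], ["s1"], np.array([[10], [90]]))
        rarefied, dropped = dv.rarefy(table, 50, seed=1)
        assert dropped == []
        col = rarefied.counts[:, 0]
        assert col.sum() == 50 and col[0] <= 10

    def test_shallow_sample_dropped_and_listed(self):
        table = OtuTable(
            ["a", "b"], ["deep", "shallow"],
            np.array([[2000, 1200], [600, 1200]]),
        )
        rarefied, dropped = dv.rarefy(table, 2500, seed=1)
        assert dropped == ["shallow"]
        assert rarefied.sample_ids == ["deep"]

    def test_hypergeometric_expectation(self):
        table = OtuTable(["a", "b"], ["s"], np.array([[500], [500]]))
        means = [
            dv.rarefy(table, 100, seed=s)[0].counts[0, 0]
            for s in range(1000)
        ]
        assert np.mean(means) == pytest.approx(50.0, abs=1.0)

    def test_deterministic(self):
        table = OtuTable(
            ["a", "b", "c"], ["s1", "s2"],
            np.array([[40, 10], [30, 60], [30, 30]]),
        )
        a, _ = dv.rarefy(table, 50, seed=9)
        b, _ = dv.rarefy(table, 50, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5, 5, 5], 2.0), ([7, 0, 0], 0.0), ([75, 25], 0.811278)],
    )
    def test_known_values_bits(self, counts, expected):
        assert dv.shannon(counts) == pytest.approx(expected, abs=1e-6)

    def test_zero_sum_rejected(self):
        with pytest.raises(DomainError):
            dv.shannon([0, 0])

    def test_natural_log_base(self):
        assert dv.shannon([1, 1], base=np.e) == pytest.approx(np.log(2))


class TestFaithPD:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], 6.0),  # all branches
            ([1, 0, 0, 0], 2.0),  # path A -> root
            ([1, 1, 0, 0], 3.0),  # two tips + shared internal
        ],
    )
    def test_hand_computed(self, four_tip_tree, counts, expected):
        assert dv.faith_pd(counts, list("ABCD"), four_tip_tree) == pytest.approx(
            expected
        )

    def test_missing_taxon_rejected(self, four_tip_tree):
        with pytest.raises(DomainError, match="E"):
            dv.faith_pd([1, 0, 0, 0, 1], list("ABCDE"), four_tip_tree)


class TestCanberra:
    def test_identity(self):
        assert dv.canberra([3, 1, 4], [3, 1, 4]) == 0.0

    def test_hand_computed(self):
        assert dv.canberra([1, 0, 2], [0, 1, 2]) == pytest.approx(2.0)

    def test_double_zero_skipped(self):
        assert dv.canberra([0, 0], [0, 0]) == 0.0
        assert dv.canberra([1, 0], [1, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            dv.canberra([1, 2], [1, 2, 3])

    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=12),
        st.integers(0, 2 ** 31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 100, size=len(x))
        d_xy = dv.canberra(x, y)
        assert d_xy >= 0
        assert d_xy == pytest.approx(dv.canberra(y, x))
        assert dv.canberra(x, x) == 0.0


class TestUnifrac:
    def test_identical_presence(self, four_tip_tree):
        assert dv.unweighted_unifrac(
            [1, 1, 0, 0], [2, 5, 0, 0], list("ABCD"), four_tip_tree
        ) == pytest.approx(0.0)

    def test_disjoint_clades(self, four_tip_tree):
        assert dv.unweighted_unifrac(
            [1, 1, 0, 0], [0, 0, 1, 1], list("ABCD"), four_tip_tree
        ) == pytest.approx(1.0)

    def test_hand_computed_three_fifths(self, four_tip_tree):
        assert dv.unweighted_unifrac(
            [1, 1, 0, 0], [1, 0, 1, 0], list("ABCD"), four_tip_tree
        ) == pytest.approx(0.6)

    def test_bounded_on_random_communities(self):
        taxa = [f"x{i}" for i in range(12)]
        tree = synth.make_random_tree(taxa, seed=4)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 3, 12)
            y = rng.integers(0, 3, 12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            d = dv.unweighted_unifrac(x, y, taxa, tree)
            assert 0.0 <= d <= 1.0


class TestPcoa:
    def test_two_points_closed_form(self):
        dm = DistanceMatrix([[0, 2], [2, 0]], ["a", "b"])
        result = dv.pcoa(dm)
        assert result.coordinates.shape == (2, 1)
        assert sorted(result.coordinates.ravel()) == pytest.approx([-1, 1])

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.random((10, 4))
        dm = euclidean_dm(pts)
        result = dv.pcoa(dm)
        assert np.all(result.eigenvalues >= -1e-9)
        from scipy.spatial.distance import pdist, squareform

        recon = squareform(pdist(result.coordinates))
        assert np.allclose(recon, dm.data, atol=1e-6)

    def test_three_equidistant_points(self):
        dm = DistanceMatrix(1 - np.eye(3), ["a", "b", "c"])
        result = dv.pcoa(dm)
        pos = result.eigenvalues[result.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean: violates the triangle inequality
        data = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 3.5], [1, 1, 3.5, 0]]
        )
        result = dv.pcoa(DistanceMatrix(data, list("abcd")))
        assert result.eigenvalues.min() < 0


class TestAnosim:
    def test_maximal_separation_gives_r_one(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(9, 0.1, (4, 2))])
        dm = euclidean_dm(pts)
        res = dv.anosim(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_statistic_matches_rank_oracle(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.random((8, 3)))
        groups = ["a", "b"] * 4
        res = dv.anosim(dm, groups, n_perm=49, seed=0)
        assert res.statistic == pytest.approx(anosim_r_oracle(dm.data, groups))

    def test_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        dm = euclidean_dm(rng.random((6, 2)))
        groups = ["a", "a", "a", "b", "b", "b"]
        exact = anosim_exact_p(dm.data, groups)
        res = dv.anosim(dm, groups, n_perm=9999, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        dm = euclidean_dm(rng.random((10, 2)))
        groups = ["a"] * 5 + ["b"] * 5
        r1 = dv.anosim(dm, groups, n_perm=9, seed=0).statistic
        squared = DistanceMatrix(dm.data ** 2, dm.ids)
        r2 = dv.anosim(squared, groups, n_perm=9, seed=0).statistic
        assert r1 == pytest.approx(r2)

    def test_restricted_permutations_respect_strata(self):
        # stratum 2 has a single group: it must be held fixed (warn),
        # and the test must still run using stratum 1
        rng = np.random.default_rng(9)
        dm = euclidean_dm(rng.random((8, 2)))
        groups = ["a", "a", "b", "b", "a", "a", "a", "a"]
        strata = ["x"] * 4 + ["y"] * 4
        with pytest.warns(UserWarning, match="single group"):
            res = dv.anosim(dm, groups, strata=strata, n_perm=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_all_degenerate_strata_rejected(self):
        rng = np.random.default_rng(10)
        dm = euclidean_dm(rng.random((4, 2)))
        with pytest.raises(DomainError, match="admissible"):
            dv.anosim(
                dm, ["a", "a", "b", "b"], strata=["x", "x", "y", "y"],
                n_perm=9, seed=0,
            )

    def test_null_r_centered_at_zero(self):
        rng = np.random.default_rng(11)
        stats = []
        for rep in range(100):
            dm = euclidean_dm(rng.random((10, 2)))
            groups = list(rng.permutation(["a"] * 5 + ["b"] * 5))
            stats.append(dv.anosim(dm, groups, n_perm=9, seed=rep).statistic)
        assert abs(np.mean(stats)) < 0.05


class TestPermdisp:
    def test_equal_dispersion_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (6, 2))
        dm = euclidean_dm(np.vstack([base, base + 40]))
        res = dv.permdisp(dm, ["a"] * 6 + ["b"] * 6, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_inflated_copy_detected(self):
        rng = np.random.default_rng(2)
        tight = rng.normal(0, 1, (10, 2))
        dm = euclidean_dm(np.vstack([tight, tight * 5]))
        res = dv.permdisp(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0)
        assert res.p_value <= 0.01

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.random((5, 2)))
        with pytest.raises(DomainError, match="size 1"):
            dv.permdisp(dm, ["a", "a", "a", "a", "b"], n_perm=9, seed=0)


class TestCentroidProximity:
    @staticmethod
    def _bed_groups(table, meta):
        host, env = {}, {}
        for s in table.sample_ids:
            rec = meta[s]
            target = host if rec.community_type == "root" else env
            target.setdefault(rec.bed_id, []).append(s)
        return host, env

    def test_matched_centroids_beat_all_permutations(self):
        # hosts exactly on their own env centroid, beds far apart
        coords = np.array(
            [[0.0, 0], [0, 0], [10, 0], [10, 0], [0, 10], [0, 10]]
        )
        ordination = dv.OrdinationResult(
            sample_ids=[f"s{i}" for i in range(6)],
            coordinates=coords,
            eigenvalues=np.ones(2),
            proportion_explained=np.full(2, 0.5),
        )
        host = {"b1": ["s0"], "b2": ["s2"], "b3": ["s4"]}
        env = {"b1": ["s1"], "b2": ["s3"], "b3": ["s5"]}
        res = dv.centroid_proximity_test(ordination, host, env,
                                         n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_detects_shared_bed_effect(self):
        table, meta, _ = synth.make_bedded_communities(
            6, 150, 3, 2500, 0.8, seed=21
        )
        ordination = dv.pcoa(dv.canberra_matrix(table))
        host, env = self._bed_groups(table, meta)
        res = dv.centroid_proximity_test(ordination, host, env,
                                         n_perm=999, seed=0)
        assert res.p_value <= 0.05

    def test_null_p_not_concentrated(self):
        pvals = []
        for rep in range(20):
            table, meta, _ = synth.make_bedded_communities(
                5, 80, 2, 800, 0.0, seed=100 + rep
            )
            ordination = dv.pcoa(dv.canberra_matrix(table))
            host, env = self._bed_groups(table, meta)
            pvals.append(
                dv.centroid_proximity_test(
                    ordination, host, env, n_perm=199, seed=rep
                ).p_value
            )
        assert 0.2 <= np.mean(pvals) <= 0.8

    def test_fewer_than_two_beds_rejected(self):
        ordination = dv.OrdinationResult(
            ["s0", "s1"], np.zeros((2, 1)), np.ones(1), np.ones(1)
        )
        with pytest.raises(DomainError):
            dv.centroid_proximity_test(
                ordination, {"b": ["s0"]}, {"b": ["s1"]}, n_perm=9, seed=0
            )
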