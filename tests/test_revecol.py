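"""Seed sets, competition/cooccurrence matrices, and Mantel tests."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from conftest import brute_force_seeds, euclidean_dm, mantel_exact_p
from seabiome import revecol as re_
from seabiome import synth
from seabiome._errors import DomainError
from seabiome.containers import OtuTable, ReactionRecord


def _rec(rid, subs, prods, rev=False):
    return ReactionRecord(rid, frozenset(subs), frozenset(prods), rev)


class TestCompoundGraph:
    def test_substrates_cross_products(self):
        net = re_.build_compound_graph([_rec("R1", "AB", "C")], "x")
        assert net.edges == {("A", "C"), ("B", "C")}

    def test_reversible_adds_back_edges(self):
        net = re_.build_compound_graph([_rec("R1", "A", "B", rev=True)], "x")
        assert net.edges == {("A", "B"), ("B", "A")}

    def test_duplicate_reactions_idempotent(self):
        once = re_.build_compound_graph([_rec("R1", "A", "B")], "x")
        twice = re_.build_compound_graph(
            [_rec("R1", "A", "B"), _rec("R1b", "A", "B")], "x"
        )
        assert once.edges == twice.edges


class TestSeedSet:
    def test_chain(self):
        net = re_.build_compound_graph(
            [_rec("R1", "A", "B"), _rec("R2", "B", "C")], "x"
        )
        assert re_.seed_set(net).seeds == {"A": 1.0}

    def test_cycle_with_tail(self):
        net = re_.build_compound_graph(
            [_rec("R1", "A", "B", rev=True), _rec("R2", "B", "C")], "x"
        )
        assert re_.seed_set(net).seeds == {"A": 0.5, "B": 0.5}

    def test_two_disconnected_chains(self):
        net = re_.build_compound_graph(
            [_rec("R1", "A", "B"), _rec("R2", "C", "D")], "x"
        )
        assert re_.seed_set(net).seeds == {"A": 1.0, "C": 1.0}

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 25))
            density = rng.uniform(0.05, 0.3)
            nodes = [f"c{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(n)
                if i != j and rng.random() < density
            ]
            if not edges:
                continue
            records = [
                _rec(f"R{k}", [u], [v]) for k, (u, v) in enumerate(edges)
            ]
            net = re_.build_compound_graph(records, "x")
            ours = re_.seed_set(net)
            expected = brute_force_seeds(net.compounds, edges)
            assert ours.seeds == pytest.approx(expected)

    def test_confidence_sums_to_component_count(self):
        records, _, components = synth.make_toy_network(3, 8, 4, seed=5)
        ss = re_.seed_set(re_.build_compound_graph(records, "x"))
        assert sum(ss.seeds.values()) == pytest.approx(len(components))

    def test_generated_truth_recovered(self):
        for seed in range(20):
            records, truth, _ = synth.make_toy_network(3, 10, 3, seed=seed)
            ss = re_.seed_set(re_.build_compound_graph(records, "x"))
            assert ss.seeds == pytest.approx(truth)


class TestSeedJaccard:
    @staticmethod
    def _ss(otu, compounds):
        return re_.SeedSet(otu, {c: 1.0 for c in compounds}, [[c] for c in compounds])

    def test_identical(self):
        assert re_.seed_jaccard(self._ss("a", "AB"), self._ss("b", "AB")) == 0.0

    def test_disjoint(self):
        assert re_.seed_jaccard(self._ss("a", "AB"), self._ss("b", "CD")) == 1.0

    def test_partial_overlap(self):
        d = re_.seed_jaccard(self._ss("a", "AB"), self._ss("b", "BC"))
        assert d == pytest.approx(2 / 3)

    def test_both_empty(self):
        empty = re_.SeedSet("e", {}, [])
        assert re_.seed_jaccard(empty, empty) == 0.0

    def test_competition_matrix_consistency(self):
        sets = [self._ss(f"o{i}", s) for i, s in enumerate(["AB", "BC", "DE"])]
        comp = re_.competition_matrix(sets)
        for i in range(3):
            for j in range(3):
                assert comp.data[i, j] == pytest.approx(
                    re_.seed_jaccard(sets[i], sets[j])
                )


class TestCooccurrence:
    def test_hand_computed(self):
        counts = np.array([[1, 1, 0], [0, 1, 1], [1, 1, 0]])
        table = OtuTable(["o1", "o2", "o3"], ["s1", "s2", "s3"], counts)
        dm = re_.cooccurrence_matrix(table)
        assert dm["o1", "o2"] == pytest.approx(2 / 3)
        assert dm["o1", "o3"] == pytest.approx(0.0)

    def test_complementary_profiles(self):
        counts = np.array([[1, 0], [0, 1]])
        dm = re_.cooccurrence_matrix(OtuTable(["a", "b"], ["s1", "s2"], counts))
        assert dm["a", "b"] == pytest.approx(1.0)

    def test_absent_pair_warns_and_zero(self):
        counts = np.array([[0, 0], [0, 0], [1, 1]])
        table = OtuTable(["a", "b", "c"], ["s1", "s2"], counts)
        with pytest.warns(UserWarning, match="absent"):
            dm = re_.cooccurrence_matrix(table)
        assert dm["a", "b"] == 0.0


class TestPhyloDistances:
    def test_cherry(self):
        from seabiome import io

        tree = io.parse_newick("(A:1,B:1);")
        dm = re_.phylo_distance_matrix(tree, ["A", "B"])
        assert dm["A", "B"] == pytest.approx(2.0)

    def test_three_taxa(self):
        from seabiome import io

        tree = io.parse_newick("((A:1,B:1):1,C:2);")
        dm = re_.phylo_distance_matrix(tree, ["A", "C"])
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["A", "A"] == 0.0

    def test_missing_tip_rejected(self, four_tip_tree):
        with pytest.raises(DomainError, match="missing"):
            re_.phylo_distance_matrix(four_tip_tree, ["A", "Z"])


class TestMantel:
    def test_identity_gives_r_one_minimal_p(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.random((8, 2)))
        res = re_.mantel(dm, dm, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        d1 = euclidean_dm(rng.random((4, 2)))
        d2 = euclidean_dm(rng.random((4, 2)), ids=list(d1.ids))
        exact = mantel_exact_p(d1.data, d2.data)
        res = re_.mantel(d1, d2, n_perm=9999, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        d1 = euclidean_dm(rng.random((7, 2)))
        d2 = euclidean_dm(rng.random((7, 2)), ids=list(d1.ids))
        r1 = re_.mantel(d1, d2, n_perm=9, seed=0).r
        perm = rng.permutation(7)
        ids = [d1.ids[i] for i in perm]
        d1p = DistanceMatrix(d1.data[np.ix_(perm, perm)], ids)
        d2p = DistanceMatrix(d2.data[np.ix_(perm, perm)], ids)
        assert re_.mantel(d1p, d2p, n_perm=9, seed=0).r == pytest.approx(r1)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(5)
        d1 = euclidean_dm(rng.random((10, 3)))
        d2 = euclidean_dm(rng.random((10, 3)), ids=list(d1.ids))
        ours = re_.mantel(d1, d2, n_perm=99, seed=0)
        ref_r, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert ours.r == pytest.approx(ref_r, abs=1e-9)

    def test_zero_variance_rejected(self):
        dm = DistanceMatrix(1 - np.eye(5), [f"s{i}" for i in range(5)])
        rng = np.random.default_rng(6)
        d2 = euclidean_dm(rng.random((5, 2)), ids=list(dm.ids))
        with pytest.raises(DomainError, match="variance"):
            re_.mantel(dm, d2, n_perm=9, seed=0)


class TestPartialMantel:
    def test_uncorrelated_control_changes_little(self):
        rng = np.random.default_rng(7)
        pts = rng.random((12, 2))
        d1 = euclidean_dm(pts)
        d2 = euclidean_dm(pts + rng.normal(0, 0.05, pts.shape),
                          ids=list(d1.ids))
        d3 = euclidean_dm(rng.random((12, 2)), ids=list(d1.ids))
        raw = re_.mantel(d1, d2, n_perm=99, seed=0)
        partial = re_.partial_mantel(d1, d2, d3, n_perm=99, seed=0)
        assert partial.r == pytest.approx(raw.r, abs=0.15)

    def test_control_equal_to_d2_degenerate(self):
        rng = np.random.default_rng(8)
        d1 = euclidean_dm(rng.random((8, 2)))
        d2 = euclidean_dm(rng.random((8, 2)), ids=list(d1.ids))
        with pytest.raises(DomainError, match="degenerate"):
            re_.partial_mantel(d1, d2, d2, n_perm=9, seed=0)

    def test_shared_driver_removed_by_control(self):
        # d1 and d2 both linear in d3 plus independent noise:
        # raw r12 > 0 but r12.3 ~ 0
        rng = np.random.default_rng(9)
        n = 20
        ids = [f"s{i}" for i in range(n)]
        base = euclidean_dm(rng.random((n, 2)), ids=ids)

        def noisy(scale):
            noise = rng.random((n, n)) * scale
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            return DistanceMatrix(base.data + noise, ids)

        d1, d2 = noisy(0.15), noisy(0.15)
        raw = re_.mantel(d1, d2, n_perm=199, seed=0)
        partial = re_.partial_mantel(d1, d2, base, n_perm=199, seed=0)
        assert raw.r > 0.5
        assert abs(partial.r) < 0.35


class TestHabitatFilteringContrast:
    def test_structured_scenario_detected_random_not(self):
        hits_structured = 0
        hits_random = 0
        reps = 20
        for rep in range(reps):
            for structured in (True, False):
                table, seed_map = synth.make_resource_pool_scenario(
                    24, 4, 40, 6, structured, seed=1000 + rep
                )
                sets = [
                    re_.SeedSet(o, {c: 1.0 for c in cs}, [sorted(cs)])
                    for o, cs in seed_map.items()
                ]
                comp = re_.competition_matrix(sets)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cooc = re_.cooccurrence_matrix(table)
                res = re_.mantel(cooc, comp, n_perm=199, seed=rep)
                if res.p_value <= 0.05:
                    if structured:
                        hits_structured += 1
                    else:
                        hits_random += 1
        assert hits_structured >= 0.85 * reps
        assert hits_random <= 0.25 * reps
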