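"""Shared fixtures and independent oracles used across the test suite."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from seabiome import io
from seabiome.containers import OtuTable


@pytest.fixture
def four_tip_tree():
    """Balanced 4-tip tree with unit branch lengths."""
    return io.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(6, 4))
    return OtuTable(
        [f"t{i}" for i in range(6)], [f"s{j}" for j in range(4)], counts
    )


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_seeds(nodes, edges):
    """Seed set by full reachability: a compound is a seed iff nothing
    outside its own SCC reaches it.  Confidence = 1 / |SCC|."""
    nodes = list(nodes)
    reach = {u: {u} for u in nodes}
    changed = True
    adjacency = {u: set() for u in nodes}
    for u, v in edges:
        adjacency[u].add(v)
    while changed:
        changed = False
        for u in nodes:
            new = set(reach[u])
            for v in adjacency[u]:
                new |= reach[v]
            if new != reach[u]:
                reach[u] = new
                changed = True
    scc_of = {}
    for u in nodes:
        scc_of[u] = frozenset(
            v for v in nodes if u in reach[v] and v in reach[u]
        )
    seeds = {}
    for u in nodes:
        outside_reachers = [
            v for v in nodes if u in reach[v] and v not in scc_of[u]
        ]
        if not outside_reachers:
            seeds[u] = 1.0 / len(scc_of[u])
    return seeds


def anosim_r_oracle(dm_data, labels):
    """Clarke's R computed directly from average ranks of all distances."""
    n = len(labels)
    condensed = squareform(np.asarray(dm_data), checks=False)
    ranks = rankdata(condensed)
    iu = np.triu_indices(n, k=1)
    within = np.asarray(labels)[iu[0]] == np.asarray(labels)[iu[1]]
    m = n * (n - 1) // 2
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)


def anosim_exact_p(dm_data, labels):
    """Exact one-sided p over all distinct label assignments."""
    labels = list(labels)
    observed = anosim_r_oracle(dm_data, labels)
    assignments = set(itertools.permutations(labels))
    hits = sum(
        anosim_r_oracle(dm_data, list(a)) >= observed - 1e-12
        for a in assignments
    )
    return hits / len(assignments)


def mantel_exact_p(d1, d2):
    """Exact one-sided Mantel p over all relabelings of d2."""
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = d1[iu]

    def corr(perm):
        v2 = d2[np.ix_(perm, perm)][iu]
        return np.corrcoef(v1, v2)[0, 1]

    observed = corr(tuple(range(n)))
    perms = list(itertools.permutations(range(n)))
    hits = sum(corr(p) >= observed - 1e-12 for p in perms)
    return hits / len(perms)
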