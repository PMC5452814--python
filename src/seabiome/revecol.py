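"""Reverse-ecology: seed sets, competition, cooccurrence, Mantel tests.

An organism's metabolic network is a directed compound graph (reactants ->
products).  Its seed set — the minimal set of compounds it must acquire
exogenously to synthesize everything else — equals the union of the source
components (in-degree zero nodes) of the graph's strongly-connected-
component condensation; each compound in a source component of size s gets
confidence 1/s.  Pairwise Jaccard distances between seed sets form the
competitive dissimilarity matrix C: small entries mean high predicted
resource overlap.  Habitat filtering predicts a positive association
between C and cooccurrence dissimilarity, assessed by (partial) Mantel
tests with matrix permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode

from ._errors import DomainError
from .containers import OtuTable, ReactionRecord


# ---------------------------------------------------------------------------
# Compound graphs and seed sets
# ---------------------------------------------------------------------------

@dataclass
class MetabolicNetwork:
    """Directed compound graph for one organism."""

    otu_id: str
    graph: nx.DiGraph
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def compounds(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


@dataclass
class SeedSet:
    """Seed compounds with confidences and their source-SCC memberships."""

    otu_id: str
    seeds: dict[str, float]
    components: list[list[str]]

    def compound_set(self) -> frozenset[str]:
        return frozenset(self.seeds)


def build_compound_graph(
    reactions: list[ReactionRecord], otu_id: str
) -> MetabolicNetwork:
    """Edges (s, p) for every substrate s and product p of each reaction;
    reversible reactions also contribute (p, s).  Set semantics: duplicate
    reactions are idempotent."""
    if not reactions:
        raise DomainError(f"{otu_id!r}: empty reaction list")
    graph = nx.DiGraph()
    provenance: dict[tuple[str, str], set[str]] = {}
    for rec in reactions:
        graph.add_nodes_from(rec.substrates | rec.products)
        pairs = [(s, p) for s in rec.substrates for p in rec.products]
        if rec.reversible:
            pairs += [(p, s) for s in rec.substrates for p in rec.products]
        for u, v in pairs:
            if u == v:
                continue
            graph.add_edge(u, v)
            provenance.setdefault((u, v), set()).add(rec.reaction_id)
    return MetabolicNetwork(otu_id, graph, provenance)


def seed_set(net: MetabolicNetwork) -> SeedSet:
    """Seed set via SCC condensation.

    Source components are condensation nodes with in-degree 0; every
    compound in a source component of size s is a seed with confidence 1/s.
    """
    if net.graph.number_of_nodes() == 0:
        return SeedSet(net.otu_id, {}, [])
    condensation = nx.condensation(net.graph)
    components: list[list[str]] = []
    seeds: dict[str, float] = {}
    for node, in_deg in condensation.in_degree():
        if in_deg == 0:
            members = sorted(condensation.nodes[node]["members"])
            components.append(members)
            conf = 1.0 / len(members)
            for compound in members:
                seeds[compound] = conf
    return SeedSet(net.otu_id, seeds, components)


# ---------------------------------------------------------------------------
# Dissimilarity matrices
# ---------------------------------------------------------------------------

def seed_jaccard(a: SeedSet, b: SeedSet, weighted: bool = False) -> float:
    """Jaccard distance between two seed sets.

    Binary over compound identity by default; ``weighted=True`` uses the
    generalized (min/max over confidences) form.  Two empty sets are at
    distance 0.
    """
    if not weighted:
        sa, sb = a.compound_set(), b.compound_set()
        union = sa | sb
        if not union:
            return 0.0
        return 1.0 - len(sa & sb) / len(union)
    compounds = set(a.seeds) | set(b.seeds)
    if not compounds:
        return 0.0
    mins = sum(min(a.seeds.get(c, 0.0), b.seeds.get(c, 0.0)) for c in compounds)
    maxs = sum(max(a.seeds.get(c, 0.0), b.seeds.get(c, 0.0)) for c in compounds)
    return 1.0 - mins / maxs


def competition_matrix(
    seed_sets: list[SeedSet], weighted: bool = False
) -> DistanceMatrix:
    """Competitive dissimilarity matrix C of pairwise seed-set Jaccard
    distances; low c_ij means OTUs i and j compete for similar resources."""
    ids = [s.otu_id for s in seed_sets]
    if len(set(ids)) != len(ids):
        raise DomainError("duplicate otu_id among seed sets")
    if len(ids) < 2:
        raise DomainError("need >= 2 OTUs")
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = seed_jaccard(seed_sets[i], seed_sets[j], weighted=weighted)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids)


def cooccurrence_matrix(
    table: OtuTable, quantitative: bool = False
) -> DistanceMatrix:
    """Pairwise Jaccard distances between OTU occurrence profiles.

    Profiles are presence/absence across samples (binarized after upstream
    rarefaction); ``quantitative=True`` uses the Ruzicka (weighted Jaccard)
    form on counts.  A pair of everywhere-absent OTUs gets distance 0 with
    a warning.
    """
    x = table.counts.astype(float)
    if not quantitative:
        x = (x > 0).astype(float)
    n = x.shape[0]
    if n < 2:
        raise DomainError("need >= 2 OTUs")
    mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    maxs = np.maximum(x[:, None, :], x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        data = 1.0 - mins / maxs
    empty_pairs = maxs == 0
    if empty_pairs.any():
        warnings.warn(
            "OTU pair(s) absent from every sample; their distance is set to 0",
            stacklevel=2,
        )
        data[empty_pairs] = 0.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix((data + data.T) / 2.0, table.taxon_ids)


def phylo_distance_matrix(
    tree: TreeNode, otu_ids: list[str]
) -> DistanceMatrix:
    """Patristic (path branch-length) distances between the given tips."""
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise DomainError(f"taxa missing from tree: {missing}")
    full = tree.tip_tip_distances()
    return full.filter(otu_ids)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str
    controlled: str | None = None

    def __post_init__(self):
        if not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise DomainError(f"correlation {self.r} outside [-1, 1]")


def _triangle(dm: DistanceMatrix) -> np.ndarray:
    data = np.asarray(dm.data)
    iu = np.triu_indices(data.shape[0], k=1)
    return data[iu]


def _corr(u: np.ndarray, v: np.ndarray, method: str) -> float:
    if method == "spearman":
        from scipy.stats import rankdata

        u, v = rankdata(u), rankdata(v)
    elif method != "pearson":
        raise DomainError(f"unknown method {method!r}")
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        raise DomainError("zero-variance distance triangle: r undefined")
    return float(np.corrcoef(u, v)[0, 1])


def _align(d1: DistanceMatrix, d2: DistanceMatrix) -> DistanceMatrix:
    if set(d1.ids) != set(d2.ids):
        raise DomainError("distance matrices have different label sets")
    return d2.filter(d1.ids) if tuple(d1.ids) != tuple(d2.ids) else d2


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix association by row/column permutation of d2.

    One-sided by default (positive association, the habitat-filtering
    expectation); ``alternative`` may be "greater" or "two-sided".
    """
    d2 = _align(d1, d2)
    n = len(d1.ids)
    if n < 4:
        raise DomainError("Mantel test needs n >= 4")
    v1 = _triangle(d1)
    m2 = np.asarray(d2.data)
    r_obs = _corr(v1, _triangle(d2), method)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = m2[np.ix_(perm, perm)][iu]
        r_perm = _corr(v1, v2p, method)
        if alternative == "greater":
            exceed += r_perm >= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, method)


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d3: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel: association of d1 and d2 controlling for d3.

    r12.3 = (r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2)); the null
    permutes d2's labels and recomputes r12.3 each draw.
    """
    d2 = _align(d1, d2)
    d3 = _align(d1, d3)
    n = len(d1.ids)
    if n < 4:
        raise DomainError("partial Mantel test needs n >= 4")
    v1, v3 = _triangle(d1), _triangle(d3)
    m2 = np.asarray(d2.data)
    iu = np.triu_indices(n, k=1)

    r13 = _corr(v1, v3, method)

    def partial_r(v2):
        r12 = _corr(v1, v2, method)
        r23 = _corr(v2, v3, method)
        denom_sq = (1.0 - r13 ** 2) * (1.0 - r23 ** 2)
        if denom_sq <= 1e-12:
            raise DomainError(
                "degenerate partial correlation: |r13| or |r23| = 1"
            )
        return (r12 - r13 * r23) / np.sqrt(denom_sq)

    r_obs = partial_r(m2[iu])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = partial_r(m2[np.ix_(perm, perm)][iu])
        if alternative == "greater":
            exceed += r_perm >= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(float(r_obs), float(p), n_perm, method,
                        controlled="d3")
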