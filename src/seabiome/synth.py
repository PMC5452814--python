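"""Synthetic community, tree, and metabolic-network generators.

Every generator is deterministic under its seed and records the ground truth
needed to score the downstream stage it feeds: mixing proportions for source
tracking, spiked fold changes for differential abundance, bed perturbations
for the centroid-proximity test, and exact seed sets for the reverse-ecology
stage.  The defaults mirror the study conditions the pipeline targets: a
rarefaction depth of 2,500 sequences, tens of samples per community type,
and negative-binomial count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DomainError
from .containers import OtuTable, ReactionRecord, SampleMetadata, SampleRecord


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    mixing_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    spiked_taxa: dict[str, float] = field(default_factory=dict)
    true_seed_sets: dict[str, set[str]] = field(default_factory=dict)
    bed_effect_sd: float = 0.0


def make_source_profiles(
    n_sources: int, n_taxa: int, concentration: float, seed: int
) -> np.ndarray:
    """Draw source relative-abundance profiles from a symmetric Dirichlet.

    Returns an ``(n_sources, n_taxa)`` matrix; each row sums to 1.  Large
    ``concentration`` gives near-uniform profiles, small values give sparse,
    well-separated ones.
    """
    if concentration <= 0:
        raise DomainError("concentration must be positive")
    if n_sources < 1 or n_taxa < 2:
        raise DomainError("need n_sources >= 1 and n_taxa >= 2")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_taxa, concentration), size=n_sources)


def make_mixed_sinks(
    sources: np.ndarray,
    mixing: np.ndarray,
    unknown_profile: np.ndarray | None,
    depth: int,
    n_sinks: int,
    seed: int,
    source_names: list[str] | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Sample sink communities as multinomial draws from mixed source profiles.

    ``mixing`` has one entry per known source plus a trailing "unknown"
    entry; it may be a single vector (shared by all sinks) or one row per
    sink.  Each sink column is a multinomial of size ``depth`` from
    ``sum_k mixing_k * profile_k``.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    k, n_taxa = sources.shape
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim == 1:
        mixing = np.tile(mixing, (n_sinks, 1))
    if mixing.shape != (n_sinks, k + 1):
        raise DomainError(
            f"mixing shape {mixing.shape} does not match "
            f"{n_sinks} sinks x {k} sources + unknown"
        )
    if not np.allclose(mixing.sum(axis=1), 1.0):
        raise DomainError("mixing rows must sum to 1")
    if depth < 1:
        raise DomainError("depth must be >= 1")
    if unknown_profile is None:
        unknown_profile = np.zeros(n_taxa)
        if np.any(mixing[:, -1] > 0):
            raise DomainError("nonzero unknown mixing requires unknown_profile")
    unknown_profile = np.asarray(unknown_profile, dtype=float)
    if unknown_profile.shape != (n_taxa,):
        raise DomainError("unknown_profile length must match taxon count")

    all_profiles = np.vstack([sources, unknown_profile])
    rng = np.random.default_rng(seed)
    counts = np.empty((n_taxa, n_sinks), dtype=np.int64)
    for j in range(n_sinks):
        mixed = mixing[j] @ all_profiles
        mixed = mixed / mixed.sum()
        counts[:, j] = rng.multinomial(depth, mixed)

    taxa = [f"OTU_{i:05d}" for i in range(n_taxa)]
    sinks = [f"sink_{j:03d}" for j in range(n_sinks)]
    names = list(source_names) if source_names else [
        f"source_{i}" for i in range(k)
    ]
    truth = SyntheticTruth(
        mixing_proportions={
            sinks[j]: {
                **{names[i]: float(mixing[j, i]) for i in range(k)},
                "unknown": float(mixing[j, -1]),
            }
            for j in range(n_sinks)
        }
    )
    return OtuTable(taxa, sinks, counts), truth


def make_unknown_profile(
    n_taxa: int, n_reserved: int, concentration: float, seed: int
) -> np.ndarray:
    """Dirichlet profile supported on the last ``n_reserved`` taxa only.

    Reserving a disjoint taxon block makes the unknown component
    identifiable in recovery tests.
    """
    if not 0 < n_reserved <= n_taxa:
        raise DomainError("need 0 < n_reserved <= n_taxa")
    rng = np.random.default_rng(seed)
    profile = np.zeros(n_taxa)
    profile[n_taxa - n_reserved:] = rng.dirichlet(
        np.full(n_reserved, concentration)
    )
    return profile


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float):
    """Negative binomial with mean mu, variance mu + dispersion * mu^2."""
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def spike_differential_taxa(
    base_profile: np.ndarray,
    spiked: dict[str, float],
    n_host: int,
    n_env: int,
    depth: int,
    dispersion: float,
    seed: int,
    taxon_ids: list[str] | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Generate host and environment count columns with known fold changes.

    Environment columns have expected taxon counts ``depth * base``; host
    columns multiply spiked taxa by ``2**log2FC``.  Counts are
    negative-binomial with the given overdispersion (0 gives Poisson).
    Sample ids are ``host_*`` and ``env_*``.
    """
    base_profile = np.asarray(base_profile, dtype=float)
    n_taxa = base_profile.size
    if taxon_ids is None:
        taxon_ids = [f"OTU_{i:05d}" for i in range(n_taxa)]
    if dispersion < 0:
        raise DomainError("dispersion must be >= 0")
    unknown = set(spiked) - set(taxon_ids)
    if unknown:
        raise DomainError(f"spiked taxa not in table: {sorted(unknown)}")

    fold = np.ones(n_taxa)
    for taxon, lfc in spiked.items():
        if not np.isfinite(lfc):
            raise DomainError(f"non-finite log2FC for {taxon!r}")
        fold[taxon_ids.index(taxon)] = 2.0 ** lfc

    rng = np.random.default_rng(seed)
    mu_env = depth * base_profile
    mu_host = mu_env * fold
    host = np.column_stack(
        [_nb_sample(rng, mu_host, dispersion) for _ in range(n_host)]
    )
    env = np.column_stack(
        [_nb_sample(rng, mu_env, dispersion) for _ in range(n_env)]
    )
    counts = np.hstack([host, env]).astype(np.int64)
    samples = [f"host_{j:03d}" for j in range(n_host)] + [
        f"env_{j:03d}" for j in range(n_env)
    ]
    truth = SyntheticTruth(spiked_taxa={t: float(v) for t, v in spiked.items()})
    return OtuTable(taxon_ids, samples, counts), truth


def make_random_tree(taxon_ids: list[str], seed: int, scale: float = 1.0):
    """Random rooted binary tree by coalescent-style joins.

    Branch lengths are exponential with the given mean.  Deterministic under
    the seed; returns a :class:`skbio.TreeNode`.
    """
    from .io import parse_newick

    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise DomainError("need at least 2 taxa")
    if len(set(taxon_ids)) != len(taxon_ids):
        raise DomainError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    nodes = [f"{_quote(t)}:{rng.exponential(scale):.6f}" for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({left},{right})")
        else:
            nodes.append(
                f"({left},{right}):{rng.exponential(scale):.6f}"
            )
    return parse_newick(nodes[0] + ";")


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def make_toy_network(
    n_seed_components: int,
    n_downstream: int,
    max_scc_size: int,
    seed: int,
) -> tuple[list[ReactionRecord], dict[str, float], list[list[str]]]:
    """Build a compound graph whose seed set is known by construction.

    The graph's condensation has exactly ``n_seed_components`` source
    components (explicit cycles of size <= ``max_scc_size``) and
    ``n_downstream`` non-source compounds, each reachable from at least one
    source component.  Returns reaction records, the true seed-confidence
    map, and the source component membership lists.
    """
    if min(n_seed_components, n_downstream, max_scc_size) < 1:
        raise DomainError("all generator sizes must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[ReactionRecord] = []
    components: list[list[str]] = []
    ridx = 0

    def add_edge(u: str, v: str):
        nonlocal ridx
        records.append(
            ReactionRecord(f"R{ridx:04d}", frozenset({u}), frozenset({v}), False)
        )
        ridx += 1

    for c in range(n_seed_components):
        size = int(rng.integers(1, max_scc_size + 1))
        members = [f"S{c}_{m}" for m in range(size)]
        components.append(members)
        for m in range(size):  # cycle makes the component strongly connected
            if size > 1:
                add_edge(members[m], members[(m + 1) % size])

    downstream = [f"D{i}" for i in range(n_downstream)]
    for i, comp in enumerate(downstream):
        # parent: either a seed component member or an earlier downstream node
        if i == 0 or rng.random() < 0.5:
            parent_comp = components[int(rng.integers(n_seed_components))]
            parent = parent_comp[int(rng.integers(len(parent_comp)))]
        else:
            parent = downstream[int(rng.integers(i))]
        add_edge(parent, comp)

    # singleton source components need their compound mentioned somewhere;
    # give each an outgoing edge to a random downstream node
    for members in components:
        if len(members) == 1:
            target = downstream[int(rng.integers(n_downstream))]
            add_edge(members[0], target)

    truth = {
        m: 1.0 / len(members) for members in components for m in members
    }
    return records, truth, components


def make_bedded_communities(
    n_beds: int,
    n_taxa: int,
    n_reps: int,
    depth: int,
    bed_effect_sd: float,
    seed: int,
    concentration: float = 1.0,
    site_ids: list[str] | None = None,
    host_type: str = "root",
    env_type: str = "sediment",
    env_fraction: float = 0.6,
) -> tuple[OtuTable, SampleMetadata, SyntheticTruth]:
    """Paired host and environment samples sharing a per-bed perturbation.

    The host profile is a mixture of the environment profile
    (``env_fraction``) and a host-specific component, emulating colonization
    from the adjacent environment plus host selection.  Both profiles are
    multiplied by the same lognormal per-bed perturbation (sigma =
    ``bed_effect_sd``) before multinomial sampling, so host communities are
    compositionally closest to the environment of their own bed — the
    true-positive case for the centroid-proximity test.
    ``bed_effect_sd = 0`` gives the exchangeable null.
    """
    if n_beds < 2:
        raise DomainError("need >= 2 beds")
    if bed_effect_sd < 0:
        raise DomainError("bed_effect_sd must be >= 0")
    if not 0.0 <= env_fraction <= 1.0:
        raise DomainError("env_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base_env = rng.dirichlet(np.full(n_taxa, concentration))
    host_specific = rng.dirichlet(np.full(n_taxa, concentration))
    base_host = env_fraction * base_env + (1.0 - env_fraction) * host_specific

    taxa = [f"OTU_{i:05d}" for i in range(n_taxa)]
    columns, sample_ids, records = [], [], []
    for b in range(n_beds):
        bed = f"bed_{b:02d}"
        site = site_ids[b] if site_ids else f"site_{b // 2:02d}"
        pert = np.exp(rng.normal(0.0, bed_effect_sd, size=n_taxa))
        for kind, base in ((host_type, base_host), (env_type, base_env)):
            profile = base * pert
            profile = profile / profile.sum()
            for r in range(n_reps):
                sid = f"{kind}_{bed}_{r}"
                columns.append(rng.multinomial(depth, profile))
                sample_ids.append(sid)
                records.append(SampleRecord(sid, kind, bed, site))
    table = OtuTable(taxa, sample_ids, np.column_stack(columns))
    truth = SyntheticTruth(bed_effect_sd=bed_effect_sd)
    return table, SampleMetadata(records), truth


def make_resource_pool_scenario(
    n_otus: int,
    n_pools: int,
    n_samples: int,
    n_compounds_per_pool: int,
    structured: bool,
    seed: int,
    presence_prob: float = 0.45,
    noise: float = 0.1,
) -> tuple[OtuTable, dict[str, set[str]]]:
    """Cooccurrence/seed-set scenario for the habitat-filtering contrast.

    ``structured=True`` emulates a community filtered by shared resources:
    OTUs are grouped into resource pools, draw their seed compounds from
    their pool, and occur in a sample when that sample supplies their pool
    (plus occupancy noise).  ``structured=False`` draws seed sets and
    occurrences independently at random — no association between resource
    overlap and cooccurrence.
    """
    if n_otus < 4 or n_pools < 2:
        raise DomainError("need n_otus >= 4 and n_pools >= 2")
    rng = np.random.default_rng(seed)
    otus = [f"OTU_{i:05d}" for i in range(n_otus)]
    pool_of = rng.integers(n_pools, size=n_otus)
    compounds = [
        [f"P{p}_C{c}" for c in range(n_compounds_per_pool)]
        for p in range(n_pools)
    ]
    shared = [f"X_C{c}" for c in range(n_compounds_per_pool)]

    seed_sets: dict[str, set[str]] = {}
    presence = np.zeros((n_otus, n_samples), dtype=np.int64)
    if structured:
        pool_active = rng.random((n_pools, n_samples)) < presence_prob
        for i, otu in enumerate(otus):
            p = pool_of[i]
            k = rng.integers(2, n_compounds_per_pool + 1)
            seed_sets[otu] = set(
                rng.choice(compounds[p], size=k, replace=False)
            )
            occ = pool_active[p].copy()
            flip = rng.random(n_samples) < noise
            occ[flip] = ~occ[flip]
            presence[i] = occ.astype(np.int64)
    else:
        universe = shared + [c for pool in compounds for c in pool]
        for i, otu in enumerate(otus):
            k = rng.integers(2, n_compounds_per_pool + 1)
            seed_sets[otu] = set(rng.choice(universe, size=k, replace=False))
            presence[i] = (rng.random(n_samples) < presence_prob).astype(
                np.int64
            )
    samples = [f"sample_{j:03d}" for j in range(n_samples)]
    return OtuTable(otus, samples, presence), seed_sets
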