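"""Bayesian attribution of sink communities to environmental sources.

Each host (sink) community is modeled as a mixture of known source
environments plus an "unknown" component.  A collapsed Gibbs sampler
assigns every sequence in the sink to a source: known sources contribute a
fixed, smoothed taxon distribution estimated from their training counts,
while the unknown source's distribution accumulates from the sequences
currently assigned to it.  Reported proportions are posterior means over
thinned draws and independent restarts.

The conditional for sequence i of taxon t is

    P(z_i = k | .) ~ p_k(t) * (n_k + beta)

with p_k(t) = (m_{t,k} + alpha1) / (M_k + alpha1 * T) for known source k
(training counts m), and p_u(t) = (u_t + alpha2) / (U + alpha2 * T) for the
unknown source (current assignments u).  n_k is the number of sink
sequences currently assigned to k, excluding sequence i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DomainError
from .containers import OtuTable, SampleMetadata

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@dataclass
class SourceProportions:
    """Posterior mixing proportions for one sink over sources + unknown."""

    sink_id: str
    proportions: dict[str, float]
    posterior_sd: dict[str, float]

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"proportions sum to {total}, not 1")
        if "unknown" not in self.proportions:
            raise DomainError("proportions must include 'unknown'")


@njit(cache=True)
def _gibbs_kernel(
    seq_taxa,      # (depth,) int64 taxon index of each sink sequence
    p_known,       # (T, K) float64 smoothed known-source taxon probabilities
    alpha2,
    beta,
    n_taxa,
    n_burnin,
    n_draws,
    thin,
    uniforms,      # (n_sweeps + 1, depth) float64 in [0, 1)
    prop_sum,      # (K+1,) accumulator: sum of drawn proportions
    prop_sq,       # (K+1,) accumulator: sum of squared drawn proportions
):
    depth = seq_taxa.shape[0]
    n_known = p_known.shape[1]
    n_src = n_known + 1
    assign = np.empty(depth, dtype=np.int64)
    n_k = np.zeros(n_src, dtype=np.float64)
    u_t = np.zeros(n_taxa, dtype=np.float64)
    u_total = 0.0
    weights = np.empty(n_src, dtype=np.float64)

    # random initialization from row 0 of the uniforms
    for i in range(depth):
        k = int(uniforms[0, i] * n_src)
        if k >= n_src:
            k = n_src - 1
        assign[i] = k
        n_k[k] += 1.0
        if k == n_known:
            u_t[seq_taxa[i]] += 1.0
            u_total += 1.0

    n_sweeps = n_burnin + n_draws * thin
    draws_done = 0
    for sweep in range(n_sweeps):
        for i in range(depth):
            t = seq_taxa[i]
            k_old = assign[i]
            n_k[k_old] -= 1.0
            if k_old == n_known:
                u_t[t] -= 1.0
                u_total -= 1.0
            total = 0.0
            for k in range(n_known):
                w = p_known[t, k] * (n_k[k] + beta)
                weights[k] = w
                total += w
            w = (
                (u_t[t] + alpha2)
                / (u_total + alpha2 * n_taxa)
                * (n_k[n_known] + beta)
            )
            weights[n_known] = w
            total += w
            r = uniforms[sweep + 1, i] * total
            acc = 0.0
            k_new = n_src - 1
            for k in range(n_src):
                acc += weights[k]
                if r < acc:
                    k_new = k
                    break
            assign[i] = k_new
            n_k[k_new] += 1.0
            if k_new == n_known:
                u_t[t] += 1.0
                u_total += 1.0
        if sweep >= n_burnin and (sweep - n_burnin) % thin == thin - 1:
            for k in range(n_src):
                p = n_k[k] / depth
                prop_sum[k] += p
                prop_sq[k] += p * p
            draws_done += 1
    return draws_done


def fit_sources(
    sinks: OtuTable,
    sources: dict[str, OtuTable],
    alpha1: float = 0.001,
    alpha2: float = 0.1,
    beta: float = 10.0,
    n_burnin: int = 100,
    n_draws: int = 25,
    thin: int = 10,
    restarts: int = 10,
    seed: int = 0,
) -> list[SourceProportions]:
    """Estimate, for every sink sample, the source mixing proportions.

    ``sources`` maps source names to OTU tables whose samples are pooled
    (summed) into one training count vector per source.  Sinks and sources
    must share the same taxon list.  Deterministic under ``seed``.
    """
    if not sources:
        raise DomainError("need at least one source")
    source_names = sorted(sources)
    for name, table in sources.items():
        if table.counts.sum() == 0:
            raise DomainError(f"source {name!r} has no counts")
        if table.taxon_ids != sinks.taxon_ids:
            offending = sorted(
                set(table.taxon_ids) ^ set(sinks.taxon_ids)
            )[:10]
            raise DomainError(
                f"taxon universe mismatch between sinks and source "
                f"{name!r}; first differing taxa: {offending}"
            )

    n_taxa = len(sinks.taxon_ids)
    n_known = len(source_names)
    m = np.column_stack(
        [sources[name].counts.sum(axis=1) for name in source_names]
    ).astype(np.float64)
    p_known = (m + alpha1) / (m.sum(axis=0, keepdims=True) + alpha1 * n_taxa)

    rng = np.random.default_rng(seed)
    n_sweeps = n_burnin + n_draws * thin
    results = []
    for j, sink_id in enumerate(sinks.sample_ids):
        col = sinks.counts[:, j]
        depth = int(col.sum())
        if depth == 0:
            raise DomainError(f"sink {sink_id!r} has zero counts")
        seq_taxa = np.repeat(
            np.arange(n_taxa, dtype=np.int64), col
        )
        prop_sum = np.zeros(n_known + 1)
        prop_sq = np.zeros(n_known + 1)
        n_total_draws = 0
        for _ in range(restarts):
            uniforms = rng.random((n_sweeps + 1, depth))
            n_total_draws += _gibbs_kernel(
                seq_taxa,
                p_known,
                alpha2,
                beta,
                n_taxa,
                n_burnin,
                n_draws,
                thin,
                uniforms,
                prop_sum,
                prop_sq,
            )
        mean = prop_sum / n_total_draws
        mean = mean / mean.sum()
        var = np.maximum(prop_sq / n_total_draws - mean ** 2, 0.0)
        names = source_names + ["unknown"]
        results.append(
            SourceProportions(
                sink_id=sink_id,
                proportions={n: float(v) for n, v in zip(names, mean)},
                posterior_sd={
                    n: float(np.sqrt(v)) for n, v in zip(names, var)
                },
            )
        )
    return results


def fit_sources_by_site(
    sinks: OtuTable,
    env_tables: dict[str, OtuTable],
    metadata: SampleMetadata,
    **kwargs,
) -> list[SourceProportions]:
    """Site-resolved training: each sink is attributed against the source
    samples collected at its own site; sinks at sites with no source
    samples fall back to the global pool."""
    results = []
    for sink_id in sinks.sample_ids:
        site = metadata[sink_id].site_id
        local_sources = {}
        for name, table in env_tables.items():
            local = [
                s for s in table.sample_ids
                if s in metadata and metadata[s].site_id == site
            ]
            local_sources[name] = (
                table.select_samples(local) if local else table
            )
        sink_one = sinks.select_samples([sink_id])
        results.extend(fit_sources(sink_one, local_sources, **kwargs))
    return results


def select_primary_source(
    attributions: list[SourceProportions],
    metadata: SampleMetadata,
) -> dict[str, dict]:
    """Pick, per host compartment, the named source with the largest median
    proportion across that compartment's sinks.

    Returns ``{community_type: {"source": name, "medians": {...}}}``.  The
    reserved "unknown" component never wins; an exact tie between named
    sources raises, demanding an explicit override.
    """
    by_type: dict[str, list[SourceProportions]] = {}
    for att in attributions:
        if att.sink_id not in metadata:
            raise DomainError(f"sink {att.sink_id!r} missing from metadata")
        by_type.setdefault(
            metadata[att.sink_id].community_type, []
        ).append(att)

    selection = {}
    for ctype, atts in by_type.items():
        names = [k for k in atts[0].proportions if k != "unknown"]
        medians = {
            name: float(
                np.median([a.proportions[name] for a in atts])
            )
            for name in names
        }
        best = max(medians.values())
        winners = [n for n, v in medians.items() if v == best]
        if len(winners) > 1:
            raise DomainError(
                f"median proportions tie for {ctype!r} between "
                f"{winners}; supply an explicit primary source"
            )
        selection[ctype] = {"source": winners[0], "medians": medians}
    return selection
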