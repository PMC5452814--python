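"""Alpha and beta diversity, ordination, and permutation tests.

Implements the comparisons used to contrast host-associated and
environmental communities: rarefaction to a fixed depth, Shannon diversity
(bits) and Faith's phylogenetic diversity, Canberra and normalized
unweighted UniFrac distances, classical PCoA, ANOSIM with permutations
restricted to within-site strata, the permdisp2 dispersion test with
Anderson's negative-eigenvalue correction, and a Monte-Carlo test of
whether host communities sit closer to their own bed's environment than to
mismatched beds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from ._errors import DomainError
from .containers import OtuTable


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(
    table: OtuTable, depth: int, seed: int
) -> tuple[OtuTable, list[str]]:
    """Subsample every sample to ``depth`` counts without replacement.

    Samples whose total is below ``depth`` are dropped; the list of dropped
    sample ids is returned alongside the rarefied table.
    """
    if depth <= 0:
        raise DomainError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    kept_idx = [j for j, s in enumerate(sums) if s >= depth]
    dropped = [table.sample_ids[j] for j, s in enumerate(sums) if s < depth]
    counts = np.empty((len(table.taxon_ids), len(kept_idx)), dtype=np.int64)
    for out_j, j in enumerate(kept_idx):
        counts[:, out_j] = rng.multivariate_hypergeometric(
            table.counts[:, j], depth
        )
    kept_ids = [table.sample_ids[j] for j in kept_idx]
    return OtuTable(list(table.taxon_ids), kept_ids, counts), dropped


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity ``H = -sum p_i log_base p_i`` (default: bits)."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise DomainError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise DomainError("zero-sum count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def faith_pd(counts, taxon_ids: list[str], tree: TreeNode) -> float:
    """Faith's phylogenetic diversity, including the path to the root."""
    x = np.asarray(counts)
    observed = {taxon_ids[i] for i in np.nonzero(x)[0]}
    tips = {t.name for t in tree.tips()}
    missing = observed - tips
    if missing:
        raise DomainError(f"taxa missing from tree: {sorted(missing)}")
    return float(_skbio_faith_pd(x, taxa=taxon_ids, tree=tree))


def alpha_diversity_table(
    table: OtuTable, tree: TreeNode | None = None
):
    """Per-sample Shannon (and Faith's PD when a tree is given) as a DataFrame."""
    import pandas as pd

    rows = {}
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        entry = {"shannon": shannon(col)}
        if tree is not None:
            entry["faith_pd"] = faith_pd(col, table.taxon_ids, tree)
        rows[sid] = entry
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def canberra(x, y) -> float:
    """Canberra distance; double-zero indices contribute nothing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("vectors must be nonnegative")
    denom = x + y
    mask = denom > 0
    if not mask.any():
        return 0.0
    return float(np.sum(np.abs(x - y)[mask] / denom[mask]))


def canberra_matrix(table: OtuTable) -> DistanceMatrix:
    """Pairwise Canberra distances between samples."""
    data = table.counts.T.astype(float)
    condensed = pdist(data, metric="canberra")
    return DistanceMatrix(squareform(condensed), table.sample_ids)


def unweighted_unifrac(
    x, y, taxon_ids: list[str], tree: TreeNode
) -> float:
    """Normalized unweighted UniFrac between two samples."""
    _check_tips(x, y, taxon_ids, tree)
    from skbio.diversity.beta import unweighted_unifrac as _uf

    return float(_uf(np.asarray(x), np.asarray(y), taxa=taxon_ids, tree=tree))


def _check_tips(x, y, taxon_ids, tree):
    tips = {t.name for t in tree.tips()}
    observed = {
        taxon_ids[i]
        for i in np.nonzero(np.asarray(x) + np.asarray(y))[0]
    }
    missing = observed - tips
    if missing:
        raise DomainError(f"taxa missing from tree: {sorted(missing)}")


def unifrac_matrix(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Pairwise normalized unweighted UniFrac distances between samples."""
    tips = {t.name for t in tree.tips()}
    observed = {
        table.taxon_ids[i] for i in np.nonzero(table.taxon_sums())[0]
    }
    missing = observed - tips
    if missing:
        raise DomainError(f"taxa missing from tree: {sorted(missing)}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` holds the axes with positive eigenvalues (scaled by
    sqrt(eigenvalue)); all eigenvalues, including negatives, are reported in
    descending order.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal-coordinate analysis (no Lingoes/Cailliez correction).

    Negative eigenvalues are retained in ``eigenvalues`` but their axes are
    excluded from ``coordinates``.
    """
    coords, eigvals = _gower_decomposition(dm)
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coordinates = coords[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coordinates = coordinates[:, :n_axes]
    pos_sum = eigvals[pos].sum()
    proportion = np.where(eigvals > 0, eigvals, 0.0) / pos_sum if pos_sum > 0 \
        else np.zeros_like(eigvals)
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coordinates,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def _gower_decomposition(dm: DistanceMatrix):
    """Eigendecomposition of the double-centered -0.5 * D^2 matrix."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvecs[:, order], eigvals[order]


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    statistic_name: str

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise DomainError(f"p-value {self.p_value} outside (0, 1]")


def anosim(
    dm: DistanceMatrix,
    groups: list[str],
    strata: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Analysis of similarities with optional restricted permutations.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and average ranks on ties.  Group labels are permuted only
    within strata (e.g., sampling sites); strata containing a single group
    are left fixed.  One-sided p: large R means groups are separated.
    """
    n = len(dm.ids)
    groups = np.asarray(groups)
    if len(groups) != n:
        raise DomainError("groups must align with distance matrix ids")
    if len(np.unique(groups)) < 2:
        raise DomainError("need >= 2 groups")
    for g, cnt in zip(*np.unique(groups, return_counts=True)):
        if cnt < 2:
            raise DomainError(f"group {g!r} has fewer than 2 samples")
    if strata is None:
        strata_arr = np.zeros(n, dtype=int)
    else:
        if len(strata) != n:
            raise DomainError("strata must align with distance matrix ids")
        _, strata_arr = np.unique(np.asarray(strata), return_inverse=True)

    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = rankdata(condensed)
    iu = np.triu_indices(n, k=1)
    m = n * (n - 1) // 2

    def r_stat(labels):
        within = labels[iu[0]] == labels[iu[1]]
        if within.all() or not within.any():
            return 0.0
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(groups)

    # admissible strata: those containing at least two distinct labels
    stratum_members = {
        s: np.nonzero(strata_arr == s)[0] for s in np.unique(strata_arr)
    }
    admissible = [
        idx for idx in stratum_members.values()
        if len(np.unique(groups[idx])) > 1
    ]
    degenerate = len(stratum_members) - len(admissible)
    if not admissible:
        raise DomainError(
            "every stratum contains a single group; no admissible permutations"
        )
    if degenerate:
        warnings.warn(
            f"{degenerate} strata contain a single group and are held fixed",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    perm = groups.copy()
    for _ in range(n_perm):
        for idx in admissible:
            perm[idx] = groups[idx][rng.permutation(len(idx))]
        if r_stat(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return GroupTestResult(float(observed), float(p), n_perm, "anosim_r")


def _embed_with_sign_split(dm: DistanceMatrix):
    """PCoA embedding keeping negative-eigenvalue axes as 'imaginary' parts."""
    coords, eigvals = _gower_decomposition(dm)
    tol = 1e-10 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg = eigvals < -tol
    real = coords[:, pos] * np.sqrt(eigvals[pos])
    imag = coords[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag


def permdisp(
    dm: DistanceMatrix,
    groups: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Homogeneity of multivariate dispersions (permdisp2, spatial centroids).

    Samples are embedded by PCoA; distances to group centroids use
    Anderson's correction, subtracting the squared distance along
    negative-eigenvalue axes.  The statistic is the one-way ANOVA F on those
    distances; p is by permuting the observed distances-to-centroid across
    groups (so group location differences do not masquerade as dispersion
    differences).
    """
    groups = np.asarray(groups)
    n = len(dm.ids)
    if len(groups) != n:
        raise DomainError("groups must align with distance matrix ids")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise DomainError("need >= 2 groups")
    if np.any(counts < 2):
        bad = labels[counts < 2]
        raise DomainError(f"group(s) {list(bad)} of size 1: dispersion undefined")
    real, imag = _embed_with_sign_split(dm)

    def centroid_distances(g):
        z = np.empty(n)
        for lab in np.unique(g):
            idx = g == lab
            dr = real[idx] - real[idx].mean(axis=0)
            di = imag[idx] - imag[idx].mean(axis=0) if imag.size else 0.0
            sq = (dr ** 2).sum(axis=1)
            if imag.size:
                sq = sq - (di ** 2).sum(axis=1)
            z[idx] = np.sqrt(np.maximum(sq, 0.0))
        return z

    def f_stat(z, g):
        grand = z.mean()
        ss_between = ss_within = 0.0
        k = 0
        for lab in np.unique(g):
            zi = z[g == lab]
            ss_between += len(zi) * (zi.mean() - grand) ** 2
            ss_within += ((zi - zi.mean()) ** 2).sum()
            k += 1
        df1, df2 = k - 1, n - k
        if ss_within <= 1e-300:
            return 0.0 if ss_between <= 1e-300 else np.inf
        return (ss_between / df1) / (ss_within / df2)

    z = centroid_distances(groups)
    observed = f_stat(z, groups)
    rng = np.random.default_rng(seed)
    exceed = sum(
        f_stat(z[rng.permutation(n)], groups) >= observed
        for _ in range(n_perm)
    )
    p = (1 + exceed) / (1 + n_perm)
    return GroupTestResult(float(observed), float(p), n_perm, "permdisp_f")


def centroid_proximity_test(
    ordination: OrdinationResult,
    host_samples: dict[str, list[str]],
    env_samples: dict[str, list[str]],
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Are host communities closest to their own bed's environment?

    The statistic is the mean, over beds, of the Euclidean distance in PCoA
    space between the host-sample centroid of a bed and the environmental
    centroid of the same bed.  The null redistributes environmental beds at
    random (identity assignment excluded); small p means own-bed
    environments are closer than mismatched ones.
    """
    beds = sorted(set(host_samples) & set(env_samples))
    if len(beds) < 2:
        raise DomainError("need >= 2 beds with both host and env samples")
    index = {s: i for i, s in enumerate(ordination.sample_ids)}
    coords = ordination.coordinates

    def centroid(sample_ids):
        rows = [index[s] for s in sample_ids]
        return coords[rows].mean(axis=0)

    host_c = np.array([centroid(host_samples[b]) for b in beds])
    env_c = np.array([centroid(env_samples[b]) for b in beds])
    observed = float(np.linalg.norm(host_c - env_c, axis=1).mean())

    rng = np.random.default_rng(seed)
    nb = len(beds)
    at_most = 0
    for _ in range(n_perm):
        while True:
            perm = rng.permutation(nb)
            if not np.array_equal(perm, np.arange(nb)):
                break
        null = float(np.linalg.norm(host_c - env_c[perm], axis=1).mean())
        if null <= observed:
            at_most += 1
    p = (1 + at_most) / (1 + n_perm)
    return GroupTestResult(observed, float(p), n_perm, "centroid_delta")
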