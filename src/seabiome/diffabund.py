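"""Differential abundance of host vs. source communities.

Counts are normalized with trimmed-mean-of-M-values (TMM) factors, then
each OTU is fitted with a negative-binomial log-link GLM (offset =
log(library size x TMM factor)).  Significance comes from a likelihood
ratio test of the host-vs-source indicator against an intercept-only null,
with per-OTU dispersions estimated by Cox-Reid adjusted profile likelihood
and shrunk toward the common dispersion.  P-values are Benjamini-Hochberg
adjusted and OTUs are called enriched/depleted at an adjusted-P threshold.

The negative binomial is parameterized mean mu, variance mu + phi * mu^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._errors import DomainError
from .containers import OtuTable

_MIN_PHI = 1e-6
_MAX_PHI = 20.0


# ---------------------------------------------------------------------------
# Low-count filter
# ---------------------------------------------------------------------------

def filter_low_count(
    table: OtuTable, min_total: int = 5, mode: str = "total"
) -> tuple[OtuTable, list[str]]:
    """Drop underpowered OTUs.

    ``mode="total"``: drop OTUs with total count across samples below
    ``min_total``.  ``mode="incidence"``: drop OTUs detected (count > 0) in
    fewer than ``min_total`` samples.  Returns the filtered table and the
    removed taxon ids.
    """
    if mode == "total":
        stat = table.taxon_sums()
    elif mode == "incidence":
        stat = (table.counts > 0).sum(axis=1)
    else:
        raise DomainError(f"unknown filter mode {mode!r}")
    keep = stat >= min_total
    removed = [t for t, k in zip(table.taxon_ids, keep) if not k]
    kept_taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not kept_taxa:
        warnings.warn("all OTUs removed by the low-count filter", stacklevel=2)
        return (
            OtuTable([], list(table.sample_ids),
                     np.zeros((0, len(table.sample_ids)), dtype=np.int64)),
            removed,
        )
    return (
        OtuTable(kept_taxa, list(table.sample_ids), table.counts[keep, :]),
        removed,
    )


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    factors: dict[str, float]
    reference_sample: str

    def __post_init__(self):
        vals = np.array(list(self.factors.values()))
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise DomainError("factors must be finite and positive")
        if abs(np.exp(np.mean(np.log(vals))) - 1.0) > 1e-9:
            raise DomainError("factors must have geometric mean 1")

    def aligned(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors]
        if missing:
            raise DomainError(f"no factor for samples {missing}")
        return np.array([self.factors[s] for s in sample_ids])


def tmm_factors(
    table: OtuTable, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    The reference is the sample whose 75th-percentile relative abundance is
    closest to the mean of those percentiles.  For each sample, M (log2
    abundance ratio vs. reference) and A (mean log2 abundance) are computed
    over taxa positive in both; both tails of M and A are trimmed
    (``trim_m`` and ``trim_a`` per tail) and the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors are
    rescaled to geometric mean 1.
    """
    y = table.counts.astype(float)
    n_samples = y.shape[1]
    if n_samples < 2:
        raise DomainError("TMM needs >= 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = [table.sample_ids[j] for j in np.nonzero(lib <= 0)[0]]
        raise DomainError(f"zero library size for samples {bad}")

    q75 = np.array(
        [np.quantile(y[:, j] / lib[j], 0.75) for j in range(n_samples)]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a,
            table.sample_ids[j],
        )
    log_factors -= log_factors.mean()  # geometric mean 1
    return NormalizationFactors(
        factors={
            s: float(2.0 ** log_factors[j])
            for j, s in enumerate(table.sample_ids)
        },
        reference_sample=table.sample_ids[ref],
    )


def _tmm_pair(y_s, n_s, y_r, n_r, trim_m, trim_a, sample_id):
    both = (y_s > 0) & (y_r > 0)
    if not both.any():
        raise DomainError(
            f"sample {sample_id!r} shares no positive taxon with the reference"
        )
    ys, yr = y_s[both], y_r[both]
    ps, pr = ys / n_s, yr / n_r
    m = np.log2(ps / pr)
    a = 0.5 * np.log2(ps * pr)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)

    k = len(m)
    lo_m, hi_m = np.floor(k * trim_m) + 1, k + 1 - (np.floor(k * trim_m) + 1)
    lo_a, hi_a = np.floor(k * trim_a) + 1, k + 1 - (np.floor(k * trim_a) + 1)
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


# ---------------------------------------------------------------------------
# Negative-binomial GLM with likelihood ratio test
# ---------------------------------------------------------------------------

def _irls_fit(y, x, offset, phi, max_iter=60, tol=1e-8):
    """Vectorized IRLS across OTUs for a shared design matrix.

    y: (G, n) counts; x: (n, p) design; offset: (n,); phi: scalar or (G,)
    dispersions.  Returns (beta (G, p), loglik (G,), converged (G,),
    half_logdet (G,) Cox-Reid adjustment).
    """
    g, n = y.shape
    p = x.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (g,)).copy()
    phi = np.clip(phi, _MIN_PHI, _MAX_PHI)

    # initialize intercept at log mean rate, other coefficients at 0
    rate = (y.sum(axis=1) + 0.5) / np.exp(offset).sum()
    beta = np.zeros((g, p))
    beta[:, 0] = np.log(rate)
    converged = np.zeros(g, dtype=bool)
    last_ll = np.full(g, -np.inf)

    for _ in range(max_iter):
        eta = beta @ x.T + offset  # (G, n)
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)  # NB working weights, log link
        z = (eta - offset) + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", x, w, x)
        xtwz = np.einsum("ni,gn,gn->gi", x, w, z)
        xtwx += 1e-10 * np.eye(p)
        new_beta = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        step = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        ll = _nb_loglik(y, np.exp(np.clip(beta @ x.T + offset, -30, 30)), phi)
        done = (step < tol) | (np.abs(ll - last_ll) < tol)
        converged |= done
        last_ll = ll
        if converged.all():
            break

    eta = np.clip(beta @ x.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + phi[:, None] * mu)
    xtwx = np.einsum("ni,gn,nj->gij", x, w, x) + 1e-10 * np.eye(p)
    sign, logdet = np.linalg.slogdet(xtwx)
    ll = _nb_loglik(y, mu, phi)
    return beta, ll, converged, 0.5 * logdet


def _nb_loglik(y, mu, phi):
    """NB log-likelihood per OTU (rows); mu (G, n), phi (G,)."""
    phi = np.asarray(phi, dtype=float)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )
    return ll.sum(axis=1)


def _dispersion_grid(n_points: int = 21) -> np.ndarray:
    return np.exp(np.linspace(np.log(_MIN_PHI), np.log(_MAX_PHI), n_points))


def estimate_dispersions(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, prior_df: float = 10.0
) -> tuple[np.ndarray, float]:
    """Per-OTU NB dispersions by adjusted profile likelihood with shrinkage.

    The Cox-Reid adjusted profile likelihood APL_g(phi) is evaluated on a
    log-spaced grid by refitting the full model; the common dispersion
    maximizes the grid average.  Each OTU's shrunk dispersion maximizes
    APL_g + (prior_df / residual_df) * mean-APL, pulling unstable small-n
    estimates toward the common value.
    """
    g, n = y.shape
    grid = _dispersion_grid()
    apl = np.empty((g, len(grid)))
    for i, phi in enumerate(grid):
        _, ll, _, half_logdet = _irls_fit(y, x, offset, phi)
        apl[:, i] = ll - half_logdet
    mean_apl = apl.mean(axis=0)
    common = float(grid[int(np.argmax(mean_apl))])
    df_resid = max(n - x.shape[1], 1)
    weight = prior_df / df_resid
    scores = apl + weight * mean_apl[None, :]
    best = np.argmax(scores, axis=1)
    return grid[best].astype(float), common


def nb_glm_lrt(
    host: OtuTable,
    source: OtuTable,
    factors: NormalizationFactors,
    prior_df: float = 10.0,
    site: list[str] | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of host vs. source for every OTU.

    Returns a DataFrame (index otu_id) with ``log2_fold_change`` (host over
    source), ``p_value``, ``mean_normalized_abundance`` (counts per
    thousand after TMM), and ``converged``.  Non-converged OTUs get missing
    p-values and are excluded from later adjustment.  ``site`` optionally
    adds site indicator covariates to both models.
    """
    if host.taxon_ids != source.taxon_ids:
        raise DomainError("host and source tables must share the taxon list")
    y = np.hstack([host.counts, source.counts]).astype(float)
    sample_ids = host.sample_ids + source.sample_ids
    lib = y.sum(axis=0)
    f = factors.aligned(sample_ids)
    offset = np.log(lib * f)
    indicator = np.concatenate(
        [np.ones(len(host.sample_ids)), np.zeros(len(source.sample_ids))]
    )
    covars = [np.ones_like(indicator)]
    if site is not None:
        if len(site) != len(sample_ids):
            raise DomainError("site covariate must align with samples")
        levels = sorted(set(site))
        for lev in levels[1:]:
            covars.append(np.array([1.0 if s == lev else 0.0 for s in site]))
    x_null = np.column_stack(covars)
    x_full = np.column_stack(covars + [indicator])

    nonzero = y.sum(axis=1) > 0
    phi = np.full(y.shape[0], np.nan)
    stat = np.full(y.shape[0], np.nan)
    lfc = np.full(y.shape[0], np.nan)
    conv = np.zeros(y.shape[0], dtype=bool)

    if nonzero.any():
        yv = y[nonzero]
        phi_v, _ = estimate_dispersions(yv, x_full, offset, prior_df)
        beta_full, ll_full, conv_full, _ = _irls_fit(yv, x_full, offset, phi_v)
        _, ll_null, conv_null, _ = _irls_fit(yv, x_null, offset, phi_v)
        phi[nonzero] = phi_v
        stat[nonzero] = np.maximum(2.0 * (ll_full - ll_null), 0.0)
        lfc[nonzero] = beta_full[:, -1] / np.log(2.0)
        conv[nonzero] = conv_full & conv_null

    pvals = np.where(conv, chi2.sf(stat, df=1), np.nan)
    norm = y / (lib * f)[None, :]
    result = pd.DataFrame(
        {
            "log2_fold_change": np.where(conv, lfc, np.nan),
            "p_value": pvals,
            "mean_normalized_abundance": norm.mean(axis=1) * 1000.0,
            "dispersion": phi,
            "converged": conv,
        },
        index=pd.Index(host.taxon_ids, name="otu_id"),
    )
    return result


# ---------------------------------------------------------------------------
# Multiple testing and calls
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are excluded from
    the number of tests and stay NaN."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    if ok.any():
        adjusted[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adjusted


def call_enrichment(
    results: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and enriched/depleted/unchanged calls."""
    out = results.copy()
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["p_adjusted"] < alpha
    call = np.where(
        sig & (out["log2_fold_change"] > 0),
        "enriched",
        np.where(sig & (out["log2_fold_change"] < 0), "depleted", "unchanged"),
    )
    call = np.where(out["p_adjusted"].isna(), "unchanged", call)
    out["call"] = call
    return out


def enrichment_summary(results: pd.DataFrame) -> dict[str, int]:
    return {
        "n_enriched": int((results["call"] == "enriched").sum()),
        "n_depleted": int((results["call"] == "depleted").sum()),
        "n_tested": int(results["p_value"].notna().sum()),
    }
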