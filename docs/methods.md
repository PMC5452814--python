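# Methods

This note documents the statistical models and procedures implemented in
`seabiome`, the choices made where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Overview

The package implements a pipeline for contrasting host-associated
microbial communities (e.g., plant leaf and root surfaces) with the
communities of their surrounding environments (e.g., seawater and
sediment), and for testing a habitat-filtering hypothesis about how host
compartments assemble. Stages: rarefaction, alpha/beta diversity with
permutation tests, Bayesian source attribution, source-guided differential
abundance, and reverse-ecology seed-set analysis linking predicted
resource overlap to taxon cooccurrence.

## Rarefaction and diversity

Counts are rarefied by sampling without replacement
(`numpy`'s multivariate hypergeometric) to a fixed depth; samples below the
depth are dropped and reported. The default depth is 2,500 sequences, the
retention rule used in the reference analysis this pipeline reproduces.

Shannon diversity uses log base 2 (bits), switchable to natural log.
Faith's PD sums the branch lengths of the union of root-to-tip paths of
observed taxa and **includes the path to the root** (the QIIME 1.x
convention); both it and normalized unweighted UniFrac are computed through
scikit-bio, whose conventions match this definition. Canberra distances
skip double-zero indices (they contribute nothing to the sum); this is the
common ecological convention but dialects differ, so it is stated here.

PCoA is classical scaling of the double-centered −½D² matrix. No
Lingoes/Cailliez correction is applied: negative eigenvalues are reported
as is and their axes are excluded from the coordinates. This transparency
matters because the dispersion test consumes the embedding.

### ANOSIM with restricted permutations

R = (mean between-group rank − mean within-group rank) / (M/2), with
M = n(n−1)/2 and average ranks on ties (Clarke's definition). To avoid
pseudoreplication in spatially blocked designs, group labels are permuted
only **within strata** (sampling sites); strata containing a single group
carry no label diversity and are held fixed (with a warning), and the test
errors out if every stratum is degenerate. One-sided p with add-one
smoothing: p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm).

### permdisp

Samples are embedded by PCoA keeping negative-eigenvalue axes as
"imaginary" coordinates; the distance of a sample to its group centroid
uses Anderson's correction z² = d²_real − d²_imag (clamped at 0). The
statistic is the one-way ANOVA F on the z values. The null distribution
permutes the observed z values across groups — the `permutest.betadisper`
scheme — rather than recomputing centroids under permuted labels, which
would confound location differences with dispersion differences.

### Centroid-proximity (within- vs between-bed) test

For each bed, the Euclidean distance in PCoA space between the host-sample
centroid and the environment-sample centroid of the same bed is computed;
the statistic is the mean over beds. The null redistributes environment
beds uniformly at random among host beds, excluding the identity
assignment, and the test is one-sided: small p means hosts sit closer to
their **own** bed's environment than to mismatched beds. Permuting bed
assignments (not sample labels) reflects that the unit of comparison is
the bed centroid. With b beds and n_perm = 999 the attainable minimum is
p = 1/1000 (observed below every permuted value).

## Bayesian source tracking

Each sink community is modeled as a mixture over K known source
environments plus an unknown component. A collapsed Gibbs sampler assigns
each of the sink's sequences to a source with conditional

    P(z_i = k | ·) ∝ p_k(t_i) · (n_k + β)

where, for known source k, p_k(t) = (m_tk + α₁)/(M_k + α₁T) is the
smoothed taxon distribution of the pooled training counts m, and for the
unknown source p_u(t) = (u_t + α₂)/(U + α₂T) accumulates from the
sequences currently assigned to it; n_k counts the sink's current
assignments (excluding sequence i) and T is the taxon-universe size.
Reported proportions are posterior means over thinned draws and
independent restarts; the posterior SD comes from the same draws.

Hyperparameter defaults follow the published SourceTracker values:
α₁ = 0.001, α₂ = 0.1, β = 10, 10 restarts, 100 burn-in sweeps, 25 draws
spaced 10 sweeps apart. Sinks are fitted independently. A site-resolved
mode trains each sink against the source samples from its own site,
falling back to the global pool where a site has none. The sweep kernel is
JIT-compiled with numba; at depth 2,500 a sink costs well under a second
per restart.

In tests and the acceptance script the sampler runs with 3 restarts, 50
burn-in sweeps and 20 draws thinned by 5 — on well-separated synthetic
sources this already recovers known mixtures with mean absolute error
around 0.01, far inside the 0.05 calibration requirement, so the larger
defaults are reserved for real analyses.

The primary colonization source of a host compartment is the named source
with the largest **median** proportion across that compartment's sinks;
the unknown component never wins, and an exact tie demands an explicit
user override.

## Differential abundance

The unrarefied counts are used. OTUs with total count below 5 across the
compared samples are removed first (an incidence-based reading — detected
in fewer than 5 samples — is available via `mode="incidence"`).

TMM normalization follows the published trimmed-mean-of-M-values method:
reference sample by the 75th-percentile rule; M and A values over taxa
positive in both sample and reference; double trimming (30% per tail on M,
5% per tail on A); factor = 2^(precision-weighted mean of surviving M),
with delta-method weights; factors rescaled to geometric mean 1. The
implementation reproduces edgeR's `calcNormFactors` to ~4 decimals on
probe data (asserted in the test suite via Rscript).

Each OTU is fitted with a log-link negative-binomial GLM (variance
μ + φμ²) with offset log(library size × TMM factor), using a vectorized
IRLS across OTUs (cross-checked against statsmodels). Per-OTU dispersions
are estimated by Cox-Reid adjusted profile likelihood on a 21-point
log-spaced grid and shrunk toward the common (grid-mean-maximizing)
dispersion by maximizing APL_g + (prior_df/df_resid)·mean-APL with
prior_df = 10. This is a deliberate simplification of edgeR's
weighted-likelihood scheme: no abundance trend, one shared grid. The
likelihood-ratio statistic 2(ll_full − ll_null) is referred to χ²₁;
log₂ fold change is the group coefficient divided by ln 2. Non-converged
or all-zero OTUs are flagged, get missing p-values, and are excluded from
the Benjamini-Hochberg m. Calls at adjusted P < 0.01: enriched (positive
log2FC) or depleted (negative).

Operating characteristics on synthetic negative-binomial data
(φ = 0.2, 15 + 15 samples, depth 2,500): null p-values are uniform, the
fraction of null OTUs called at BH 0.01 is ≈ 10⁻⁴, and |log2FC| = 3
spikes at base proportion 0.01 are recovered with sensitivity 1.0 — all
recomputed by the test suite and acceptance script.

## Reverse ecology

Metabolic networks are directed compound graphs: every reaction
contributes an edge from each substrate to each product (reversible
reactions also the reverse). The seed set — the minimal set of compounds
the organism must acquire exogenously to synthesize all others — is the
union of the source components (in-degree-zero nodes) of the graph's SCC
condensation (networkx); each compound in a source component of size s has
confidence 1/s. The test suite and acceptance script verify exact
agreement with a brute-force full-reachability definition on hundreds of
random digraphs.

The competitive dissimilarity matrix C holds pairwise Jaccard distances
between seed compound sets (binary over compound identity; a
confidence-weighted generalized Jaccard is available behind a flag).
Cooccurrence dissimilarity is the Jaccard distance between OTU
presence/absence profiles across samples, binarized after rarefaction (a
quantitative Ružička variant is available). No currency-metabolite
filtering is applied by default; an exclusion list can be supplied.

Mantel tests correlate the upper triangles (Pearson by default, Spearman
available) and permute rows/columns of the second matrix; the partial
Mantel uses r₁₂·₃ = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)) with d₂'s labels
permuted and the statistic recomputed each draw. Tests are one-sided for
positive association by default — the habitat-filtering expectation that
taxa with overlapping predicted resources cooccur — with 1,000
permutations by default.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, plus the ground truth to score it:

- **Source profiles**: symmetric Dirichlet; small concentration gives
  sparse, well-separated sources (Jensen-Shannon divergence ≈ 0.9 at
  concentration 0.05 over 300 taxa).
- **Mixed sinks**: multinomial draws of a fixed depth from a convex
  mixture of source profiles plus an unknown profile supported on a
  reserved taxon block (which makes the unknown component identifiable).
- **Spiked counts**: negative-binomial (mean μ, variance μ + φμ², matching
  the GLM's parameterization) with environment mean depth × base and host
  mean multiplied by 2^log2FC for spiked taxa.
- **Bedded communities**: a host base profile mixing the environment
  profile (default fraction 0.6) with a host-specific component; both host
  and environment profiles of a bed are multiplied by the same lognormal
  perturbation (σ = bed_effect_sd) before sampling. The shared
  perturbation gives the centroid-proximity test its true positive; the
  env fraction gives source attribution and primary-source selection
  theirs. σ = 0 is the exchangeable null.
- **Toy metabolic networks**: explicit source cycles of bounded size plus
  downstream chains, with the exact seed set recorded.
- **Resource-pool scenarios**: in the structured ("root-like") case, OTUs
  draw seed compounds from their pool and occur where their pool is active
  (plus occupancy noise), producing a true positive for the Mantel
  association; in the random ("leaf-like") case seed sets and occurrences
  are independent.

What the generators do **not** emulate: sequencing error, chimeras and OTU
picking; realistic taxon-abundance distributions and taxonomies;
phylogenetic signal in the spiked effects; spatial autocorrelation beyond
the bed/site blocks; metabolic networks of realistic size or chemistry.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under their own model assumptions, not robustness to the
violations real amplicon data exhibit.

## Numerical choices and degenerate inputs

- IRLS: η clipped to ±30, ridge 10⁻¹⁰ on the normal equations, dispersion
  clamped to [10⁻⁶, 20]; convergence by coefficient step or log-likelihood
  change < 10⁻⁸ within 60 iterations.
- Permutation p-values always use add-one smoothing, so p ≥ 1/(n_perm+1).
- Two everywhere-absent OTUs are at cooccurrence distance 0 (warned); two
  empty seed sets at distance 0.
- Zero-variance distance triangles make Mantel's r undefined — an error,
  not a silent NaN. A control matrix perfectly collinear with either input
  makes the partial Mantel degenerate — also an error.
- A sample sharing no positive taxon with the TMM reference is an error
  naming the sample.
- Writers emit floats at 6 significant digits; integer tables round-trip
  exactly.

## Problem sizes

The test suite and acceptance script run the simulations at sizes chosen
to exercise the asymptotics the methods rely on while completing in
minutes on one CPU: 500 random digraphs (≤ 40 nodes) for the seed-set
oracle; 500 replicates for permutation-test calibration; 20 sinks at depth
2,500 for source recovery; 50 replicates of 500-OTU null and 100-OTU
spiked datasets for the GLM's operating characteristics; 100 replicates
per arm of the habitat-filtering contrast; and a 4-bed, 200-taxon
end-to-end pipeline for the determinism check.

## Known limitations

- The NB dispersion estimator uses a fixed grid; dispersions outside
  [10⁻⁶, 20] are clamped, and no abundance-dispersion trend is modeled.
- The Gibbs sampler reports within-chain posterior SDs; it does not
  compute convergence diagnostics (R̂) across restarts.
- ANOSIM's restricted permutation shuffles labels independently within
  each stratum; designs needing exchangeability across strata blocks are
  not supported.
- BIOM support is the v1.0 JSON dialect only (no HDF5).
- PCoA reports negative eigenvalues but offers no correction; proportions
  explained are relative to the positive-eigenvalue total.
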