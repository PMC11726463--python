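# Methods

This note documents the models and procedures `taxodelim` implements,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Pairwise genetic distance and windowing

π between two diploid individuals is the mean, over variant sites
genotyped in both, of d/4 where d = g_a(2−g_b) + (2−g_a)g_b counts the
differing pairings among the four cross-comparisons of their alleles
(g ∈ {0,1,2} alternate-allele dose). Only variant sites enter; a window
with no co-genotyped site yields a missing value, never zero. Sites are
partitioned into consecutive windows of exactly W SNPs (default 1,000)
in (chrom, pos) order; the trailing partial window is dropped so that
per-window π values share one sampling variance and NRMSE distributions
are comparable across pairs. W is a plain parameter: no signal/noise
window-size optimization is performed. Geographic distances are
great-circle (WGS84 decimal degrees, R = 6,371 km); clines are fitted on
log10 km, and co-located pairs (distance 0) are excluded because the log
is undefined there.

## The NRMSE–IBD heuristic

Per window and candidate: OLS of within-candidate π on log10 distance
(skipped with < 3 usable pairs), then
NRMSE = RMSE(between-candidate π − cline prediction) / sd(within π).
The normalizer is the sample standard deviation (ddof = 1) of the
within-candidate π values entering the fit. This choice controls for the
candidate's own spatial genetic variation and makes the statistic
invariant to a positive rescaling of all genetic distances; a range
(max − min) normalizer is available as a config switch. Quantiles are
empirical type-7 (linear interpolation) throughout.

Decision rule against reference nulls: reject the intraspecific model
when the 0.05 quantiles of both candidates' NRMSE distributions exceed
the benchmark 0.95 quantiles; congruent when at least one candidate 0.95
quantile falls below them; else inconclusive. With several references
the default combination is conservative (reject must clear *all*
reference q95; congruence must undercut all); `mode="any"` relaxes both.

The morphometric variant resamples variable combinations instead of
genomic windows: the largest variable-subset size with at least 50
combinations is used (individual resampling is the fallback), up to 200
replicates. Morphometric distance between individuals is Euclidean
distance on per-variable z-scores, averaging over shared non-missing
variables — a deliberately simple surrogate for a single-individual
"hypervolume overlap", which is not well defined for points. Association
with geography is a Spearman correlation with a seeded permutation
p-value. Classification: not-at-IBD if the 0.95 quantile of replicate
p-values exceeds 0.05; fits-intraspecific-IBD if at least one focal
candidate's NRMSE median is below the reference q95 (the median rather
than the q95, because variable-resampling replicates are few and
morphometric data carry strong observer effects); else inconclusive.
Candidates above 150 individuals are down-sampled per replicate.

## gdi, HPD, and time conversion

gdi = 1 − e^(−2τ/θ) applied per posterior draw; the point summary is the
posterior mean with the shortest 95% interval (ties broken toward the
lowest start). The 0.2 synonymy threshold and the 0.9 admixture
threshold are configuration values; gdi only ever argues for
synonymization. Traces are whitespace tables with named columns; a 20%
burn-in is applied to raw traces. τ converts to years as τ/μ·g with
defaults μ = 1.236×10⁻⁸ per site per generation and g = 3.5 years;
uncertainty propagates by Monte Carlo with μ ~ Gamma(mean, sd) and
g ~ Lognormal. The μ dispersion input is interpreted as a standard
deviation (a variance of 0.107×10⁻⁸ at mean 1.236×10⁻⁸ would be
dimensionally inconsistent), and this interpretation is recorded in the
output.

## Hypervolume overlap (dynamic range boxes)

For levels s_k = 0.5k/(n_boxes−1), k = 0..n_boxes−1 (default 51 levels,
s ∈ [0, 0.5]), each variable contributes the mean over levels of
|box_A ∩ box_B| / |box_A| with box_X = [Q_X(s), Q_X(1−s)] (type-7
quantiles); variables aggregate by product. A degenerate A box counts 1
if its point lies in the B box, else 0. The interval-ratio definition
(rather than point counting) guarantees port(A, A) = 1 and the exact
containment property, making the statistic brute-force testable; it is
a self-consistent surrogate for library-internal definitions of the same
statistic. Differentiation = 1 − max(port_AB, port_BA), with a jackknife
CI from resampling 90% of individuals 100 times (2.5/97.5 percentiles;
the percentile convention is a package choice). "Substantial
differentiation" for the decision engine means the differentiation CI
lower bound exceeds the benchmark band's upper bound.

## Climatic niche

Bioclimatic tables are reduced to three principal components (centered,
unit variance). The built-in suitability model is a Gaussian Mahalanobis
envelope on those PCs — suitability ∝ exp(−m²/2) from the occurrence
centroid, ridge-regularized when the occurrence covariance is
near-singular — normalized to sum to 1. It is a deliberately simple,
pluggable baseline: any model producing a per-cell suitability surface
can be substituted, and no feature-class tuning, background-point
machinery or AUC/CBI validation is attempted. Overlap is Schoener's
D = 1 − ½Σ|p−q|; the identity test refits surfaces on label-permuted
pooled occurrences and reports p = (1 + #{D_null ≤ D_obs})/(n_perm + 1).

## Reproductive seasonality

Pregnancy is back-dated 2 months and lactation 3 months (midpoint of the
2–3.5-month diagnosis window, rounded; a config option spreads lactation
weight over −2..−4 months instead) to the approximate oestrus month,
wrapping at the year boundary. Profiles are proportions of reproductively
active individuals per month; comparison is descriptive (peaks, months
above 0.5, Schoener's D between month-normalized profiles, low-effort
months masked). No automatic verdict is derived — sampling effort varies
too much across taxa for a quantitative threshold — so the decision
engine accepts reproductive asynchrony only as an analyst-attested flag.

## Trait evolution

Species means y (n species × p traits) are Gaussian with covariance
kron(R, C_model) + diag(SE²):

* BM: C_ij = shared path length from the root.
* EB: C_ij = (e^{r t_ij} − 1)/r, r ≤ 0 (r = 0 is exactly BM).
* OU (stationary, scalar α): C_ij = e^{−α d_ij}/(2α) with d_ij the
  patristic distance; root = optimum, both at the stationary
  distribution — they are not separately identifiable on ultrametric
  trees.

The root/optimum is profiled out by GLS; R is optimized through its
Cholesky factor with multi-start L-BFGS-B; the EB fit explicitly
compares the interior optimum against the r = 0 (BM) profile and snaps
to the boundary when the boundary is better, so EB never scores below
BM. AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with n = number of species and
k counting R entries, root parameters and the extra rate parameter.
A `reml=True` option maximizes the restricted (contrast-space)
likelihood instead; for univariate BM without measurement error the
REML rate equals the unbiased independent-contrasts estimator
Σpic²/(n−1), and the test suite verifies this against a Felsenstein
pruning oracle and `phytools::phylosig` (for Blomberg's K and Pagel's
λ) through Rscript.

Known limitations, measured on 15-tip depth-1 trees: α of the stationary
OU model is weakly identified and strongly upward-biased (the stationary
tip variance R/2α is well estimated and is what the suite checks), and
AICc distinguishes OU (α = 2) from BM in only about half of replicates —
small-tree behavior documented in the comparative-methods literature,
not an optimizer failure (fits were cross-checked against an independent
GLS implementation).

Simulation replicates draw species means from the fitted Gaussian (plus
observed measurement error), redrawing any dataset containing a
non-positive trait mean (at most 1,000 retries); individuals are then
rejection-sampled from a multivariate normal truncated below at zero
with the observed within-species covariance and real sample sizes. The
node profile is the nested average: a node's value recursively averages
its children's cross-combinations down to pairwise tip overlaps — an
estimate of average overlap per node without ancestral-state
reconstruction; binary trees are assumed. The age–overlap statistic is
Spearman's r_s over internal nodes (refused below 3 nodes; average
ranks for ties). A model is rejected when the observed r_s falls outside
the simulated 5–95% quantiles (nominal level 0.10, two 5% tails); the
calibration suite runs this with the observed dataset refit per
replicate, at n_sims = 200 and a 10-tip tree to keep runtimes in
minutes; problem sizes are stated with each test.

## Decision engine

The staged workflow is deterministic and fully audited: (1) IBD
rejection retains; (2) IBD congruence synonymizes; (3) otherwise any
genomic-independence failure (non-monophyly, admixture, gdi < 0.2)
synonymizes; (4) otherwise retention requires at least one additional
character differentiated beyond its benchmark band plus an analyst
attribution check (differences not explained by plasticity or
ecological flexibility). When no additional character data exist the
default verdict is *inconclusive*, not synonymize — absence of data is
not absence of differentiation (a config lean to synonymize is
available). Groups of three or more candidates are handled pairwise;
transitivity conflicts are reported, not resolved.

## Synthetic data

The spatial genotype generator is a stationary AR(1) stepping-stone
surrogate, not a coalescent: per SNP, deme allele-frequency deviations
from a Uniform(0.1, 0.9) ancestral frequency form a stationary Gaussian
AR(1) chain along a line of demes (stationary sd s = σ_step/√(1−φ²),
per-step correlation φ = 0.9 by default), clipped to [0, 1]; genotypes
are Binomial(2, p). A mean-reverting chain is essential: π between two
demes is bilinear in their frequencies, so a pure random walk — whose
cross-deme covariance is constant in distance — produces *no* expected
distance decay, and an additive mean-zero boundary jump leaves expected
between-candidate π unchanged. Divergence therefore acts by
decorrelation: at the candidate boundary the chain retains correlation
φ·exp(−σ_div²/2s²), so σ_div = 0 is one continuous population and large
σ_div gives nearly independent frequency fields (the `deep_split`
preset uses σ_div = 0.5 ≈ 1.8 s). Defaults — 8 demes × 20 km × 4
diploids, 20 windows × 250 SNPs, σ_step = 0.12 — are desk-scale study
conditions under which the benchmark null and candidate simulations
separate cleanly: the heuristic rejects in 0% of continuous-population
replicates and ~100% of deep-split replicates.

What the generator does not emulate: linkage and recombination
structure, site-frequency-spectrum realism, mutation-model detail,
two-dimensional geography, unequal sampling effort, or genealogical
(coalescent) variance across windows — window-to-window variation here
is purely binomial. Passing calibrations therefore show that the
statistic and decision rule behave correctly under clean IBD and clean
divergence, not that the thresholds transfer to any particular empirical
system; on real data the reference nulls must come from benchmark taxa.
Companion generators produce linear trait clines with optional
between-candidate offsets, lognormal pseudo-posterior τ/θ traces of
given means and CV, Gaussian environmental-suitability occurrence
scatters on a synthetic bioclimatic grid, and pure-birth ultrametric
trees. All generators are seed-deterministic.

## Numerical conventions

Empirical quantiles are type-7 everywhere. HPD ties resolve to the
lowest start within a 1e−12 relative tolerance. Half-called genotypes
are missing. Spearman statistics use average ranks. Covariance matrices
receive trace-scaled ridges (≤ 1e−8 relative) only to keep Cholesky
factorizations defined. All resampling takes explicit seeds, and every
CLI report embeds the seeds and configuration used.
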