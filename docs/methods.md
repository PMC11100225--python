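# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the design decisions made where the field's practice
is genuinely open.

## Data model

Abundance tables are taxa × samples everywhere; samples are columns.
Tables are either `counts` (non-negative integers from a profiler) or
`relative` (columns summing to 1 within 1e-9; files are detected as
relative when column sums are within 1e-6 of 1). TSVs are
tab-separated UTF-8, `.` decimals, `#` comment lines. Soil profiles
carry pH (unitless, open interval (0, 14)), soil organic carbon (SOC),
alkali-hydrolyzable nitrogen (AN), available phosphorus (AP), and
available potassium (AK), all in the units of the originating assay.
Metabolite tables are mg/g dry weight. Each input table is treated
independently; no joint normalization across, e.g., bacterial and
fungal tables is attempted.

Zero-mean normalization (used for heat-map style views) is per-vector
(x − μ)/σ with the population σ. Constant vectors are mapped to zeros
with a RuntimeWarning; constancy is detected by exact range, because a
constant float vector can acquire a tiny nonzero σ through cancellation
in the mean.

## Synthetic generator

The generator emulates the *post-profiling* state of a multi-site
rhizosphere study: 8 sites × 5 plants (40 samples) by default, matching
the common design of such surveys, with a 200-taxon compositional count
table at depth 50,000 reads per sample (a generator convention; real
studies rarely report a single depth). Per-sample counts are a
multinomial draw from latent fractions, so count columns sum to the
depth exactly.

Five planted "core" taxa have log-abundances drawn from a multivariate
normal with equicorrelation ρ = 0.8, log-mean 1.0 and log-sd 2.0. The
mean keeps the block at ≈3% mean relative abundance — far above the
0.01% candidate threshold, with prevalence ≈100% — while the large
log-sd keeps the planted correlation dominant over the compositional
distortion introduced by the shared normalizing denominator: with a
smaller spread the Spearman correlation of the *fractions* decays well
below the correlation of the underlying log-abundances. Non-core taxa
are independent log-normals with per-site mean shifts (sd 0.5) and
Bernoulli occupancy with per-taxon probability ~ Uniform(0.2, 0.6),
producing a realistic prevalence spread around the 75% cut.

Soil variables are exogenous: per-site effect (sd 0.5, i.e. 25% of
variance at the site level) plus sample-level noise, scaled to unit
population variance. Endogenous variables (fungal and bacterial
composition scores, the metabolite) are linear in their standardized
parents with Gaussian noise whose sd is solved so each variable has
*exactly* unit population variance; the recorded ground-truth
coefficients are therefore standardized coefficients, directly
comparable with the fitted model. The default coefficient set mirrors
the soil → fungi → bacteria → metabolite topology of published
rhizosphere structural models with strong (|β| 0.2–0.5) effects;
published standardized coefficients above 1 cannot be planted in a
unit-variance simulation (they would imply negative residual variance).
Raw-scale presentations (pH ≈ 5.8 ± 0.6, BSP ≈ 280 ± 75 mg/g) are
affine transforms for realism only; all fitting is on standardized
variables.

One global seed is split (via `SeedSequence.spawn`) into independent
community and soil/metabolite streams, so regeneration is bit-identical
and enlarging one component does not perturb the other.

What the generator does **not** emulate: sequencing-read noise,
phylogenetic correlation, zero-inflation beyond Bernoulli occupancy,
taxon-taxon ecological interactions outside the planted block, or any
coupling between the abundance table and the community-composition
scores used by the path model (the scores are generated variables).
Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not performance on real
profiling output.

## Diversity

Shannon entropy uses natural log (base configurable); Simpson is
Gini–Simpson 1 − Σp²; Chao1 is the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)) and requires integer counts. Kruskal–Wallis
uses the standard tie correction; all-identical data returns H = 0,
p = 1 by convention. Bray–Curtis operates on per-sample fractions.

PCoA eigendecomposes the double-centered squared-distance matrix;
negative eigenvalues are reported, not corrected. NMDS is non-metric
SMACOF: isotonic regression (average ties) of configuration distances
on the dissimilarities, followed by a Guttman-transform update,
iterated until the stress-1 decrease falls below 1e-7 or 300
iterations; the first start is the PCoA configuration, remaining
restarts random, best of 20 kept. Although k < n − 1 is the sensible
regime, k up to n − 1 is accepted because n points always embed exactly
in n − 1 dimensions (3 points in the plane reach stress 0).

ANOSIM ranks the condensed distances once and contrasts between- versus
within-group mean ranks; p counts permutations with R ≥ observed
including the identity, over n_perm + 1, so p ≥ 1/(n_perm+1) always.
Singleton groups contribute no within-group pairs and trigger a
warning.

## Core-taxon network

Prevalence is read inclusively (≥ 0.75); the abundance cut is strict
(> 1e-4). Both estimators of association are provided because practice
mixes them: Spearman (default; exact average-rank ties, t-distribution
p) and SparCC for counts. The SparCC basis-variance system uses the
standard sparsity approximation (matrix with D−1 on the diagonal, 1
elsewhere), iteratively excluding the most-correlated pair (threshold
0.1, up to 10 exclusions) and averaging over 20 Dirichlet
(pseudocount 1) posterior draws. SparCC p-values come from a
permutation null in which each taxon's counts are shuffled
independently across samples and the whole matrix is recomputed with a
single posterior draw — a documented economy; shuffling whole sample
columns jointly would leave all pairwise associations intact and test
nothing. `n_perm=0` skips p-values for r-only thresholding.

Nodes with no surviving edge are dropped from the graph. Average path
length is over connected pairs only; clustering is the mean local
coefficient (degree < 2 contributes 0), with global transitivity also
reported since either convention appears in the literature. Modularity
uses deterministic greedy (CNM) agglomeration on a canonically ordered
copy of the graph (nodes sorted by label), so results are reproducible
and independent of construction order; under exact ΔQ ties, relabelings
that change the sort order may change the partition — an unavoidable
property of tie-sensitive agglomeration.

Closeness uses the Wasserman–Faust component scaling
((n_r−1)/Σd)·((n_r−1)/(n−1)); betweenness is normalized by
(n−1)(n−2)/2. The composite core rank is the mean of the three
centrality rank positions (average ties), with ties broken by degree,
closeness, betweenness, then lexicographic taxon id — the combination
rule is not standardized in the field, so it is explicit and
configurable here. Edge p-values are used raw by default (mirroring
common practice); a BH-adjusted mode is available in the correlation
utilities.

## Differential abundance

The scorer is LEfSe-*like*, not LEfSe: the subclass/Wilcoxon stage is
omitted (no subclass structure in a one-factor site design) and the
exact effect-size formula of the original tool is under-documented, so
this module fixes its own: after a Kruskal–Wallis screen (α = 0.05),
abundances are scaled to per-million; per bootstrap round (30 rounds,
2/3 of each group, re-drawn if any group falls below 2), the effect
size per surviving taxon is the mean of (a) the average absolute
group-mean difference over group pairs and (b) the absolute
linear-discriminant coefficient times the taxon's pooled within-group
sd, and the score is log10 of the effect clipped below at 1. The LDA
step uses a least-squares solver with automatic shrinkage (defined for
collinear compositions), one-vs-rest for > 2 groups. Bootstrap draws
are keyed to lexicographically sorted sample ids, making scores
invariant to column order. Selection requires both the screen and
score > 4 (configurable), so raising the threshold can only shrink the
selected set.

## Environment linkage

RDA Hellinger-transforms the community table (square root of fractions
— the standard variance-stabilizing choice for relative abundances;
`none` and `chord` are available), column-centers it, z-scores the
environment matrix, and takes the SVD of the fitted values of the
multivariate regression. The constrained proportion is
SS(fitted)/SS(total); per-axis proportions sum to it exactly.
Collinear environment matrices are rejected with the offending columns
named. Mantel defaults to Spearman over the condensed entries with 999
joint row/column permutations, one-sided (greater) — the flavor and
count are unstated in much of the literature, so the package picks the
rank-based option consistent with its other tests. Pairwise correlation
tables use BH adjustment by default with a raw-p option.

## Path model

Observed variables only: the modeled quantities (soil chemistry,
community-composition scores, a metabolite index) are all measured or
computed scalars, so no latent structure is introduced. Community
composition enters as the first ordination axis (PCoA of Bray–Curtis by
default, NMDS selectable) sign-anchored to correlate positively with
the most abundant taxon; any other scalar (e.g. a diversity index) can
be substituted. The default metabolite variable is a single compound or
the first principal axis of the z-scored metabolite table, at the
caller's choice.

Fitting is covariance ML on z-scored data (for this recursive class
that equals post-hoc standardization): free parameters are the path
coefficients, endogenous residual variances (parameterized as squared
sds) and the exogenous covariance block (parameterized by its Cholesky
factor, keeping Σ(θ) positive semidefinite throughout). BFGS with
numerical gradients from per-equation OLS starting values, gradient
tolerance 1e-9, 500 iterations maximum; for fully recursive models the
OLS start is already the optimum. BFGS occasionally reports "precision
loss" on the flat optimum; the fit is flagged converged when the final
gradient norm is below 1e-5. χ² = (n−1)·F at the optimum with
df = p(p+1)/2 − n_free (df = 0 → p-value 1); GFI is the ML variant
1 − tr((Σ⁻¹S−I)²)/tr((Σ⁻¹S)²); SRMR averages squared standardized
residuals over the lower triangle including the diagonal. A
per-equation OLS "piecewise" mode evaluates the same indices at the
OLS solution for comparison with piecewise-SEM workflows.

Effects: direct = B, total = (I−B)⁻¹ − I (a finite sum because B is
nilpotent under the causal order), indirect = total − direct; the
identity holds to machine precision by construction and is asserted in
tests.

## Problem sizes and determinism

Recovery experiments use 10 seeds at n = 200 samples (core/SparCC) and
n ≈ 500 (path model), sizes at which the planted effects are
statistically identified while the full suite runs in well under a
minute; null-calibration suites use 200 replicates with 199
permutations each. Every stochastic routine takes an explicit seed;
`rhizolink all` writes a manifest of output checksums, and identical
config + seed reproduces identical checksums.

## Known limitations

- SparCC p-values use a single posterior draw per permutation; they
  are slightly noisier than a full-resampling null.
- Greedy modularity is deterministic but tie-sensitive (see above).
- The LEfSe-like score is not numerically comparable to the original
  tool's output, only to its selection behavior.
- The path model fits covariances; means are ignored, and no
  bootstrap confidence intervals for indirect effects are provided.
- Ordination-axis community scores discard all but one axis of
  compositional variation; parity with any particular published
  coefficient set is not claimed.
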