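# Methods

This note documents the models, defaults and design choices behind
`parasnail`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design the package assumes

Two ecotypes ("crab", "wave") sampled as sympatric pairs in three
localities. Expression is measured on one-channel arrays from pooled
samples (default 4 pools per ecotype and locality, 22 of 24 retained after
QC-style dropout); coding-sequence divergence by two-channel CGH, each
individual (default 12 per group, 69 of 72 retained) hybridized against a
common reference so M = log2(sample) − log2(reference) isolates sequence
divergence from probe affinity. Each gene is represented by a probe set
(default 5 probes); empty spots report the background level.

## Preprocessing

**Expression** (one channel, log2): across-array quantile normalization;
background threshold = mean log2 intensity of the empty spots over probes
and samples; a gene is discarded iff strictly more than 20% of its probes
have mean signal below the threshold (a 1-in-5 probe gene sits exactly at
the boundary and is kept); surviving probe sets are collapsed by Tukey
median polish (row sweep first, tolerance 1e-4, at most 10 iterations;
summarized value = overall + sample effect; single-probe genes pass
through). Median polish of a rank-one block recovers the sample effects
exactly up to an additive constant.

**CGH** (two channels): if intensities arrive on the linear scale they are
normexp-background-corrected per channel — X = S + B with S ~ Exp(θ) and
B ~ N(μ, σ²); (μ, σ) estimated from the empty spots, θ from the excess of
the gene-probe mean over μ; every x is replaced by
E[S | X = x] = a + σ φ(a/σ)/Φ(a/σ), a = x − μ − σ²/θ, which is strictly
positive — then an offset (default 16) is added before log2. A
non-positive σ estimate falls back to subtract-and-floor with a warning.
Channels are then quantile-normalized jointly (two-color variant: all
channels of all arrays pooled as columns). Probes are kept only when the
mean normalized log2 signal clears the background threshold in **both**
channels; the threshold is the per-channel empty-spot mean unless a
platform constant is supplied (`threshold_cgh`, e.g. 10.7). Filtering is
applied after normalization so a constant threshold is scale-stable; the
alternative (raw scale) is a config choice. The joint filter retains genes
kept by the expression filter whose CGH-kept probe set is nonempty, and
those genes' CGH-kept probes.

Ties in quantile normalization receive the mean of their tied quantile
values (deterministic and symmetric); rank order within each column is
preserved.

## Row-wise moderated linear models

All analyses use a group-means design over the ecotype × locality cells
(six cells in the full design), which keeps the three published contrast
families estimable without reference-level ambiguity:

* ecotype within locality — three 1-df crab-minus-wave contrasts;
* factorial — ecotype main effect (1 df), locality main effect (2 df),
  interaction (2 df);
* locality within ecotype — a 2-df among-locality contrast per ecotype.

Per feature, OLS gives β̂, s², d = n − #cells. The empirical-Bayes step
assumes s² | σ² ~ σ² χ²_d / d and σ² ~ s₀² d₀ / χ²_{d₀} and estimates
(d₀, s₀²) by method of moments on log s²: with
e = log s² − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = Var(e) − ψ′(d/2) by a
Newton inversion of the trigamma function, then
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the spread of log s² does
not exceed its pure sampling component the prior df is infinite and
s̃² = s₀² = mean(s²). Posterior variances
s̃² = (d₀ s₀² + d s²)/(d₀ + d) feed moderated t (df d₀ + d) and moderated
F statistics. No robustification (outlier-variance down-weighting) is
applied — plain method of moments, documented as such. Expression is
modeled at the gene level (summarized values), CGH at the probe level;
gene-level CGH calls derive downstream by the any-significant-probe rule.

Note one consequence of summarization: median polish averages a probe set,
so gene-level residual variances sit on a smaller scale than the
generator's per-probe prior. The prior *df* d₀ is scale-free and is
recovered at either level; the prior *variance* s₀² is recovered on the
measurement scale, i.e. at the CGH probe level.

## SGoF

With n p-values and γ = α = 0.05, F = #{p ≤ γ}. Starting at c = F, while
the exact binomial survival probability P[X ≥ c | Bin(n, γ)] ≤ α, one more
feature is declared and c decreases. Declared features are the n_declared
smallest p-values, ties broken by stable input order (the underlying
procedure leaves tie order open). A chi-square approximation of the
binomial test is available for cross-checking large-n behavior. The
correction is applied per contrast column by default; a pooled option
(one SGoF over all three locality contrasts) exists because the
alternative reading is defensible.

A structural property worth knowing: SGoF declares only the *excess* of F
over the binomial critical count (≈ nγ + z_α √(nγ(1−γ))). With 5% true
positives among 2,000 tests, even perfect per-test power cannot push the
declared fraction much past ~0.8 of the true features, and a three-way
intersection of such lists lower still. Recovery expectations for
SGoF-based parallel sets must be read against that ceiling.

## Parallelism null

The exact null treats the three per-locality significant sets as
independent uniform subsets of fixed sizes n₁, n₂, n₃ from the N analyzed
features: |A∩B| is hypergeometric (N, n₁, n₂), and given |A∩B| = m the
triple overlap is hypergeometric (N, m, n₃); convolving gives the pmf of
K with E[K] = N ∏(nᵢ/N). The three-set construction is this package's
explicit formalization of the published two-group gene-list overlap
algorithm extended to three localities (the original extension was never
published). The permutation route (`gene_shuffle`, default R = 10,000;
200,000 matches the published scale and is a config value) re-draws which
features carry each locality's calls, preserving the per-locality counts —
its null mean matches the exact E[K], which the tests verify. A `label`
mode permutes ecotype labels within localities and re-runs the model + SGoF
chain (far costlier; reduced R recommended); both are provided because the
published "data were sorted" procedure does not pin down which was used.
Permutation p-values use (1 + #{≥ obs})/(R + 1) and are never zero.

## Directionality, variance, geography

Signs come from the moderated contrast estimates (the same quantities that
drove significance). D requires all three signs equal and nonzero; a zero
estimate counts as a mismatch. The randomization null permutes the signed
estimates within each locality across the parallel features (restricting to
the parallel set is the stricter choice; a wider pool — e.g. all analyzed
genes — is available via the `pool` argument). Expectations and 95%
percentile CIs come from the permutation replicates. When every feature
shares one sign pattern the permutation cannot alter D and the tie-counting
p-value is 1 by construction.

Intrapopulation variance = mean over the six ecotype × locality groups of
the within-group unbiased variance (groups with < 2 replicates skipped).
D vs ND is compared by a pooled-variance two-sided t test (Welch behind a
flag) and by a label permutation with the absolute mean difference as
statistic; the reported ratio is mean(ND)/mean(D). If both classes are
exactly constant and equal, t = 0 and p = 1 by convention.

Geography: within each ecotype, features with a significant 2-df
among-locality moderated F after SGoF form the differentiated set; the
fraction of the parallel set in it is compared with B = 1,000 same-size
uniform resamples from the analysis universe (null mean, 95% percentile
CI, upper-tail p). "Nonparallel" defaults to features significant in at
least one but not all localities; the complement-of-parallel definition is
a config switch.

## Synthetic data generator

The generator emulates the assumed study design at a reduced default scale
(2,000 genes × 5 probes, 200 empty spots) so the full pipeline runs in
seconds; the real platform is an order of magnitude larger. Defaults:
baseline gene level 12 (log2), between-gene sd 1, probe affinity sd 0.5,
empty spots N(8, 0.5²), per-gene within-group variances drawn from the
moderation prior with d₀ = 4, s₀² = 0.05 (so the empirical-Bayes step has
a true value to recover), dropout of 2 pools / 3 individuals mirroring the
assumed QC losses. Effects are injected directly on the log2 scale;
`effect_size` defaults to 3 in units of the gene's own within-group sd
(`effect_scale="sd"`), making per-gene power homogeneous; absolute log2
units are available. Gene classes (parallel directional, parallel
nondirectional, locality-specific, null) are assigned by rounded fractions
without replacement; directional signs are symmetric Bernoulli(0.5) draws,
which realizes the intended symmetric null directionality (the signed
effect is carried by the crab group; every tested contrast is
distribution-identical to randomizing the carrier ecotype). CGH effects are
realized on a random subset of each divergent gene's probes (default 60%,
at least one), giving the many-probes-to-one-gene structure that gene-level
"any significant probe" calls assume. Optional per-locality offsets shared
by both ecotypes (`geo_sd_parallel`, `geo_sd_nonparallel`) create genuine
geographic differentiation. A `directional_var_factor` scales the
within-group variance of directional genes (0.5 reproduces the
"directional changes have half the variance" scenario).

What the generator does **not** emulate: probe-sequence/GC effects,
spatial artifacts, scanner saturation, correlated probe noise within a
gene, or linear-scale mean–variance coupling. Passing tests therefore
validate the statistical chain under its own assumptions, not robustness
to platform-specific artifacts.

The within-pool vs between-pool variance split for pooled expression
samples is not pinned down by the design; `pool_size_effect` (default 1)
divides the noise sd by its square root and is left to the user.

## Numerical and reproducibility choices

Trigamma inversion by safeguarded Newton (unique root; tolerance 1e-10).
Median polish convergence: max |adjustment| < 1e-4 or 10 iterations.
Quantile ties: mean of tied quantiles. All randomized stages take explicit
seeds; the pipeline derives per-stage child seeds from one master seed via
`SeedSequence`, and reruns with the same config are byte-identical.
Percentages are printed half-up at one decimal with a trailing ".0"
stripped; values below 0.1% are truncated at two decimals; within-parallel
fractions print as integer percent — matching the precision conventions of
the count tables this reporting style imitates.

## Problem sizes used by the test and acceptance runs

The suite exercises the pipeline at the generator's default scale (2,000
genes; 100-seed null calibration for the intersection coverage check;
10,000 rows for the null-uniformity KS checks; 10⁵ Monte-Carlo subset draws
per configuration against the exact intersection null). The
variance-comparison scenario averages its ND/D ratio over three replicate
datasets: the per-gene variance prior at d₀ = 4 is heavy-tailed (its
second moment does not exist), so a single dataset's ratio of class means
is noisy by design and averaging replicates is the appropriate estimator
of the simulated twofold factor. Permutation counts are scaled to desk
runtime (R = 2,000–10,000; B = 200–1,000); the config accepts the
published-scale R = 200,000 where exact replication of that budget is
wanted.

## Known limitations

* SGoF's declared-count ceiling (above) bounds recovery of dense signal;
  this is a property of the chosen correction, not of the implementation.
* Gene-level CGH significance by "any significant probe" does not control
  the gene-level error rate; it mirrors the reporting convention the
  pipeline imitates.
* The moderated F for multi-df contrasts assumes a common posterior
  variance across the contrast's cells; no array-quality weights or
  duplicate-correlation structure is modeled.
* No sex covariate enters the CGH models; individuals are treated as
  exchangeable within ecotype × locality.
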