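# Methods

This note records the statistical model behind `morphodist`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Data model

An assemblage is a flat table: one row per unretouched flake, one grouping
column (cultural phase, or raw material in the corresponding sensitivity
variant), and 16 attribute columns declared by a schema. The packaged
default schema follows a standard flake recording protocol: 7 continuous
variables (percent cortex CPE, length LEN, width WID, thickness THI,
exterior platform angle EPA, platform width PWI, platform thickness PTH),
2 ordinal variables (bulb expression BUL, 5 grades; number of dorsal
negatives NNU, 10 grades) and 7 nominal variables (raw material RMA, shape
SHA, eraillure scar ESC, lip LIP, Hertzian cone HCO, platform type PTY,
orientation of negatives NOR). LEN, WID, THI, PWI, PTH carry a geometry
flag. Any cell may be missing; empty strings and NA-style tokens parse as
missing, and unparseable continuous cells become missing rather than
aborting a read.

**Filtering.** Records are retained when they carry a group label and at
most ⌊f·p⌋ missing attributes (default f = 0.20 over p = 16 variables,
i.e. at most 3). Filtering is idempotent and logs per-group retained counts
so sample sizes are auditable.

**Shape variables.** Geometry measurements are divided by the per-flake
geometric mean of the geometry block, removing gross size so that flakes of
different sizes but similar proportions become comparable. The protocol
does not dictate how size correction interacts with missing geometry cells,
so the default computes the geometric mean over the observed geometry
subset of each record (broken flakes stay size-corrected and analysable); a
strict mode transforms only complete geometry blocks and leaves the rest
untouched. The observed-cell product after transformation is 1 by
construction, which the tests verify to 1e-10. Whether the shape transform
runs before or after filtering is an orchestration choice; the pipeline
filters first so that the missingness cap refers to the recorded data.

## Heterogeneous correlations

Associations among mixed-scale variables are estimated under a latent
Gaussian model: Pearson for continuous pairs, polychoric for
ordinal/ordinal (tetrachoric when 2×2), polyserial for continuous/ordinal
(biserial when binary). Polychoric and polyserial use the two-step
estimator — thresholds fixed at inverse-normal cumulative marginals, then a
bounded scalar search for ρ on [−0.999, 0.999] maximising the
bivariate-normal cell likelihood — which is the common default in practice
and avoids the cost of joint ML with no practical accuracy loss at these
sample sizes. Bivariate-normal rectangle probabilities come from scipy's
multivariate normal CDF at absolute tolerance 1e-10; cell probabilities are
floored at 1e-12 inside the log-likelihood.

Missing data are handled by pairwise deletion (the correlation summary is
descriptive and precedes imputation in the workflow). Nominal variables
with more than two categories enter the displayed matrix as per-category
binary indicators, so single categories (e.g. platform type
"linear/punctiform") appear as their own rows/columns; indicator pairs from
the same parent variable are mutually exclusive by construction and sit at
the negative boundary, which is expected and left visible. Undefined pairs
(degenerate margins, too few complete cases) are reported as NaN with a
diagnostic, never silently zeroed. An optional eigenvalue-clipping repair
restores positive semi-definiteness and records whether it ran; repair is
skipped (and flagged) when the matrix contains undefined entries.

## Mixed-data PCA and distances

Encoding: continuous and ordinal-rank columns are z-scored (ordinal levels
treated as equally spaced integer ranks, the PCAmix convention); each
nominal category k becomes a centred indicator divided by √p_k (FAMD
convention), so an all-continuous table reduces exactly to classical
correlation-matrix PCA — a property the tests assert to 1e-10. Zero-variance
columns (constants, unobserved categories) are dropped with a notice.

Scores are the encoded matrix projected on the eigenvectors of its
covariance (denominator n−1). Distances are Euclidean over scores divided
by √eigenvalue, restricted to components with eigenvalue above 1e-8 times
the largest; this equals the Mahalanobis distance in encoded space and, on
two correlated continuous variables, matches the textbook
inverse-covariance form to 1e-10. All non-degenerate components are
retained by default because the inference stage deliberately uses the full
high-dimensional space, not just the plotted plane; a fixed component count
is configurable.

## Multiple-imputation combination

Missing cells are imputed by independent marginal resampling of each
variable's observed values — the weakest assumption available, whose
between-imputation variability is exactly what the interval machinery
quantifies. A within-group hot-deck mode is provided (off by default) for
users who prefer group-conditional draws. With m imputations (default
1000; tests and the fast profile use 8–50), each completed table yields a
PC model and a distance matrix. Per-pair medians and 2.5/97.5% bounds
(linear-interpolation quantiles; level configurable) are computed in pair
blocks from the stored per-iteration score matrices, so m full n×n
matrices are never materialised at once. With no missing cells the
procedure collapses to the single-run distance matrix exactly, intervals
have zero width, and object ellipses are degenerate.

Distances are invariant to PC sign and rotation, so only the plotted
coordinates need alignment: per-PC signs are fixed by maximising loading
agreement with the first (reference) iteration, then an orthogonal
Procrustes rotation of the first-two-PC plane (estimated on loadings,
applied to scores) aligns each iteration for averaging. Object centroids
are means of the m aligned positions; their 95% ellipses use the 2×2
covariance of those positions scaled by the χ²(2) quantile — a bivariate
normal ellipse was chosen over an empirical hull because m positions per
object are cheap and near-elliptical in practice. Group centroids average
object centroids; group dispersion ellipses use the same χ² construction
on the object-centroid cloud. Variable arrows are correlations of encoded
columns with the aligned PC1/PC2 scores, averaged over iterations; their
norms are bounded by 1.

## Permutation inference

**PERMANOVA.** With N objects in a groups, SS_T = (1/N)Σ_{i<j} d²_ij,
SS_W = Σ_g (1/n_g)Σ_{i<j∈g} d²_ij, SS_A = SS_T − SS_W,
F = (SS_A/(a−1))/(SS_W/(N−a)), R² = SS_A/SS_T. On Euclidean distances of
1-D data this equals the classical one-way ANOVA F. Sampled p-values use
(b+1)/(m+1) with ties counted as exceedances (conservative); tiny problems
can be enumerated exhaustively over all distinct label arrangements, where
p is the plain exceedance fraction (the observed arrangement counts
itself), giving p = 1/3 on the canonical 4-point example. Degenerate
partitions use a scale-relative tolerance (1e-12 of SS_T) to classify
zero within-group variance as F = ∞ (or 0 when between-group variance is
also zero) rather than amplifying floating-point noise.

**PCoA / PERMDISP.** Principal coordinates come from the eigen-decomposition
of the double-centred −½D² matrix; axes with negative eigenvalues are kept,
scaled by √|λ|, and flagged imaginary, with the negative-eigenvalue mass
reported. Each object's distance to its group centroid subtracts the
imaginary-axis contribution from the real-axis contribution, clamping
negative corrected squares at zero with a diagnostic count. The group
centroid is the coordinate mean by default; a spatial-median mode
(Weiszfeld) is provided as a sensitivity switch, since reference
implementations differ on this point. Significance permutes object-to-group
assignments and recomputes centroids and distances per permutation — the
self-consistent scheme; a faster mode permuting the fixed distances is
available. R² is the between/total sum-of-squares ratio of the distances.

**Pairwise testing.** Every unordered group pair is balanced by randomly
down-sampling the larger group to the smaller one's size (PERMANOVA is
robust to heterogeneity only in balanced designs), then both tests run on
the restricted distance matrix with a per-contrast seeded stream (default
seed 1). Significance is starred at the Bonferroni level α/(number of
pairs); with 1000 permutations the attainable p floor is 1/1001.

**Dispersion profiles.** For sina-style plots, the distance of each object
to its group centroid is computed directly from the distance matrix by the
Gower identity d²(i,c_G) = (1/n_G)Σ_{j∈G}d²_ij − (1/n_G²)Σ_{j<k∈G}d²_jk
(clamped at 0), with per-group medians and 2.5–97.5% interpercentile
ranges. On Euclidean-embeddable matrices this matches coordinate-space
distances to 1e-8.

## Synthetic assemblages

The generator draws a latent Gaussian vector per flake — one dimension per
continuous and ordinal variable — with a configurable correlation matrix
(default: the five geometry dimensions share an exchangeable size factor,
ρ = 0.4), then applies per-group mean shifts (latent SD units) and
dispersion multipliers. Observation maps: geometry variables are lognormal
(e.g. length with median 32 mm, log-SD 0.35, matching realistic calliper
ranges); percent cortex is a clipped linear map to [0, 100] with a mass at
0; platform angle is clipped to [35°, 105°]; ordinal variables threshold
their latent dimension at cut points derived from the packaged reference
level frequencies; nominal variables are drawn from per-group categorical
tables whose base frequencies are the packaged reference counts (dolerite
dominant at ~71%), with an optional phase-graded log-probability tilt on
raw material, platform type and negative orientation — the variables that
carry the cultural signal in real sequences. Defaults encode the study-like
conditions: four ordered phases, a 0.3-SD-per-step latent gradient on three
dimensions, U-shaped dispersion multipliers (1.3, 1.0, 1.0, 1.3).
`SimulationConfig.null()` produces exchangeable groups for calibration
experiments. Missingness is injected strictly MCAR per cell; group labels
are never masked.

What the generator does **not** emulate: fracture-mechanical dependence of
nominal states on the latent space (nominal draws are group-conditional but
latent-independent), measurement rounding to integer millimetres,
missingness that depends on breakage (MAR/MNAR), and inter-observer error.
Passing tests therefore demonstrate calibration, invariances and recovery
under known, well-behaved conditions — not robustness to informative
missingness or observer effects in real assemblages.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately moderate problem sizes chosen
to give stable Monte-Carlo estimates: 1,000 null replicates at n = 30/group
with 199 permutations for type-I rates (binomial SE ≈ 0.7 percentage
points), 100 replicates at n = 100/group for power, 20 replicates of
four-phase assemblages at n = 80/group for the graded-signal ordering,
m = 10–50 imputations where only identities or orderings are asserted, and
n = 5,000 for latent-correlation recovery. Quantiles use linear
interpolation; eigenvalues are clipped at zero below 1e-10 relative noise;
optimiser tolerance for latent correlations is 1e-6 on ρ.

## Known limitations

- Marginal resampling imputes without preserving inter-variable
  correlation; intervals quantify this variability but the median matrix
  can be attenuated under strong correlation with heavy missingness.
- Two-step (not joint) ML for polychoric/polyserial is slightly less
  efficient at small n.
- The exhaustive permutation mode is limited to n ≤ 12.
- Single-factor designs only: no nested or multi-factor partitions, no
  permutation strata.
- Ordinal variables enter the PCA as equally spaced ranks; strongly
  non-linear level spacings are only captured by the correlation summary,
  not the ordination.
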