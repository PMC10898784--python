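# Methods

This note documents the models, conventions, and design choices behind
`connectoprint`, in the order the pipeline runs.

## Functional connectomes and edge bookkeeping

Each subject contributes a regions × timepoints BOLD matrix on a fixed
parcellation (200 cortical regions, each assigned to one of the seven
canonical resting-state networks: Vis, SM, DA, VA, LIM, FPN, DMN). The scan
is split into temporal halves — samples `[0, T//2)` and `[T//2, 2·(T//2))`,
dropping the final sample when `T` is odd so both halves have equal length
and Iself is not biased by unequal estimation noise. Pearson correlation of
the raw series (no rank transform, no additional filtering; preprocessing is
upstream of this package) gives first-half, second-half, and full-scan FCs.

All downstream computation uses one canonical edge order: the row-major
upper triangle with `i < j`, zero-based internally and one-based region ids
in emitted files. For N = 200 this gives 19,900 edges. A single fixed order
makes ICC ranks, edge selections, and PCA loadings comparable across runs.
Missing values are a hard error — corrupted subjects are excluded, never
imputed.

## Identifiability

The identifiability matrix of a condition with s subjects is s × s, with
`a[i,j]` the Pearson correlation between subject i's second-half and subject
j's first-half edge vectors over an edge selection. Iothers averages the
off-diagonal row and column of a subject, `(1/2(s−1))·Σ_{j≠i}(a[i,j]+a[j,i])`,
and uses within-condition pairs only; a combined two-condition matrix exists
solely for display. Group means are reported with standard error
`SD/√s`. Correlations are computed on the selected edge values as-is (no
Fisher z-transform); identifiability-curve grids default to
`{50, 100, …, 19,900}` (step 50, ending at the full edge set).

## Edgewise ICC

With two measurements per subject (the two half-FC values of an edge), the
class-1 intraclass correlation is `(MSR − MSW)/(MSR + MSW)` where
`MSR = 2·var(μ)` uses the sample variance (divisor s−1) of the per-subject
means and `MSW` is the mean of the per-subject within-pair variances
`(x₁ − x₂)²/2`. These divisors make the formula coincide exactly with the
classical one-way random-effects ICC(1,1) at k = 2, which the tests verify
against an independent ANOVA oracle and against `pingouin`. Degenerate edges
(all four values equal) get ICC = 0 with a warning so rankings stay total.
Ranking ties are broken by ascending edge id. Condition contrasts use paired
t-tests — pairing edges within an RSN pair, or regions within an RSN — with
Benjamini–Hochberg (not Benjamini–Yekutieli) FDR; strength maps are z-scored
with the sample SD across the 200 regions.

## Prediction

Behavioral PCA z-scores the 11 subscale columns (the subscales live on
heterogeneous sub-score scales) before the SVD; edge PCA mean-centers but
does not scale its columns (edges already share the correlation scale). Both
choices are conventions, not data-driven. PCA signs are arbitrary, so they
are fixed: the behavioral PC1 sign makes the coefficient sum positive (high
b = intense experience); each edge component's sign makes its
largest-magnitude loading positive.

Models are ordinary least squares with intercept, in-sample (no
cross-validation, matching the analysis this package implements). The
overall p is the F-test for multi-predictor models and the correlation
t-test for single predictors. The ensemble comparison is a two-sided
one-sample t-test of the 100 ensemble R² values with the ICC-ranked R² as
the null mean, BH-corrected across the n-grid; a zero-variance ensemble is
reported as p = 1 when it coincides with the reference (t = 0) and p = 0
otherwise. Prediction grids default to step 250 plus a final all-edges
point; the step count is emergent, not hard-coded. Default k = 3 predictors;
with k = s − 1 any generic design reaches R² = 1 (the overfitting identity
the tests assert at k = 20 with 21 subjects).

Spin surrogates preserve spatial contiguity: one random rotation
(QR-orthonormalized Gaussian, determinant +1) is drawn for the left
hemisphere and its x-mirrored image applied to the right; regions are
reassigned to rotated centroid positions by greedy nearest-neighbor matching
without replacement, processing positions in decreasing order of their
nearest-available distance. The result is a hemisphere-preserving bijection;
surrogate models read the same region pairs through the permutation.

## Characterization

Rank-1 reconstruction adds the edgewise mean back
(`x̂_i = mean + score_i·loading`), so reconstructed RSN averages read as
connectivity levels. Archetype matrices weight each subject's RSN matrix by
|score|, separately over positive- and negative-score subjects; subjects
with a score of exactly 0 belong to neither side, and an empty side is
reported as undefined. Per-subject RSN means are computed within subject
first, then averaged across subjects. DMN-block correlations use the real
(non-reconstructed) full-scan FCs; DMN-attentional pools DMN-DA and DMN-VA
edges, DMN-sensory pools DMN-Vis and DMN-SM.

## Synthetic cohorts

The generator emulates the statistical skeleton the analysis assumes of a
placebo-controlled psychedelic study: 21 drug and 25 placebo subjects, 200
regions, T = 256 timepoints (≈ 6 min at a 1.4 s sampling interval). Each
subject's series are T i.i.d. draws from a zero-mean Gaussian with a
subject-specific correlation matrix

    Σ_i = C_base + α_c·W_i + γ·G_i + β·b_i·P

- `C_base`: block structure, 0.35 within an RSN, 0.05 between.
- `W_i` (signature component): a subject-fixed symmetric Gaussian field on
  edges incident to the condition's signature RSNs — FPN under placebo
  (α = 0.055), DMN ∪ Vis under the drug (α = 0.075) — attenuated to 0.6 on
  edges with only one signature endpoint. This is what makes the two
  conditions idiosyncratic in different places.
- `G_i` (diffuse heterogeneity, γ = 0.07): a subject-fixed Gaussian field on
  all edges. Real cohorts carry large unspecific inter-subject FC variance;
  without this term, random edge selections would pick up the planted
  behavioral pattern essentially noise-free and match the ICC-ranked models,
  which would misrepresent the phenomenon the pipeline exists to detect.
- `P` (planted pattern, β = 3.4): unit-Frobenius, concentrated on a fixed
  24-region DMN core (12 per hemisphere): −1 on core–core edges, −0.2 on
  core–LIM, +0.2 on core–DA and core–VA. Concentration on a core mirrors
  empirical reports that such patterns load on a posterior-medial/prefrontal
  subset of the DMN rather than the network as a whole, and it is what lets
  a top-n ICC selection capture most of the pattern's norm while a random
  selection of the same size captures only n/19,900 of it. `b_i` is standard
  normal for drug subjects and 0 under placebo.

Σ is repaired to a valid correlation matrix by clipping eigenvalues at
ε = 1e−4 and rescaling to unit diagonal. Behavior subscales are
`λ_j·(b_i − min b) + noise` (λ all positive, largest on insightfulness,
unity, bliss, and changed-meaning; noise SD 5), clipped at 0 — giving a
dominant all-positive first component whose scores track b. The motion
covariate is drawn per condition (means 14.2 vs 10.0, SD 7, rounded and
clipped at 0) and deliberately has no effect on the signal: it exists to
exercise the covariate-adjusted group tests, an honest simplification.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics, scanner noise, motion corruption of the signal, session
effects, and any spatial smoothness of the idiosyncratic fields beyond the
RSN block structure. Passing recovery tests therefore show that the pipeline
detects the planted structure under the stated covariance model — not that
real data contain such structure.

## Problem sizes and numerical choices

Unit tests run on a 40-region, 8+8-subject configuration; the recovery
suite and the reproduction script run the full default scale (200 regions,
46 subjects, 100-model ensembles) over 20 replicate seeds, a scale chosen to
keep a complete run in the low minutes on one CPU. Tolerances: FC and
identifiability values match brute-force oracles at 1e−12; ICC matches the
ANOVA oracle at 1e−10; PCA reconstructions at 1e−10. All randomness flows
through `numpy.random.Generator` seeded from a single integer; regenerating
a cohort with the same configuration is byte-identical on disk.

## Known limitations

- ICC confidence intervals and other ICC classes are out of scope.
- Models are in-sample by design; no cross-validated prediction.
- The spin surrogate operates on synthetic spherical centroids; with real
  parcellation centroids the same code applies unchanged.
- The greedy spin matching is order-dependent (a deliberate, reproducible
  choice); it is not an optimal-transport assignment.
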