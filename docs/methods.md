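# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design choices made where the design was
genuinely open.

## Bootstrap laterality index

**Model.**  For a t-statistic volume with left/right hemisphere masks and an
exclusion mask, voxels are kept if they lie in a hemisphere mask, outside
the exclusion mask, and are *strictly* above the threshold (default t = 0:
the positive t-map; zeros are excluded).  Per hemisphere, `n_iter` (default
100) resamples with replacement of size `clamp(round(k·n_voxels),
min_sample, max_sample)` (defaults k = 0.25, 5, 1000) are drawn; all
`n_iter²` pairwise left/right combinations give indices
`100·(L−R)/(L+R)` where L and R are resample *sums* of voxel t-values
(magnitude-weighted; a count-based mode exists behind
`BootstrapConfig(weighting="count")`).  The lowest and highest
`trim_fraction` (default 0.25 per tail) of the combinations are discarded
and the mean of the rest is the index.

**Numerical choices.**  Voxel values are sorted before resampling so the
result is invariant to voxel storage order; the two hemispheres use
independent child generators spawned from one seed (`mirror_seed=True`
exchanges them, making left/right swap an exact negation when resample
sizes agree).  The index is exactly 0 for a mirror-symmetric noiseless
volume and exactly ±100 when one hemisphere is silent and the other has at
least `min_sample` suprathreshold voxels; a hemisphere with 1–4
suprathreshold voxels yields an invalid result with a reason rather than a
number.  A multi-threshold ladder with rank-weighted averaging is provided
(`compute_hfli_ladder`) but is off the default path, which fixes the
threshold at 0.

## Gaussian mixture fitting and model selection

**Model.**  `f(x) = Σᵢ πᵢ φ(x; μᵢ, σᵢ)`, univariate, fit by EM to the HFLI
values of a handedness group.  Components are reported in descending mean
order.  Free parameters: `p = 3n − 1` (n means, n SDs, n−1 weights) — this
count is what makes the single-Gaussian AICc reproducible from printed
sample moments.  Model selection minimizes
`AICc = −2ℓ + 2p + 2p(p+1)/(N−p−1)` over n = 1…5.

**Evidence ratios.**  The per-model relative likelihood defaults to
`exp(AICc_best − AICc_i)` because that convention reproduces the published
model-comparison column; the textbook `exp(Δ/2)` form is available via
`mode="standard"`.

**EM details.**  50 restarts by default; means initialized at sample
quantiles (restart 0) plus Gaussian jitter of half a sample SD (restarts
1+); initial SDs are drawn log-uniformly between twice the SD floor and the
sample SD so that narrow-component local optima are explored equally at
every component count — a search that only finds them at large n biases
model comparison upward.  Convergence: absolute log-likelihood change
below 1e-8, capped at 1000 iterations; monotonicity of the EM objective is
asserted at every iteration (except immediately after an SD clamp, which
voids the guarantee).  The SD floor (0.5 index units) guards the unbounded
likelihood of mixture ML; a restart that ends on the floor, or with a
vanished weight, is discarded as degenerate, and a fit whose restarts all
degenerate is flagged failed rather than reported.  `n = 1` bypasses EM for
the closed-form mean and ML standard deviation.  Internally SDs are ML
(divisor N); cohort summary tables use the N−1 convention, matching how the
printed group moments reconcile with their printed AICc.

**Confidence intervals.**  Nonparametric bootstrap over subjects (resample,
refit, match components by mean order, percentile interval per parameter).
The source analysis does not describe its CI method; this is the package's
choice.  Refits that degenerate are dropped and counted.

**What a single cohort can resolve.**  At N = 153 drawn from the published
4-component left-hander mixture, AICc selects n = 4 in roughly 60% of
replicates and n = 5 in most of the rest (a spurious narrow component
fitted to a chance cluster); the modal choice over ≥100 replicates is
stably 4, and the recovered low-mean component sits at mean ≈ −63,
weight ≈ 6.5%.  This is the computation `scripts/acceptance.py` performs.

## Typing thresholds

Cutpoints are interior local minima of the fitted mixture density, located
by a 0.1-step grid scan for sign changes of the *log*-density derivative
(identical sign, but immune to floating-point underflow in the deep valley
between well-separated components) refined by Brent's method to 1e-3.
A minimum whose density is at least `dip_ratio_threshold` times the lower
of the two flanking modal densities marks a shallow dip, and the two pools
it separates are merged.  The default ratio is 0.7: for the published
parameters the dip between the two left-dominant components has ratio
0.80 (right-handers) and 0.97 (left-handers) while the genuine separations
have ratios ≤ 0.47, so 0.7 splits the two regimes with margin on both
sides.  For the published models this pooling yields exactly the published
grouping: two types for right-handers, three for left-handers.

The minima of the published mixtures fall at ≈ −47.5 and ≈ 22.1, not at the
operational −50 and 18 used in the reference analysis; both are reported,
and the operational pair ships as the `REFERENCE_THRESHOLDS` preset used for
reproduction runs.  Type intervals: Typical strictly above the upper cut,
Strongly-atypical strictly below the lower cut, ties fall to Ambilateral.
The binary classification is strict positivity: HFLI exactly 0 is atypical.

## Association statistics

* **Edinburgh laterality quotient**: `100·(R−L)/(R+L)` over inventory item
  tallies, in [−100, 100].
* **MPS3**: Strong L for score ≤ −55, Strong R only for exactly +100,
  Moderate otherwise (the terciles of a handedness-balanced cohort put a
  full third of subjects at exactly +100).  **MPS7**: extreme single-point
  categories at ±100; interior boundaries resolved downward (−75 → category
  2), keeping the categories mutually exclusive.
* **Kappa**: unweighted Cohen's kappa, `κ = (P₀ − Pₑ)/(1 − Pₑ)`, with the
  Fleiss large-sample null standard error and a two-sided normal test.  The
  3-level agreement between lateralization type and MPS3 aligns
  Typical↔Strong R, Ambilateral↔Moderate, Strongly-atypical↔Strong L,
  unweighted — the alignment and weighting that reproduce the published
  value.
* **Fisher exact test**: closed-form hypergeometric for 2×2; complete
  enumeration of margin-consistent tables for larger ones (p = total null
  probability of tables no more probable than the observed, the
  Freeman–Halton rule), falling back to seeded Monte-Carlo sampling of the
  conditional null (≥ 1e5 permutations, standard error reported) when
  enumeration would exceed the table budget.  The enumeration agrees with
  R's `fisher.test` to all printed digits on the study's tables.
* **Spearman correlation**: midrank ties, t-approximation p (scipy).
* **Occurrence regression**: per MPS7 category, the percentage of atypical
  subjects (Ambilateral + Strongly-atypical) regressed by OLS on the fixed
  category mid-values (−100, −87, −50, 0, 50, 87, 100); empty categories
  are skipped.  The per-category counts behind the published slope were
  never published, so this regression is validated structurally (exact
  recovery on noiseless linear occurrence; negative slope in the majority
  of synthetic cohorts) rather than numerically.

## Synthetic cohorts

The generator draws each subject's HFLI from the published
handedness-specific mixture (3 components for right-handers, 4 for
left-handers; printed weights renormalized to sum to one), records the
generating component, and draws the manual-preference score from the
published (handedness, type) cell moments, clipped to [−100, 100].
Clipping — not truncation — is deliberate: the Edinburgh score has a point
mass at exactly +100, which clipping reproduces and which the MPS3
Strong-R category depends on.  It also pulls the realized cell mean below
the nominal one (a normal(93, 11) clipped at +100 has mean ≈ 91.3); tests
check against the closed-form clipped mean, not the nominal value.
Cutoffs mapping components to types use the operational boundaries
(component mean > 18 → Typical, < −50 → Strongly-atypical).

Within a cell, preference score and HFLI are drawn independently — the
published summaries constrain only cell moments, so independence is an
assumption of this generator, not an observed fact.  The generator emulates
the marginal and cell-wise structure of real cohorts but none of the
following: measurement noise in HFLI, discreteness of real inventory
scores, age/sex/education structure, or within-cell score–index
correlation.  Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

Synthetic t-maps are normal noise around per-hemisphere effect means on a
3-D grid split at the midplane (odd-sized axes leave the midplane slab
unassigned), with a posterior slab standing in for excluded non-cortical
tissue.  They exercise masking, thresholding and resampling, not realistic
spatial correlation.

## Problem sizes used in the shipped checks

Simulation-based checks use 100 replicate cohorts of 153 subjects for
model-selection recovery (200 for the tail-weight summary), 1e5 draws for
law-of-large-numbers checks, and bootstrap refits at reduced data size
(1000 subjects, 100 resamples, 3 restarts) for CI behavior.  These sizes
were chosen so each property is resolved with comfortable Monte-Carlo
margin on a single core.

## Known limitations

* The bootstrap index assumes exchangeable voxels within a hemisphere;
  spatial autocorrelation in real fMRI shrinks the effective voxel count
  and the trimmed-mean's stability accordingly.
* AICc selection at N ≈ 150 has genuine ~40% probability of overshooting
  the component count by one on replicate data; conclusions should rest on
  the modal choice across cohorts (or on the pooled sample), as done here.
* The r×c Fisher enumeration is exponential in table size; large sparse
  tables silently fall back to Monte-Carlo (the result object says which
  path was taken).
* Kappa p-values use the large-sample null SE; for tables with very small
  margins an exact or bootstrap test would be preferable.
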