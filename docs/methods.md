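# Methods

## The problem

Phasic pupil responses — the fast, event-locked changes in pupil size that
follow a stimulus — superimpose several autonomic processes: the
parasympathetically driven light-reflex constriction, its later inhibition,
and sympathetically driven dilation. Classical analyses either collapse a
trial to a scalar (mean, peak) inside a hand-picked window, or run one test
per timepoint and face hundreds of correlated comparisons. `pupilpca`
implements a third route: treat every post-onset timepoint of a trial as a
variable and every trial as an observation, reduce the trials × timepoints
matrix by temporal PCA (optionally with a factor-analytic promax rotation),
and carry the per-trial component scores — coordinates on a low-dimensional
"pupillary manifold" — into ordinary mixed-model inference.

## Preprocessing

The pipeline assumes artifacts arrive pre-marked as missing samples; blink
detection from raw eye-tracker streams is out of scope. Defaults:

| step | default | notes |
|---|---|---|
| gap interpolation | `max_gap` = 500 ms | linear, interior gaps only; edge gaps stay missing |
| z-scoring | per subject, whole session | sample sd (n − 1); makes amplitudes comparable across subjects |
| baseline | mean over [−250, +250) ms | the 500-ms window centred on target onset; median optional |
| epoch | [0, 4500) ms, half-open | 450 samples at 100 Hz |

Order is configurable and defaults to interpolate → z-score → baseline.
Longer gaps are deliberately left missing so the matrix stage drops the
whole trial: a trial with any missing cell is omitted entirely (and
counted), which keeps the decomposition exact rather than imputed.

Time is in milliseconds with 0 = target onset; epochs are half-open so
sample counts are unambiguous. Missing data are encoded as absent values,
never sentinels.

## Temporal PCA

`TemporalPCA` centres columns (no rescaling — the data are already
z-scored upstream, and column variance carries the amplitude information
the scores summarise) and eigen-decomposes the sample covariance via SVD.
Conventions that matter for reproducibility:

- variance proportions always use the **total** variance as denominator,
  so "the first three components reconstruct X%" is well defined under
  truncation;
- `ncomp < 1` selects the smallest k whose cumulative share is at least
  `ncomp`; an integer is taken literally (clamped to the rank with a
  warning);
- eigenvector signs are arbitrary, so each loading column is flipped to
  make its largest-magnitude element positive (scores flip jointly; the
  reconstruction is invariant).

A trial's score on a component is the centred trace projected on the
loading curve — a weighted average of the samples, weighted by the
component's temporal shape. `back_project` inverts this: `center +
score · loading`.

## Rotated (factor-analytic) PCA

`RotatedPCA` follows the factor-analytic convention instead: columns are
standardised (correlation-matrix PCA), the leading k eigenvectors are
scaled by the square roots of their eigenvalues — turning them into
timepoint–component correlations — and then rotated. The two roads
deliberately differ (covariance vs correlation); the plain and rotated
models therefore produce slightly different solutions, and the package
keeps both surfaces separate.

- **varimax** (orthogonal): SVD-iteration maximisation of the Kaiser
  criterion, row-normalised by default; stops at relative criterion gain
  < 1e-10 or 1,000 iterations.
- **promax** (oblique, default, power κ = 4): varimax first, then an
  oblique least-squares transformation toward the sign-preserving
  |loading|^κ target, with the inter-component correlation matrix Phi
  derived from the normalised transform. κ = 4 is the method's
  conventional value. A singular intermediate system falls back to
  varimax with a warning.
- components are re-ordered by descending rotated variance share
  (`diag(Phi · PᵀP) / p`) and sign-fixed by the same max-|element| rule.

Scores for oblique solutions use the regression method — weights
`R⁻¹ · structure` applied to the standardised columns, where R is the
timepoint correlation matrix inverted through its eigen-decomposition with
eigenvalues floored at 1e-8 when near-singular (logged). Bartlett scores
are available as an option. The score-estimation method for oblique
solutions is a genuine design choice; regression scoring was chosen as the
most common default in the factor-analytic tradition.

Tucker congruence (`congruence`, `match_components`) quantifies the cosine
similarity of loading curves; matching is greedy on |φ| with the signed
value reported. Values ≥ ~0.95 are conventionally read as equivalence,
≥ 0.90 as high similarity.

## Time-course inference

- `TimecourseLMM`: per timepoint, `pupil ~ condition` with a by-subject
  random intercept (statsmodels MixedLM). The fixed effect is tested by a
  likelihood-ratio test between full-ML refits of the full and null
  models; this keeps the contract free of denominator-degrees-of-freedom
  approximations, which differ across ecosystems. Default multiplicity
  control is BH-FDR across timepoints. Non-convergent timepoints are
  recorded as missing and the run continues.
- `ClusterPermutation`: the per-timepoint statistic is two-stage — the
  within-subject OLS slope of pupil on the numeric condition, then a
  one-sample t of the slopes across subjects. This statistic was chosen
  over refitting a mixed model inside every permutation because it is
  exactly exchangeable under within-subject label permutation, is the
  standard choice for cluster tests in neuroimaging time-series, and makes
  1,000 permutations a sub-second operation. Clusters form at two-sided
  p < `cluster_alpha`; cluster mass is Σ|t|; the null is the maximal
  cluster mass over permutations that shuffle condition labels across
  trials within each subject; cluster p uses the add-one formula
  (1 + #{null ≥ obs}) / (1 + n_perm).
- `BayesFactorTimecourse`: subject enters as an additive nuisance (pupil
  and condition residualised on subject means); the slope t statistic is
  converted to a JZS Bayes factor under a zero-centred Cauchy prior with
  scale r = √2/2 on the standardized slope, evaluated by adaptive 1-D
  quadrature over the prior's normal-mixture parameter (log-substitution
  around the integrand's mode). Evidence flags default to BF₁₀ > 3. For a
  balanced two-group design this reproduces the canonical two-sample JZS
  Bayes factor with scale r·sd(x).
- `ScoreModel`: the recommended path — a mixed model per component score,
  REML, random intercept by subject (random slopes opt-in; a failed slope
  fit falls back to intercept-only, logged). Numeric condition values are
  treated as an ordered covariate, categorical otherwise.

All stochastic operations are bit-reproducible given their seed.

## The simulator

`simulate_dataset` is the statistical twin of a 20-subject, 8-level
luminance experiment: 64 trials per subject, 4,500-ms epochs at 100 Hz
(450 samples). Traces are weighted sums of three gamma-family
pupil-response kernels `(t/t_max)^n · exp(n(1 − t/t_max))` (shape
n = 10.1) peaking at 900, 1,800 and 3,200 ms, with polarities (−, +, +) so
the earliest component is the light-reflex constriction; kernel overlap
makes the basis mildly correlated in time, which is precisely the regime
where an oblique rotation is advantaged over plain PCA. Peak latencies are
package defaults chosen to respect the physiological ordering
(parasympathetic activation < parasympathetic inhibition < sympathetic
activation) — the reference loading curves themselves are not tabulated
anywhere, so no test treats them as ground truth.

Per trial, component strengths are
`s_k = β0_k + β1_k·(level − mean level) + b_subject,k + e_trial,k`, and the
trace adds AR(1) noise (φ = 0.92, innovation sd 0.04) on the sample grid;
artifact gaps (contiguous, 50–400 ms, probability 0.05 per trial) are
inserted as missing runs. The default amplitude parameters
(β0 = (1.1, 0.55, 0.4), β1 = (0.25, −0.05, 0.06) per level step,
subject sd (0.45, 0.18, 0.10), trial sd (0.70, 0.20, 0.12)) were calibrated
once so the generated data reproduce the qualitative structure of a real
luminance experiment — a dominant PLR component near 79% of the variance,
three components jointly near 94%, and a luminance effect detectable from a
few hundred ms after onset — and are fixed thereafter.

Random streams are partitioned by (subject, trial) via spawned seed
sequences, so enlarging the design never reshuffles earlier trials.

What the simulator does **not** emulate: tonic/baseline drifts beyond
AR(1), gaze-contingent artifacts, blink dynamics, non-Gaussian score
distributions, and any temporal jitter of the component latencies across
trials. Passing recovery tests therefore show that the estimator chain is
correct under the stated generative model, not that three components
suffice for any real dataset.

## Problem sizes in the test suite

Calibration checks run at desk scale: type-I error of the per-timepoint
LMEM over 500 single-timepoint null replicates (12 subjects × 16 trials);
cluster-permutation family-wise error over 200 null replicates of 30
timepoints at 1,000 permutations; score-model coverage over 300
replicates; component recovery over 50 generator seeds at the full default
design. These sizes give Monte-Carlo standard errors comfortably inside
the asserted bands while keeping the whole suite within minutes.

## Numerical choices and degenerate inputs

- Grid regularity tolerance 1e-6 ms; loading orthogonality/unit-norm
  tolerances 1e-8; varimax criterion tolerance 1e-10.
- Zero-variance columns (e.g. the onset sample of noise-free data) are
  rejected with a pointer to post-onset epoching; zero-spread z-score
  groups raise naming the group; fewer than 2 complete trials raise.
- Negative eigenvalues from roundoff are clamped at 0.
- Ties in greedy congruence matching break by column order.
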