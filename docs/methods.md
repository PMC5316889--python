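# Methods

## The problem

Trial-by-trial pain reports vary substantially even when the noxious
stimulus is held constant. Part of that variation is cerebral rather than
nociceptive: endogenous fluctuations and psychological state (expectations,
perceived control) shape the experienced intensity. `painsig` implements a
pipeline that isolates this component as a multivariate voxel-weight map —
a *stimulus-intensity-independent pain signature* — on trial-level brain
activation maps, and provides the inferential machinery (multilevel GLM,
multilevel mediation) to test what that signature explains and mediates.

## Signature development

Given per-subject trial activation matrices `X` (trials x in-mask voxels)
and pain ratings `y`, restricted to painful, QC-passing trials:

1. **Residualization.** Within each subject, `y` and every voxel column of
   `X` are regressed on `[intercept | one indicator per stimulus intensity
   level (lowest dropped) | reference-signature response]`, where the
   reference response is the dot product of each trial map with a supplied
   nociceptive weight map. The indicator set removes per-level means
   (linear *and* nonlinear intensity effects); the reference regressor
   removes residual within-level nociceptive variation. Residuals are
   orthogonal to every design column to 1e-8 by construction.
2. **Per-subject decoding.** Principal component regression (PCR) of
   residual ratings on residual activity. Default `n_components="all"`
   keeps every nonzero component, which equals unregularized least squares
   (the minimum-norm solution when voxels outnumber trials); a fixed
   component count is available. Each subject's precision is the Pearson
   correlation between 10-fold out-of-fold predictions and outcomes
   (`cv_r`); folds are a seeded random partition, with a run-contiguous
   option because trial autocorrelation can inflate `cv_r`.
3. **Group aggregation.** Each subject map is divided by the s.d. of its
   own weights (scale harmonization across subjects/studies), then averaged
   with weights `max(cv_r, 0)`; negative precisions contribute nothing.
   Voxel-wise weighted one-sample t-tests (reliability-weights form:
   weights normalized to sum to n, weighted variance with n-1 df — the
   estimator reduces exactly to the classical t-test at equal weights)
   give p-values, thresholded by Benjamini–Hochberg FDR at q = 0.05.
4. **Region extraction.** Connected components of surviving voxels,
   labelled separately for positive (pro-pain) and negative (anti-pain)
   weights with a 26-neighbourhood (6/18 configurable), dropped below 15
   voxels unless allowlisted with a lower bound.

A univariate encoding–decoding baseline is included: per-voxel OLS slopes
of residual activity on residual rating, averaged across subjects, inverted
for prediction by averaging `beta_v * x_v` over voxels.

## Applying a signature

The signature response of an image is the dot product over in-mask voxels.
Local pattern expression restricts the product to one region, by default
with absolute weights so that a positive correlation with stimulus
intensity always means "regional activation increases with intensity".
Grids are never implicitly resampled; a mismatch is an error. Evaluation
constructs: leave-one-subject-out (LOSO) development/application (each
subject scored by a map aggregated from the others only — per-subject
decoders are independent, so models are fit once and the per-fold work is
aggregation; the leakage contract is exact), quartile-binned
prediction–outcome correlation (z-score both series, bin by outcome with
stable-sort tie-breaking, correlate the four bin means), and forced-choice
accuracy (top vs bottom 30% of trials by rating, exhaustive cross-pairs,
optional averaging of `n_avg` trials per set before comparison).

## Multilevel inference

First level: OLS within subject. Second level: Empirical Bayes weights
`1/(v_i + tau^2)` with `v_i` the first-level coefficient variance and
`tau^2` the DerSimonian–Laird method-of-moments between-subject variance,
floored at zero. Group p-values come from bootstrap resampling of subjects
with replacement (default 10,000; `p = 2 min(P(b* <= 0), P(b* >= 0))`,
floored at `1/(n_boot+1)`; one-tailed also reported). Unique variance of a
predictor is the mean over subjects of the R² drop when it is removed;
its null distribution shuffles that predictor's trial labels within each
subject (default 5,000 permutations; the reduced model is shuffle-invariant,
which the implementation exploits).

Mediation fits, per subject and on listwise-complete trials (so the
single-mediator identity `c = c' + a b` holds exactly): `M_j ~ X + covs`
(a), `Y ~ M + X + covs` (b, c'), `Y ~ X + covs` (c); three-path adds
`M1 ~ X` (a), `M2_j ~ M1 + X` (d), `Y ~ M2 + M1 + X` (b), indirect
`a d b`. Condition labels map to +1/-1 codes (anti-pain conditions +1 by
convention); stimulus intensity enters as a covariate where the design
crosses manipulations with intensity. The group indirect effect is the
second-level summary of per-subject products `a_i b_i` — not the product
of group means — so a–b covariance across subjects is counted. Products
carry the Goodman delta-method variance
(`a² v_b + b² v_a + v_a v_b`, extended analogously for triple products) as
their first-level variance, so the same EB machinery applies to every
path; in null simulations (29 subjects x 64 trials, 4,000 runs) this choice
measured a type-I rate of 0.061 at nominal 0.05 versus 0.077 for an
unweighted mean of products.

## Single-trial estimation and QC

Beta-series GLM: one boxcar regressor per trial convolved with the
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, ratio 1/6, 32 s support, unit peak — the field's default, all
configurable), plus intercept, linear drift, caller-supplied nuisance
columns and spike indicators. Per-trial variance inflation factors
(`1/(1-R²)` against all other columns) flag trials above 2.5 as excluded —
flags persist, rows are never dropped, so counts stay auditable.
Rank-deficient designs yield infinite VIFs rather than exceptions. Spike
detection computes slice-wise means and s.d.s per volume, Mahalanobis
distance in that feature space against a chi-square law with df = feature
count (our reading; the df is not standardized), and flags volumes passing
the *stricter* of Bonferroni and Benjamini–Hochberg at alpha = 0.05 —
implemented literally as the intersection of the two rejection sets. A
singular feature covariance is ridge-inflated with a warning. The flexible
alternative fits three time-shifted canonical kernels (shifts 0/+2/+4 s,
configurable) per trial and returns the trapezoidal area under the
reconstructed response per trial and voxel.

## The synthetic world

The generator stands in for multi-study thermal-pain data sets that are not
publicly deposited. Each subject's trials follow a linear generative model
with two planted spatial systems on a 12x12x12 ellipsoid-masked grid
(~550 voxels; a desk-scale stand-in for a 2 mm whole-brain grid):

* a **nociceptive pattern** (random weights, ~50% support, unit norm)
  whose expression scales with the calibrated stimulus level;
* an **endogenous pattern** — six 3³ subregions, alternating pro-pain
  (positive) and anti-pain (negative) signs, unit norm — whose trial
  amplitude `endo_amp` carries condition effects, a subject offset
  (s.d. 0.5) and trial noise (s.d. 1.0), and drives ratings through the
  mediator→pain path.

Ratings are `level + b·endo_amp + direct·condition + noise`, affinely
placed on the study's scale and clipped at its bounds; a configurable
fraction of trials (10% in the generic design) is non-painful, carrying no
planted signal and near-zero ratings, and is flagged rather than dropped.
Trial images add i.i.d. voxel noise (s.d. 0.5) **and** spatially
structured noise: five fixed unit-norm random modes with N(0, 2²) trial
amplitudes, emulating global/physiological fluctuations. The structured
component matters: it is rating-independent, so the multivariate decoder
learns to project it out while voxel-wise univariate decoding cannot —
with i.i.d. noise only, the univariate baseline matches the PCR decoder on
held-out variance and the documented multivariate advantage disappears.

Noise scales are stated nowhere in the source material; they were fixed
once, by pilot simulation, so that (a) per-voxel single-trial SNR is well
below 1, (b) per-subject cross-validated decoding r is ~0.7–0.8, and
(c) the default 20-subject / ~50-painful-trial world sits in the recovery
regime the acceptance properties assert (group-map cosine to the planted
pattern ~0.85). The `study6` preset (8 runs x 8 trials, balanced 2x2
perceived-control x expectancy crossing, 16 trials per cell, 50/50
high/low heat in every cell, perceived-control self-reports; the control
factor routes through the self-report, giving a recoverable three-path
chain) uses weaker paths — manipulation→mediator 0.29, mediator→pain 0.5 —
calibrated so the standardized indirect effect is ~0.06, the magnitude
reported for cue and control mediations in this literature. The `study5`
preset delivers the LL/LM/HM/HH cue structure with medium-intensity trials
flagged for mediation.

What a green test does **not** establish: the generator has no spatial
autocorrelation within patterns, no HRF variability across regions, no
scanner drift or motion structure, one homogeneous cohort rather than six
heterogeneous studies, and planted effects that are linear by construction.
Recovery results certify the estimators, not the empirical claims of any
particular study.

## Numerical choices and degenerate inputs

* Residual orthogonality and the PCR-with-all-components = OLS identity are
  enforced at 1e-8; rank decisions use an SVD tolerance of
  `s_max * max(n, p) * eps`.
* Zero-variance reference responses are dropped with a warning; an
  intensity level with one trial yields exactly-zero residuals and a
  warning; constant cross-validated predictions define `cv_r = 0` with a
  warning; all-nonpositive precisions abort aggregation.
* Weighted t-tests at zero variance report infinite t with the sign of the
  mean and p = 0 (underflow convention).
* Quartile ties break by a stable sort on trial index; forced-choice ties
  count one half; forced-choice pairing is exhaustive over high/low set
  pairs, deterministic given the grouping seed.
* Bootstrap and permutation p-values are floored at `1/(n+1)` and never
  exceed 1; all resampling is seeded and reproducible.
* z-scoring uses the sample (n-1) s.d. and errors on zero variance, naming
  the subject.

## Known limitations

The Empirical Bayes scheme is a documented stand-in (inverse
within-plus-between variance with method-of-moments tau²) for a procedure
whose exact update the source toolbox does not print; it is validated by
its own calibration suite rather than by equivalence to that toolbox.
Whether the original PCR kept all components, and whether ratings were
rescaled across studies before aggregation, is unknown; both are exposed
as configuration and the defaults are documented above. Perceived-control
ratings are supported per trial, with block-constant values a valid input.
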