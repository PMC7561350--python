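# Methods

This note documents the models implemented in `preycap`, the conventions
and tunable parameters, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

- Frames are 0-based; epochs are half-open `[start, end)`. Default epochs
  follow the recording protocol: 1500 spontaneous frames (~7 min at
  3.6 Hz) before the prey is introduced, then 2500 evoked frames (~11 min).
- Prey angle is in radians in (−π, π], 0 straight ahead, positive to the
  fish's left; prey radius is in millimetres.
- The *radial basis coordinate* is kept in basis-space units at
  40 units/mm, so the 0–5 mm span maps to 0–200 units. This is because
  the radial Gaussian width σ = 40 is specified in those units; both the
  scale and σ are configurable (`BasisConfig`).
- Eye angles are degrees, nasal rotation positive for each eye, so
  vergence = left + right. Eye-blob orientation is measured against the
  image row axis (the fish midline by convention), in (−90°, 90°].
- `Fz` denotes z-scored fluorescence: standard deviations away from the
  trace's own mean, population-SD convention (divide by n). Any
  consistent SD convention satisfies the invariants; this one is fixed
  and documented.

## Preprocessing

Order of operations: bleach correction → z-scoring → motion interpolation.
The narrative order of the acquisition pipeline fixes this; z-scoring
before interpolation means interpolated frames can leave the final mean/SD
infinitesimally off 0/1, which is intended (the invariant holds before
interpolation).

**Bleach model.** A single and a double exponential (plus offset) are
fitted by nonlinear least squares to each ROI's mean trace and arbitrated
by the small-sample-corrected Akaike information criterion (AICc), which
adds a parsimony penalty the bare residual comparison lacks — the double
model nests the single one, so raw goodness-of-fit would always prefer it.
Outliers (motion and activity artifacts) are excluded before the final
fits by flagging samples more than 3 scaled median absolute deviations
from the residuals of a preliminary single-exponential fit. A moving-median
criterion was rejected: on a monotone decay it flags the steep early
frames themselves — the most informative part of the curve — as outliers.
If neither exponential converges, a zero-amplitude constant model is
returned with a warning. Only the decaying component is subtracted from
pixels inside the ROI, so a zero-amplitude model is exactly the identity.

**Motion cleaning.** Frames whose upstream rigid-registration displacement
exceeds 2 pixels are replaced by linear interpolation between the nearest
valid frames (nearest-value extension at the edges). Registration itself
is out of scope; the displacement trace is an input.

## Behavioral and neural event detection

The recordings these detectors target were curated semi-automatically; an
explicit refractory gap (default 5 frames, ~1.4 s) replaces manual
curation. Consequences of that trade-off:

- **Convergences**: upward crossings of the 30° vergence threshold are
  accepted only when both eyes' mean nasal velocity over the preceding 3
  frames is positive ("both eyes moving sharply toward the midline" has no
  published numeric criterion; the positivity window is this package's
  choice and is configurable).
- **Tail flicks**: side intensity traces are baseline-corrected by a
  centred 20-frame rolling mean and thresholded at mean + 2 SD of the
  corrected trace.
- **Pretectal transients**: each (z-scored) trace is thresholded at 2 SD
  above its own mean; excursions of the element-wise left/right maximum
  are events, the excursion maximum is the peak, and the side with the
  larger value at peak is labelled the (putative) contralateral pretectum.
  Exact bilateral ties break to the left and are flagged. Note that a 2-SD
  threshold on any noise-only trace yields ~2% false crossings per frame by
  construction; on real data those were removed by hand, and in synthetic
  fixtures the noise floor is kept smooth (see below) so planted events
  dominate.
- **Transient classification**: a transient is `with_behavior` iff a
  convergence peak falls within ±5 frames of the transient peak. The
  association window is not published; ±5 frames was chosen to match the
  ±5-frame integration window used for the forebrain activity contrasts,
  and is recorded in output metadata.
- **Event-triggered summaries**: windows are inclusive frame offsets —
  baseline [−10, −5], response [0, +5] (6 frames each), activity map
  [−5, +10] (16 frames, ≈4.4 s), per-event integral [−5, +5]. Events whose
  windows leave the recording are dropped with a warning, never padded.
  The baseline-vs-response comparison reuses the permutation test on the
  per-event window means.

## Encoding model

The stimulus representation and fitting procedure are described in the
README. Numerical and design choices:

- **Delay count.** The nominal delay window −5…+15 frames contains 21
  values, but the feature count of the reference design (95 × 20 = 1900)
  implies 20; the default is delays −5…+14, keeping the printed feature
  count, with the range fully configurable. The run manifest records this.
- **Basis amplitude.** Each spatial basis is normalized to peak 1 at its
  centre (a pure von Mises × Gaussian shape) rather than to unit integral.
  Density normalization with σ = 40 units yields peak feature values of
  ~0.02, for which the default regularization grid (20 values log-spaced
  on [1, 1000]) is uniformly too strong against z-scored pixel traces —
  every α then shrinks the fit into an equivalent matched filter and the
  ridge path never explores the bias–variance trade-off. Unit-peak bases
  make the grid meaningful; preferred angles and significance are
  unaffected by the choice of scale. The tuned-pixel simulator uses the
  same shapes, so the recovery model is well specified.
- **Centering.** The design matrix is column-mean-centred once, globally;
  pixel traces are mean-centred per outer-fold estimation set. No
  intercept is fitted.
- **Held-out predictions** are kept in the per-fold centred space when
  concatenated. Re-adding each fold's estimation-set mean would imprint
  fold-level offsets that anticorrelate with the held-out segment's own
  mean, giving null pixels a systematic spurious correlation — measured
  on the recovery fixture, that inflates the untuned false-discovery
  fraction from ~5% to ~30%.
- **Inner loop.** Per fold and repetition, 10 blocks of 40 consecutive
  time points are removed from the estimation set (sampled disjoint where
  possible, seeded), the ridge path is solved for all pixels at once via
  one eigendecomposition of the feature Gram matrix, and α is selected
  per pixel by mean held-out correlation across repetitions (ties go to
  the smallest α).
- **Outer segments.** T is split into 10 sequential segments of ⌊T/10⌋
  frames; remainder frames join the final segment.
- **Significance.** Two-sided p under the exact null of the correlation of
  two independent Gaussian series (t-transform, T − 2 df), BH-FDR at
  q = 0.05 within fish. Preferred angles are reported only for significant
  pixels; an all-zero weight grid yields an undefined-preference flag, and
  exact angular ties break to the lower bin index with a flag.
- **Retinotopic gradients** project significant pixels onto the ROI
  mask's principal axis (second spatial moments) and take circular means
  of preferred angle per normalized-position bin; a near-isotropic mask
  has no defined axis, so the row axis is used and flagged.

## Granger causality

- Both nested models are fitted by OLS on frames q…T−1, so the residual
  comparison is on identical samples and var[e₂] ≤ var[e₁] holds exactly;
  GC = ln(var[e₁]/var[e₂]) is clipped at 0 against floating-point error.
- The orientation of the variance ratio is fixed by the requirement that
  GC be non-negative by construction.
- F = ((RSS₁ − RSS₂)/q) / (RSS₂/(T_eff − 2q − 1)) with null distribution
  F(q, T_eff − 2q − 1), T_eff the usable samples after lag trimming. A
  fixed critical value (as used for display thresholds in the source
  figures, e.g. 3.88) is not derivable from these degrees of freedom and
  is therefore exposed as configuration rather than hard-coded; the
  default significance comes from the F quantile under the df above.
- Order selection minimizes C_q = T ln det Σ₂ + T(TN + qN²)/(T − qN − N − 1)
  (N = 2, Σ₂ the bivariate residual covariance), averaged over region
  pairs within a fish; the cohort-wide order is the rounded mean of
  per-fish optima (q = 5 is the convention for the hunting dataset). Note
  this cost is asymptotically ordinary AIC (penalty ≈ 2qN²), which
  overfits by one order with non-negligible probability on a single pair;
  averaging across pairs is what stabilizes it.
- Only strictly pairwise (bivariate) GC is computed — no conditional,
  multivariate or spectral variants — and fluorescence is analyzed
  directly, without deconvolving the calcium kinetics. Two regions driven
  in parallel can therefore both appear as sources, and slow indicator
  dynamics blur fast causal timing; these are limitations of the method
  itself, not of the implementation.
- Traces are re-standardized over the analyzed epoch before fitting, so
  GC is invariant to affine rescaling of either trace.
- Group comparison: Welch's unequal-variance t per directed link across
  fish, BH-FDR at 0.05 across links. Links with zero variance in both
  groups get statistic 0 and p = 1 when means agree, or an
  undefined-statistic flag (excluded from FDR) when they differ.

## Bespoke statistics

- **Permutation test**: two-sided on the difference in group means. The
  Monte-Carlo p uses the add-one estimator (b + 1)/(m + 1), keeping p
  strictly positive and valid; at the reference resample count (10⁵) the
  difference from the raw proportion is ≤ 10⁻⁵. Totals of ≤ 10
  observations switch to exact enumeration of all label assignments
  (the raw proportion, since the null is then exhausted).
- **d′**: extreme rates are clamped to 1/(2N) and 1 − 1/(2N) when the
  trial count N is known, otherwise the z-score is capped at ±5. The
  clamping rule is unpublished; this is the standard correction.
- **Bootstrap percent change**: 10,000 resamples and a percentile
  interval by default (resample count and interval type are unpublished
  choices). If the reference-group mean changes sign in >1% of resamples
  the ratio is declared unstable and an error is raised rather than a
  meaningless interval returned.
- **Robust interaction regression**: iteratively reweighted least squares
  with Tukey bisquare weights, tuning constant 4.685 × MAD scale (the
  standard convention implied by a "robust fit" option), via statsmodels
  RLM. R² is computed on the final weighted fit. With a single diet level
  the diet and interaction columns are collinear and are dropped (reported
  NaN) — the reduced model is fitted instead of failing.
- Every stochastic operation takes an explicit seed, recorded in its
  result object and in run manifests. Pipeline stages derive sub-seeds by
  hashing the stage name with the master seed, so adding a stage never
  reshuffles the draws of another.

## What the synthetic generators emulate — and what they don't

- **Prey trajectory**: a reflecting Gaussian random walk on the arena
  disk (default radius 5 mm, per-frame step SD 0.25 mm). Real paramecia
  swim with runs, reversals and 3-D excursions; none of that is modelled,
  and the defaults are fixtures, not claims about paramecium kinematics.
  What matters downstream is angular coverage, which is reported
  (`angular_coverage`) and warned on when any basis bin goes unvisited.
- **Tuned pixels**: drive = unit-peak von Mises (κ = 20) × Gaussian
  (σ = 40 units) evaluated at the prey's position, convolved with a causal
  exponential calcium kernel (τ = 1.0 s, GCaMP6f-like, configurable),
  plus a shared exponential bleach trend and i.i.d. Gaussian noise. The
  generator deliberately mirrors the analysis basis, so recovery tests
  probe estimation, not model mismatch; real pixels have nonlinearities,
  correlated noise and motion residue the generator omits. Passing
  recovery therefore shows the estimator is correct and calibrated under
  its own assumptions — not that real recordings satisfy them.
- **Coupled regions**: a stable VAR(q) process (stability checked via the
  companion-matrix spectral radius; unstable specifications raise), with
  500 burn-in frames discarded. Calcium convolution is *not* applied here,
  matching the decision to run GC on fluorescence directly.
- **Behavior sessions**: Gaussian-bump pretectal transients (amplitude
  5 z, width 2 frames) on a random dominant side with a 0.3× contralateral
  echo, each independently followed (probability p) by a vergence
  excursion crossing 30° within ±5 frames plus a tail pulse. The pretectal
  noise floor is exponentially filtered white noise rescaled to unit SD:
  calcium-like smoothness keeps spurious 2-SD crossings rare, standing in
  for the manual curation applied to real traces.

## Problem sizes used by the checks

The automated checks run at desk scale, chosen to exercise each property
with adequate statistical power: permutation calibration uses 2,000 null
datasets × 10,000 permutations (the reference procedure uses 10⁵
permutations; the estimator differences are negligible at these counts);
encoding recovery uses 225 pixels × 2,500 frames with 5 delays, 10 inner
repetitions and 10 candidate α values; Granger direction recovery uses
100 seeds at T = 2500 and order selection 50 seeds of a 6-region VAR(3)
built from three disjoint unidirectionally coupled pairs — a ground truth
for which every bivariate pair model is well specified, which is what the
pair-averaged order criterion estimates.

## Known limitations

- Bivariate GC cannot distinguish direct from indirect or common-drive
  connectivity, and slow calcium dynamics limit temporal attribution.
- The encoding model is linear in the basis representation; strong
  response nonlinearities would bias receptive-field shape.
- Event detectors inherit the 2-SD threshold's false-crossing rate on
  noise-dominated traces; refractory gaps mitigate but do not remove this.
- The video-based projection of the original procedure is reduced to
  evaluating the basis at the tracked prey position — equivalent for a
  single bright object on a subtracted baseline, which is the recorded
  situation, but not for multi-object scenes.
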