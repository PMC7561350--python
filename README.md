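# preycap

Analysis pipeline for wide-field calcium imaging of larval zebrafish prey
capture: preprocessing of single-plane GCaMP6f fluorescence movies,
detection of hunting-related behavioral and neural events, pixel-wise
encoding models of prey position, and Granger-causality estimates of
directed functional connectivity between brain regions — together with a
synthetic-data generator that produces every input with known ground
truth, so the whole pipeline is testable without animal recordings.

It is aimed at systems neuroscientists analyzing slow (~3.6 Hz)
fluorescence time series around visually guided behaviors, and at anyone
who wants a reference implementation of the three core methods below.

## The methods

**Pixel-wise prey-position encoding model.** Prey position relative to the
fish is expressed in polar coordinates (angle α, radius r) and projected
onto 19 von Mises angular bumps (concentration κ = 20, centres evenly
spaced on the circle) × 5 Gaussian radial bumps (width σ = 40
radial-coordinate units over a 0–5 mm span), giving 95 spatial basis
functions. Each basis time series is delay-embedded (−5…+14 frames) into a
1900-feature stimulus matrix **X**; per pixel, weights **w** minimizing
‖y − X**w**‖² + α‖**w**‖² are estimated inside a 10-fold sequential outer
cross-validation, with α chosen per fold by an inner block bootstrap.
Concatenated held-out predictions give a cross-validated Pearson r per
pixel; significance is assessed against the null distribution of the
correlation of independent Gaussian series and Benjamini–Hochberg
corrected (q < 0.05). The angular centre maximizing the delay- and
radius-averaged weights is the pixel's *preferred angle*; the map of
preferred angles is the retinotopic map.

**Granger causality.** A region F1 Granger-causes F2 if F1's past improves
prediction of F2 beyond F2's own past. Both nested autoregressions
(univariate: F2(t) = Σₖ a(k) F2(t−k) + e₁(t); bivariate adds Σₖ b1(k)
F1(t−k)) are fitted by OLS on identical samples, so
GC(1→2) = ln(var[e₁]/var[e₂]) ≥ 0. Link strength is the nested-model
F-statistic with (q, T − 2q − 1) degrees of freedom; the order q is chosen
by a small-sample-corrected Akaike cost on the bivariate residual
covariance, and group differences per link use Welch's t-test, FDR
corrected.

**Bespoke statistics.** Two-sided difference-in-means permutation tests
(exact enumeration for tiny samples, Monte-Carlo otherwise), the signal
detection index d′ = Z(hit rate) − Z(false-alarm rate), bootstrap
percent-change intervals, and a robust (Tukey bisquare) interaction
regression ConvergenceFrequency ~ 1 + Diet + GC + Diet×GC linking
connectivity to hunting behavior.

## Worked example

```python
import numpy as np
from preycap import synthetic, encoding, granger, events, stats

# simulate a movie of pixels with polar receptive fields, then recover them
traj = synthetic.simulate_prey_trajectory(2500, seed=11)
pixels = synthetic.make_ground_truth_pixels(30, 19, seed=12, gain=3.0)
movie, pixels = synthetic.simulate_pixel_movie(traj, pixels, noise_sd=0.05, seed=13)
flat = movie.pixel_traces().astype(float)
Y = (flat - flat.mean(0)) / flat.std(0)

basis = encoding.build_spatial_basis()                       # 95 functions
series = encoding.project_trajectory(traj, basis)
design = encoding.build_design_matrix(series, delays=range(0, 5), basis=basis)
res = encoding.nested_cv_fit(design, Y, alphas=np.logspace(0, 3, 10),
                             n_inner_reps=10, seed=42, basis=basis)

# directed coupling between two simulated regions (0 -> 1, c = 0.5)
coeffs = np.zeros((2, 2, 1)); coeffs[1, 0, 0] = 0.5
tr, _ = synthetic.simulate_coupled_regions(
    synthetic.CouplingSpec(2, 1, coeffs), 2500, seed=3)
fwd = granger.granger_link(tr.traces[0], tr.traces[1], q=1)
rev = granger.granger_link(tr.traces[1], tr.traces[0], q=1)

# pretectal transients followed (or not) by eye convergence
sess = synthetic.simulate_behavior_session(200, 0.4, 5200, seed=1)
eyes = events.EyeTrace(sess.left_eye, sess.right_eye)
conv = events.detect_convergences(eyes)
trans = events.classify_transients(
    events.detect_pretectal_transients(sess.pretectal_left,
                                       sess.pretectal_right), conv)
```

This prints (via the obvious `print` statements):

```
significant pixels: 30/49 (tuned: 30/30)
median preferred-angle error: 4.2 deg
GC(0->1) = 0.242 (F = 681.9, p = 4.3e-133)
GC(1->0) = 0.0012 (F = 2.88, p = 0.09)
transition probability: 0.416 (planted 0.4)
```

All 30 tuned pixels are recovered as significant with preferred angles
well inside one angular bin (≈18.9°); the planted directed link produces a
huge forward F-statistic while the reverse direction stays at the null;
and the detected fraction of pretectal transients followed by an eye
convergence matches the planted probability of 0.4. For GC(0→1), the
analytic value for this construction is ln(1 + 0.5²) ≈ 0.223.

A full synthetic demonstration (movie + trajectory + region traces +
behavior, through both analyses) is one call or one command:

```bash
preycap run-all --out demo_run --seed 0
```

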