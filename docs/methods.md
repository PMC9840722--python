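# Methods

`pcctherm` implements an end-to-end photon-counting CT (PCCT) thermometry
pipeline: spectral linear attenuation coefficients (LACs) are extracted
from projections of a liquid phantom, decomposed into base-material volume
fractions, and mapped to temperature by a small neural regressor trained on
base-material thermal data. Everything runs on synthetic data produced by
the package's own generator, so the full chain is testable without any
measurement files.

## Projection model and geometry

A point source illuminates a square-cross-section phantom; a
photon-counting detector (256 x 1280 pixels, 55 um pitch) records counts
above programmable energy thresholds. Within a detector row the beam is a
fan; obliquity across rows is ignored because the analysis is strictly
one-dimensional (one line of interest, LOI, per projection), so every row
sees the same fan. Counts follow Beer-Lambert attenuation,
`I = I0 exp(-mu * c)`, with the chord `c` computed analytically by
ray-square slab intersection. A brute-force ray-marching integrator exists
only in the test suite, as an independent oracle for the analytic chords.

Geometry defaults keep the reference distances (source-center 278.5 mm,
source-detector 342.5 mm, magnification m = 342.5/278.5 = 1.23). The
nominal phantom side L = 254 mm cannot cast a shadow inside a
70.4 mm-wide detector at this magnification, so simulations use
`PhantomGeometry.self_consistent()` with L = 25.4 mm; all values remain
overridable. Note the magnification is stated as the detector/center
distance ratio; the inverse ordering sometimes seen in prose would give
0.81 and is inconsistent with the printed factor 1.23.

Threshold acquisitions are paired (8 with 45 keV, 33 with 60 keV, two
thresholds per readout) and subtracted into the four energy bins 8-33,
33-45, 45-60 and 60-100 keV. With counting noise a bin difference can be
negative; such pixels are clipped to zero and counted, since negative
photon counts are unphysical.

## LAC extraction (LOI chain)

Per energy bin and LOI (default: detector row 200):

1. *Unstable-pixel removal.* Columns deviating more than 3 SD from the
   row mean are masked. Statistics are computed on the raw profile over the
   currently valid columns, in a single pass; an iterated rule would bite
   into the Gaussian tail, and a single pass suffices for the small
   unstable fraction this models.
2. *Profile difference.* `dp(x) = ln(I_empty / I_filled)`; the phantom
   enclosure attenuates both acquisitions identically and cancels exactly.
   Columns with non-positive counts are masked, not propagated.
3. *Denoising.* A 5-pixel sliding average, then a 7-pixel median filter,
   in that order, over valid columns with truncated windows at the edges.
4. *Integration.* `mu = pitch / (L^2 * m) * integral dp(x) dx`
   (trapezoidal, pixel-index spacing, masked columns linearly
   interpolated). The interpretation is the area between empty and filled
   log-profiles, demagnified to the object plane, divided by the phantom
   cross-section area: the mean LAC in mm^-1. If the profile does not
   return to baseline at the row ends the shadow exceeds the detector and
   the result is flagged as biased low.

The demagnification is a weak-perspective correction: dividing the profile
area by `m` approximates the parallel-beam line-integral area. For the
self-consistent geometry the residual error is ~0.1% (the theoretical
bound for this setup is 3%); with parallel rays and `m` forced to 1 the
identity `integral chord dx = L^2` makes extraction exact to the
integration tolerance.

Averaging 10 adjacent LOIs (rows 200..209) gives the measurement mean and
an unbiased sample variance per bin; degenerate LOIs are excluded, and
with fewer than two usable LOIs the variance is reported unavailable
rather than zero.

## Material model

Volume-fraction mixing is linear per energy bin:
`mu(E_k) = sum_i V_i mu_i(E_k)` with `sum_i V_i = 1`. Decomposition solves
this as an equality-constrained least squares over all four bins (KKT
system; the sum constraint holds exactly, the four spectral equations are
fit). The basis is taken at the 33 degC baseline, matching the
baseline-scan design of the regressor input. Fractions outside [0, 1] are
flagged, never clipped, so the residual norm stays meaningful as a
dissimilarity diagnostic. A near-collinear basis raises an error carrying
the condition number.

CT numbers use water at the same bin and temperature:
`HU = 1000 (mu - mu_w)/mu_w`. The thermal CT model
`dCT = -(1000 + CT(T0)) alpha dT` (with `alpha` the volumetric expansion
coefficient) and the mixture thermal model
`alpha' = sum V_i alpha_i`, `beta' = sum V_i mu_i(T0)` are provided as the
non-learned reference. The mixture model is exact only when thermal
sensitivity is linear in composition; measured sensitivities are
quadratic/higher-order in solute concentration, which is the motivation
for the learned regressor. The expansion coefficient of the CT model and
the fitted LAC-per-degC sensitivity are kept as distinct quantities,
related through the HU conversion.

## Temperature regressor

Input (8 elements): the four per-bin LACs at the current temperature, then
the four heating residuals against the 33 degC baseline scan, multiplied
by exactly 100 to land in the numeric range of the baseline values.

Features are expressed in cm^-1, the conventional unit of CT attenuation
plots, while the geometry/extraction modules work in mm^-1 (the
integration constants are in mm). The choice is not cosmetic: with
water-like LACs the cm^-1 scale puts baseline features at ~0.2-0.5 and
scaled residuals at up to ~2, which is what makes the fixed x100 residual
scaling and the fixed SGD learning rate of 1e-5 converge in a few hundred
epochs. At mm^-1 scale all gradients are 10x smaller and the same
optimizer stalls. A single constant (`LAC_FEATURE_UNIT_SCALE = 10`)
applies the conversion wherever features are assembled.

Architecture 8-4-4-1, ReLU on the hidden layers. The output unit is
identity by default: temperatures are strictly positive, so a ReLU output
is either inactive (dead at initialization, with no gradient path to
recover — observed for a material fraction of random initializations) or
the identity. Both behaviours are selectable (`RegressorSpec.output_relu`).

Training: per-sample stochastic gradient descent on the mean squared
error, learning rate 1e-5, 80/20 train/validation split stratified by
material, all randomness seeded (bitwise-reproducible histories). Hidden
weights use fan-in-scaled (He) initialization; the output head starts
small (SD 0.1, biases 0.1) so the untrained network predicts near zero and
the epoch-0 history row — recorded before any update — shows the
uninformed error (about the mean target temperature, ~60 degC). Up to 600
epochs with early stopping on validation MAE (patience 40) and the
best-validation parameters restored; validation error plateaus near
3.5-4 degC.

Training data: 333 inputs per base material on a uniform temperature grid
over 33-90 degC, each perturbed with zero-mean Gaussian noise of SD 0.5%
of the per-bin baseline LAC (relative noise; the magnitude is
configurable). This input noise is a key regularizer: much smaller values
give lower validation error but clearly worse generalization to
compositions between the material clusters, larger values wash out the
water-like materials' small residual signal. At 0.5% the
temperature-equivalent noise floor is a few degC, consistent with the
accuracy regime the method targets.

Three further elements make the estimator robust to the ways test
materials differ from the training clusters; each was validated on
held-out generator seeds, none uses test-material information:

- *Baseline augmentation.* An unknown material is always referenced to
  its own baseline scan, which sits wherever its series starts (35-38
  degC in the held-out series), not at 33 degC exactly. Each training
  row's residual is therefore referenced to a baseline-scan temperature
  drawn uniformly from 33-40 degC, so deployment inputs lie on the
  training manifold. (With every training residual pinned to 33 degC,
  every test input is off-manifold and the network's response there is
  unconstrained — observed as seed-dependent systematic errors of
  5-10 degC.)
- *Per-presentation input jitter.* During SGD each presented sample
  receives fresh Gaussian jitter: a measurement-style component (0.5% of
  the baseline LAC, applied consistently to the LAC half and x100 to the
  residual half) and an independent material-spectrum component (2.5%,
  LAC half only) that emulates a material whose baseline spectrum
  deviates slightly from the basis family while its thermal response does
  not — the regime dissimilar materials occupy (the generator bounds that
  deviation at 5%). Validation always uses unjittered rows.
- *Restart selection by a mixture probe.* Networks this small fit the
  three training clusters equally well from almost any initialization but
  interpolate *between* them erratically for a material fraction of
  initializations, and validation data (drawn from the same clusters)
  cannot detect this. `fit_thermometry` trains three independently seeded
  candidates and keeps the one with the lowest anchored MAE on synthetic
  volumetric mixtures of the training bases — legitimate probes, since
  volume-fraction mixing is the method's own physical model.

Prediction anchoring: the baseline scan's temperature is measured (the
acquisition protocol reads a digital thermometer), so the network's
prediction for the zero-residual baseline feature is calibrated to it and
the same shift applies to every scan referenced to that baseline
(`anchored_offset`). This removes the network's residual misreading of
baseline spectra and is how `evaluate_on_series` and the CLI report
temperatures. The first tabulated temperature of a series is taken as its
baseline scan.

## Monte-Carlo confidence intervals

`predict_with_ci` perturbs the measured LAC per bin with independent
Gaussian noise whose variance is the 10-LOI measurement variance, rebuilds
the residual half of the feature consistently against the implied
baseline, and evaluates the network per draw (default 1000). The 2.5/97.5
percentiles form the 95% interval; the noiseless prediction is the point
estimate, and the interval is extended to contain it in the rare case the
percentile band excludes it. Zero variance degenerates to a point
interval. The baseline scan is itself a measurement; passing its variance
(`baseline_var_per_bin`) propagates it through the residual half as well,
which is the configuration whose empirical coverage is checked by the
acceptance suite (92-93% over the validated 35-60 degC operating range
with matched 0.5% noise).

## Synthetic generator

The generator emulates the *structure* of the measured data, not its
absolute values:

- water baseline LAC per bin [0.034, 0.026, 0.022, 0.019] mm^-1, with a
  concentration term 3.0/1.5/0.8/0.4 x 1e-5 mm^-1 per mmol/L CaCl2 and a
  mild bin-dependent saturation (10/6/3/1.5% at 600 mmol/L). The
  saturation makes the three base spectra affinely independent; exactly
  linear concentration dependence would make volume fractions
  unidentifiable (the constrained basis matrix loses rank).
- thermal sensitivity: water slopes [-1.4, +0.9, -1.1, -0.9] x 1e-5
  mm^-1/degC — positive in the 33-45 keV bin, negative elsewhere, the
  phenomenological sign signature of temperature-dependent Compton
  scatter; magnitudes correspond to a relative drop of ~4e-4 per degC,
  the order of water's volumetric expansion coefficient.
- concentration scaling of sensitivity: quadratic,
  `g(c) = 1 + 2.1667e-3 c + 1.6667e-6 c^2`, so 600 mmol/L is 2.9x water
  and 300 mmol/L (g = 1.80) deviates ~8% from the water/600 midpoint
  (1.95). Any quadratic with non-zero curvature makes the linear mixture
  model systematically wrong at 300 mmol/L; this curvature makes the miss
  clearly resolvable without making the interpolation task hopeless for a
  60-parameter network.
- base series tabulated every 5 degC over 33-93 degC; similar test series
  (equal-volume water/600 baseline, g(300) slope) over 35-60 degC;
  dissimilar surrogate (water baseline perturbed up to +-5% per bin,
  slopes perturbed +-10%, sign pattern kept) over 38-50 degC. The
  dissimilar material is a perturbed-LAC construct, not a compositional
  model of any real foodstuff.

What the generator does *not* emulate: polychromatic spectra and beam
hardening, detector charge sharing and fluorescence escape, pixel-gap
artifacts (beyond an optional dead-column mask), flat-field structure, and
any physically derived attenuation values. Passing tests therefore
demonstrate the correctness and statistical behaviour of the processing
and learning chain under the stated noise model — not detector physics.

## Numerical choices and degenerate inputs

- Noiseless simulations keep counts as float64 so analytic identities hold
  exactly; Poisson noise produces integers, and TIFF output rounds to
  uint16.
- The detector grid is symmetric about the beam axis, so shadow-edge
  truncation errors cancel pairwise in the trapezoidal integral.
- Constant profiles have zero SD: the 3-SD rule is then a no-op rather
  than a divide-by-zero.
- `n_loi = 1` yields a mean but no variance; accessing it raises.
- Decomposition refuses bases with condition number above 1e10.
- Training raises (with the epoch index) on non-finite loss rather than
  returning NaN weights.

## Problem sizes

Default examples and tests use the 256 x 1280 (or 12 x 1280 for full-chain
unit tests) detector, 999-row training sets and trainings of up to 600
epochs with three probe-ranked restarts; end-to-end checks train three
independent seeds. These sizes keep any single check within a few minutes
on one CPU while leaving every algorithmic path identical to larger runs.

## Known limitations

- Input-noise regularization shrinks the temperature response slightly
  toward the training mean; anchored predictions therefore develop a
  negative bias that grows with the temperature rise above the baseline
  scan (a few degC at +50 degC). Within the validated 35-60 degC
  evaluation ranges the effect is small.
- The mixture probe ranks restarts by interpolation between the training
  bases; a network can still respond imperfectly to compositions far
  outside the basis simplex.
- The weak-perspective correction assumes the phantom shadow is fully
  inside the detector row; partial shadows bias the LAC low (flagged, not
  corrected).
- Confidence intervals propagate measurement noise only; they do not
  include the network's systematic error, so empirical coverage can fall
  below nominal when measurement variance is very small.
- The generator's linear LAC-temperature trends are an idealization of
  "near-linear" measured behaviour; curvature in temperature is not
  modelled.
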