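# Methods

This note records the models, defaults and design choices behind `rpvolt`,
in enough detail to judge what a passing test suite does and does not
demonstrate.

## Waveforms and the feature layout

One scan digitizes only the *active* window of the applied waveform; the
electrode rests at the holding potential between repetitions and no samples
are taken there. The default digitization rate is 125 kHz. It is not a
measured quantity but the unique rate that makes the 8-ms four-step pulse
yield 1000 features with step boundaries at samples 250/500/750 — i.e. the
second pulse step occupies the half-open index range [250, 500), which in
1-based inclusive language is "points 251–500". All ranges in the package
are 0-based half-open; 1-based inclusive descriptions are converted at the
I/O boundary only.

The triangle waveform is specified as −0.4 → +1.2 → −0.4 V delivered at
10 Hz. A scan rate of 400 mV/s is sometimes quoted for such waveforms, but
a 3.2 V round trip at 400 mV/s lasts 8 s and cannot repeat at 10 Hz; the
only self-consistent value is 400 V/s (8 ms sweep), which is what the
default uses. The rate is configurable and this discrepancy is deliberately
documented rather than silently corrected elsewhere.

The combined waveform alternates pulse and triangle scans strictly, each
kind at 5 Hz (10 scans/s total), pulse first at t = 0.

## The voltammogram simulator

No public dataset accompanies this problem, so the simulator is a
first-class, tested component: it defines the study conditions under which
every downstream claim is evaluated. It is a deliberately minimal
parametric model of the qualitative current decomposition — not a
finite-element electrode simulation.

**Faradaic current.** Per analyte:
`i = gain · c · [σ((E−e_ox)/slope) − σ((e_red−E)/slope)] · shape(t)` with
`shape(t) = ((t+ε)/ε)^(−d) · (1 − exp(−t/τ_ads))`, t measured from the
enclosing step's onset. The sigmoid activation stands in for electron-
transfer kinetics, the power decay for Cottrell-like diffusion limitation
(ε is fixed at 8 μs, one default sample period, so the decay factor is 1 at
step onset), and the exponential onset for adsorption-limited supply. The
response is strictly linear in concentration by construction.

**Defaults** (modeling choices, with the reasoning):

| parameter | DA | 5-HT | why |
| --- | --- | --- | --- |
| e_ox (V) | +0.20 | +0.35 | overlapping but distinct oxidation waves |
| e_red (V) | −0.20 | 0.00 | reduction of the oxidized products at low-potential steps |
| slope (V) | 0.05 | 0.05 | ~kT-scale activation width |
| gain (nA·μM⁻¹) | 60 | 48 | sensitivity of coated carbon-fiber electrodes; strong faradaic SNR |
| τ_ads (ms) | 1.0 | 3.0 | serotonin adsorbs far more strongly → slower onset; also keeps faradaic current out of the first ~0.5 ms capacitive transient |
| decay exponent | 0.5 | 0.3 | diffusive vs adsorption-buffered decay |

The distinct within-step time profiles of the two analytes are what makes a
pulse waveform informative: without them the two signatures are nearly
collinear and the calibration becomes a poorly conditioned contrast whose
large cancelling coefficients amplify any baseline offset into μM-scale
prediction error.

**Capacitive current.** Every potential transition injects
`(ΔE/R)·exp(−t/RC_eff)`; transitions are superposed with a recursive
single-pole filter, so a triangle ramp produces the steady `C·dE/dt`
envelope automatically. Defaults R = 100 kΩ, C_dl = 1 nF give RC = 100 μs:
the transient occupies the first ~12% of a 2-ms step and decays to < 5% of
its peak by mid-step. The effective capacitance is weakly concentration
dependent, `C_eff = C_dl + Σ_k κ_k c_k`, with per-analyte weights
κ = (0.25, 1.0) fF/μM — serotonin, the strongly adsorbing analyte, perturbs
the double layer four times more than dopamine. This is the mechanism by
which *non-faradaic* regions of the scan carry analyte-specific
information; a scalar coupling to total concentration is also accepted but
can only inform the concentration *sum*, never the DA/5-HT contrast. The
coupling magnitude (~2 nA/μM near t = RC, a few times the noise floor but
an order below the faradaic signals) is chosen so the information is real
yet magnitude-wise easy to overlook — see the VIP discussion below.

**Drift and noise.** Baseline drift = deterministic ramp
(2×10⁻⁴ nA/s) + seeded random walk (0.03 nA per √scan), added as a
per-scan offset; white Gaussian noise (1 nA SD) per sample. A calibration
session spaces standards 60 s apart (drift accumulates accordingly) and
injects them in seeded pseudo-random order. These magnitudes describe a
stable, coated electrode in buffer; scan-synchronous ramps much above
~1 nA per session chance-correlate with the 18-standard design and visibly
bias the calibration — with real, less stable electrodes one should expect
the recovery figures below to degrade accordingly.

**Release transients.** Stimulation-evoked concentration excursions are
peak-normalized differences of exponentials (rise 2 s, clearance 15 s),
superposed on the basal level; the ground-truth trace is returned with
every session and never inferred.

**What the simulator does not emulate:** electrode fouling and sensitivity
drift, pH and ionic interferents, nonlinear adsorption saturation,
multiplicative (flicker) noise, inter-electrode variability. Passing
recovery tests therefore show the *pipeline* is correct and well
conditioned under the stated conditions, not that any particular in vivo
recording meets them.

## Preprocessing

Transform order is fixed: background-subtract → per-scan normalization →
mean-center → column scaling (standardize, or per-feature norms behind a
flag). Per-scan unit-norm scaling (ℓ1/ℓ2/max) runs *before* centering
because it corrects acquisition magnitude scan by scan; normalizing
after centering would divide each scan by the norm of its analyte-dependent
residual, a nonlinear distortion of exactly the signal being calibrated.
Standardization z-scores features with training statistics; zero-variance
features are centered but not divided (with a warning) so synthetic blanks
cannot produce NaNs. Y (concentrations) is centered only, never scaled.
Whether normalization should act per scan or per feature is ambiguous in
common usage; per scan is the default, per feature available via
`per_feature_normalize`.

## Chemometrics

NIPALS PLS2 fits both analytes jointly, deflating X only (Y-deflation
provably does not change the fit when X is deflated, and omitting it keeps
Q²Y bookkeeping simple). Weights are sign-fixed so the largest-magnitude
entry of each w_a is positive — signs are otherwise arbitrary and this
makes results platform-stable. The inner loop is a power iteration on the
cross-covariance; its convergence rate is the squared ratio of that
matrix's top singular values, so the tolerance is tight (1e−13 on the unit
weight's successive change, sign-insensitive) and the iteration cap
generous (50 000 — near-degenerate pairs converge slowly but each step is
cheap). When the deflated X residual falls below 1e−12 of the original
Frobenius norm the requested component exceeds the data's effective rank
and the fit raises rather than regress on rounding noise (fitting past the
rank silently produces exploding coefficients and *decreasing* training
R²Y).

Q²Y uses leave-one-out at scan level (group-level folds available), with
the preprocessing scaler refit inside every fold — the training set is too
small to tolerate leakage. TSS uses the full-data Y mean; Q²Y may be
negative. A fold must retain at least A+1 scans.

VIP uses the standard multivariate-Y generalization
SSY_a = ‖q_a‖² t_aᵀt_a; Σ VIP² = p holds identically.

Correlation shading projects X-loadings onto Y-loadings per analyte
(`|Σ_a p_ja q_ka|`), smooths with a centered moving average (default
window 25 features — about a tenth of a pulse step, wide enough to merge a
transient with its decay, narrow enough to separate steps) and buckets at
⅓/⅔ of the per-analyte maximum into low/medium/high (0/50/100% shading).
Both thresholds and window are free parameters.

Component selection: the `elbow` strategy takes the marginal Q²Y gains
along the candidate list (the first listed count is the baseline) and
returns the count with the largest *drop* in gain — on a curve like
Q²Y(2..5) = 0.1, 0.6, 0.62, 0.63 that is 3. `fixed` honors a user's choice
with a logged note: deliberately deploying fewer components than the
cross-validation optimum is a legitimate overfitting guard on small, noisy
training sets, and the deployed configuration in this package's examples
is the 2-component model for exactly that reason.

### Why standardization recruits capacitive regions

The unscaled fit weights features by covariance with Y, i.e. by absolute
signal amplitude; the standardized fit weights them by correlation,
`s/√(s²+σ²)` — a *saturating* function of amplitude. Features whose signal
is a few times the noise floor (the concentration-coupled capacitive
transients) are invisible next to 10σ faradaic peaks in the unscaled fit
but saturate to near-unit correlation once standardized, and so clear the
VIP > 1 line. The region diagnostic (`feature_regions`) calls a feature
capacitive-transient-dominated within 5·RC of a potential transition, and
faradaic where some analyte's oxidation activation exceeds ½ past the
transient. The package's tests assert the *direction* of the contrast
(standardized marks more capacitive features than unscaled; a substantial
fraction of its important features lie outside faradaic windows), not any
particular count — printed counts from real recordings depend on data that
is not available.

## Quantification

Peri-stimulation windows take 150 scans before and 150 from onset (300
scans = 120 s at 5 scans/s, onset at index 150). Basal level = mean of the
first 100 scans; the mean of a constant trace is returned exactly so flat
traces have exactly zero AUC. Stimulation AUC = trapezoidal integral of
the baseline-subtracted trace over 52 scans from onset; subtracting the
basal mean is a choice (it makes AUC measure the stimulation-induced
increase), as is Welch's t-test over Student's for condition comparisons
(no equal-variance assumption; a flag restores Student's). Predicted
concentrations may be negative and are reported as-is by default — a real
phenomenon of linear calibration at low concentrations worth seeing, not
hiding; clipping is opt-in. The time-course smoothing window defaults to 5
scans (1 s at 5 Hz), enough to suppress scan-to-scan noise without
flattening a 2-s rise. The 4-sample microdialysis AUC window exists as a
documented preset only (`n_points=4`).

## Comparison harness

`run_grid` demultiplexes a combined calibration per waveform, optionally
subtracts the mean *blank* voltammogram (the blanks of the calibration run
are the only principled reference available within it), grid-searches
ℓ1/ℓ2/max normalization by Q²Y per cell, and reports R²Y and Q²Y for every
model × waveform × background × component-count cell — 24 rows by default.
Reports embed input hashes, the seed and the package version;
re-running with the same inputs is byte-identical. A missing waveform
yields explicit NaN rows, never silent omission.

## Problem sizes and tolerances

Tests and the acceptance script run on the sizes the design prescribes:
18-scan calibrations (plus 8 held-out mixtures), 400–800-scan sessions,
and the 24-cell grid; waveforms are digitized at 125 kHz where the
1000-feature layout matters and at 12.5 kHz (100 features, same geometry)
where only the pipeline structure is under test. Oracle agreements are
asserted at 1e−8 (coefficients vs an SVD-route PLS2), 1e−10 (Q²Y vs an
explicit LOO loop; VIP normalization), and exact-limit fits at 1e−8.
Basal-recovery accuracy is judged against the estimator's own spread
across replicate noise seeds rather than an absolute figure, since the
spread is itself a simulator property.

## Known limitations

- The simulator's linearity is the best case for PLSR; real electrodes
  saturate and foul.
- Capacitance coupling weights are not identifiable from the package's own
  synthetic data (any pair with the same ratio rescales), so they are
  stated constants, not estimates.
- The single-pole capacitive model ignores distributed (constant-phase)
  double-layer behavior.
- Group-level cross-validation (leaving out whole standards) is available
  but not the default; with three repeated blanks per subject, scan-level
  LOO is mildly optimistic on real repeated-measures data.
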