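# Methods

`nirspain` implements the analysis chain used in breathing-based pain
modulation studies with continuous-wave fNIRS: raw two-wavelength optics are
converted to hemoglobin concentration changes, thermal-pain (tQST) trials
are mapped with a prewhitened robust GLM and a mixed-effects group model,
breathing-practice recordings yield band-limited robust functional
connectivity, the cardiac pulse in the optics yields SDNN heart-rate
variability, and an elastic-net sweep relates connectivity edges to pain
thresholds. A synthetic cohort generator provides ground truth for every
stage. This note records the models, the parameters that matter, and the
numerical choices.

## Signal model and conversion

Raw intensities `I(t)` per channel and wavelength are converted to optical
density change `dOD(t) = -log(I(t)/I0)` with `I0` the **geometric** temporal
mean of the trace. The geometric mean makes `dOD` exactly zero-mean and
exactly linear in the underlying chromophore signal (an arithmetic-mean
baseline leaves a second-order offset through the exponential), so the
noiseless forward-inverse round trip is exact to floating point. Gain
changes of a channel cancel exactly.

The modified Beer-Lambert law relates `dOD` at the two wavelengths to
oxy/deoxyhemoglobin concentration changes:

    dOD_l = (eps_HbO,l * dHbO + eps_HbR,l * dHbR) * L * DPF_l

solved per time point as a 2x2 system. Packaged extinction coefficients
(OD / uM / cm): 690 nm — HbO 2.760e-4, HbR 2.052e-3; 830 nm — HbO 9.740e-4,
HbR 6.930e-4, from the standard compiled hemoglobin spectra. Defaults
`L = 3 cm` (the montage separation) and `DPF = 6.0` at both wavelengths are
configuration-exposed; they rescale concentrations only and cancel out of
every t-statistic, so their exact values are not load-bearing.

Down-sampling (25 Hz acquisition to 2 Hz for activation, 4 Hz for
connectivity) uses polyphase anti-aliased decimation. Band-pass filtering
uses zero-phase (forward-backward) Butterworth filters of order 4,
implemented as a separate high-pass/low-pass cascade so that each band edge
keeps its full rolloff even for very wide bands (0.01-2 Hz for the cardiac
signal). The double pass preserves event timing exactly; order 4 keeps
passband loss below 5% at the 0.01-0.08 Hz band centre while attenuating
the respiratory band (0.3-0.5 Hz) by >99%.

## First-level activation GLM

Per subject and channel, HbO at 2 Hz during the tQST phase is regressed on
a design with one column per condition (per-trial boxcars of the actual
ramp durations convolved with a canonical double-gamma HRF peaking at 6 s,
undershoot at 16 s at 1/6 amplitude, unit peak), plus intercept and linear
drift. The convolution is scaled by the sample interval so the coefficient
is invariant to the analysis rate. Trials are modelled as variable-duration
boxcars because the thermode ramp is an extended stimulus whose duration is
known per trial.

Estimation alternates (a) Tukey-bisquare robust regression (tuning constant
4.685) and (b) AR(p) modelling of the residuals with AIC order selection,
whitening both data and design by the fitted filter, until the coefficients
move less than 1e-6 or 10 alternations (non-convergence is flagged, the
last iterate kept). Two deliberate choices here:

* **AR order cap = 12 s of lags** (order 24 at 2 Hz). Slow vasomotor
  fluctuations overlap the trial frequency (~0.04 Hz at 26 s trial
  spacing); a shorter memory leaves them partly unwhitened and the
  confidence intervals under-cover (0.88 at a 4 s window in our
  calibration runs, ~0.94-0.95 at 12 s).
* **Burg recursion for AR estimation.** Yule-Walker's bias at strong
  autocorrelation (rho ~ 0.8) under-whitens and inflates the type-I error;
  Burg estimates reflection coefficients from forward/backward prediction
  errors and restores calibration.
* **Conditional treatment of the filter warm-up.** The causal whitening
  filter needs `order` past samples; its first outputs are mis-scaled and
  are dropped from the whitened regression (conditional-likelihood
  convention), which matters when the selected order is large.

Standard errors come from the whitened residuals with a short Newey-West
(Bartlett) correction — window 3 s — that absorbs the short-range residual
autocorrelation AR whitening leaves behind under strongly band-limited
noise. Calibration measured by simulation (1000+ replicates): type-I error
0.05-0.06 at alpha = .05 under AR(1) rho = 0.8 noise; 95% CI coverage
0.93-0.96 under the generator's default noise mix; ordinary unwhitened
least squares on the same data rejects at ~0.47.

## Group level

Per channel (and per connectivity edge), first-level estimates are combined
with a linear mixed-effects model with a subject random intercept, fit by
REML, followed by a two-tailed t-test `t = c'B / sqrt(c' Cov c)` and
Benjamini-Hochberg FDR over the 45 channels (or 990 edges). For the
balanced intercept-only case the REML solution has a closed form — a
one-sample t on subject means with n-1 dof (with a pooled-variance branch
when the random-intercept variance estimate hits zero) — which the package
uses as a fast path; general designs go through statsmodels MixedLM, with a
fixed-effects-only fallback (flagged) when the random-effects fit is
singular. The closed form is verified against brute-force GLS and MixedLM
in the test-suite. Degrees of freedom follow the subject count, not the
pooled per-observation count; published channel statistics that pool
differently will print different dof for the same effect.

## Functional connectivity

HbO during breathing practice, down-sampled to 4 Hz, is filtered into a low
(0.01-0.08 Hz) and a high (0.5-1 Hz) band — both chosen to avoid the Mayer
wave (0.1 Hz), respiration (0.3-0.5 Hz) and cardiac (1-1.5 Hz) bands. Every
unordered channel pair is correlated robustly: each channel is first
AR-prewhitened (AIC-selected order, Yule-Walker estimation — its stability
bias matters here, because Burg fits of band-limited series are marginally
stable and their whitening filters amplify out-of-band leakage
catastrophically), then a Tukey-reweighted correlation is iterated to
convergence with weights in the bivariate Mahalanobis distance of each
standardized sample pair. The Tukey cutoff is 6.5 rather than the
univariate 4.685: radial distances in 2-D concentrate around sqrt(2), and
the univariate constant over-downweights, inflating the null Fisher-Z
spread ~11%; at 6.5 the null spread is within ~2% of the nominal
1/sqrt(n-3) while gross outliers (|d| > 6.5) still get zero weight. A
plain-Pearson escape hatch (`robust=False, prewhiten=False`) exists for
oracle testing. Correlations are Fisher-transformed (`z = atanh r`),
degenerate pairs (duplicated channels) are masked with a warning, and group
edge maps use the mixed model above. The "significant pattern" is the edge
set with p below a configurable level (default .001).

Prewhitening corrects the autocorrelation-inflated degrees of freedom of
band-limited series, but imperfectly: an AR model cannot fully whiten a
brick-band process, so subject-level Z values carry an effective-sample
penalty (empirical null SD ~0.1 rather than 1/sqrt(n-3) ~ 0.03 at 300 s /
4 Hz). Group statistics are unaffected because they rest on
between-subject variation.

## Heart-rate variability

The cardiac pulse is extracted from 830 nm optical density: spatial weights
are the first principal component of a pulse-band (0.5-2 Hz) filtered copy
(the pulse is global, so averaging boosts SNR; estimating weights on the
raw series can instead lock onto slow vasomotor fluctuations), the weighted
trace is band-passed to 0.01-2 Hz, and peaks are detected as local maxima
above half the robust (MAD) amplitude with a 0.4 s refractory period (at
most 150 bpm). From peak times: `rr_i = t_{i+1} - t_i`, `SDNN` is the
sample standard deviation (n-1 denominator) of the intervals. Fewer than
three peaks is an error.

## Brain-behavior edge selection

Subject x visit rows of standardized edge Fisher-Z features are regressed
on mean tQST thresholds (degC) with elastic net. The lasso-ridge mixing
weight runs 0..1 in steps of 0.1; for each weight a geometric penalty path
(25 alphas spanning two decades below the null-model penalty) is scored by
10-fold cross-validation repeated over Monte-Carlo fold assignments (100 by
default), and the (weight, penalty) pair with minimum mean CV error is
refit on all rows. Edges with |coefficient| > 1e-8 are "selected", with one
convention: if the pure-ridge corner wins the sweep, the selected set is
empty — ridge zeroes no coefficients, so a ridge winner means the sweep
found no sparse structure (the null-selection outcome). An optional 1-SE
rule picks the sparsest penalty within one standard error of the minimum,
with the SE computed across the 10 fold MSEs (glmnet convention), averaged
over repetitions. Selected edges are reported with Pearson r (two-tailed
t-based p) and Spearman rho (rank correlation, robust to outlying
observations), unadjusted per-edge plus an FDR column. Groups can be pooled
or selected separately (`groups=` in `assemble_features`); visits are
pooled as separate rows by default.

With ~1000 candidate edges and ~40 rows, selection is intrinsically
unstable when the per-edge signal is modest: the expected maximum null
correlation at n=40 (~0.5) rivals a planted edge carrying a third of a
moderate coupling. Recovery statements should therefore be read per
replicate-ensemble, not per dataset.

## Synthetic cohort generator

The generator inverts the analysis assumptions so every stage is testable.
Defaults reproduce the study design: 2 groups (TMB/VRB) x 20 subjects x 2
visits at 25 Hz; 5 min rest, 10 min breathing practice, 20 tQST trials
(30 degC baseline, 1 degC/s ramp, stop at the subject's threshold, 10 s
rests), 5 min rest. Per channel, HbO sums:

* neural response: per-trial boxcars * canonical HRF, scaled by the planted
  beta (default 0.05 uM on the four S1 channels — chosen so single-subject
  t values land around 3-5 at 20 trials);
* low-band background (SD 0.3 uM): latent band-limited (0.01-0.08 Hz) unit
  factors mixed by the symmetric square root of the planted correlation
  matrix, so target edge correlations are hit exactly in population;
  per-subject edge strength varies on the Fisher-Z scale (SD 0.3), with
  deviations shrunk toward the targets when a joint draw would be
  infeasible (non-PSD);
* cardiac oscillation (0.3 uM): `cos(2 pi phase)` with a phase accumulator
  over a jittered R-R sequence (1.1 Hz base, 50 ms beat-to-beat SD), so
  waveform maxima fall exactly on beat times and ground-truth SDNN is
  exact by construction;
* Mayer (0.1 Hz) and respiratory (0.35 Hz) sinusoids (0.05 uM) with random
  per-channel phases so they plant no spurious cross-channel correlation;
* AR(1) noise (rho 0.3, SD 0.1 uM).

HbR is -1/3 of the neural + background HbO component plus independent
noise, so the Beer-Lambert inversion is a genuine 2x2 solve. Intensities
are the forward Beer-Lambert projection exponentiated around a unit
baseline. Thresholds are planted as intercept (45.4 degC) + slope
(-2 degC per Fisher-Z unit) x the subject's centred coupling-edge trait +
group offset (VRB +1.1) + visit offset (visit 2 +0.6) + residual (SD 0.5),
truncated to the 30-50 degC thermode range. All randomness flows from one
root seed through a `numpy.random.SeedSequence` splitting scheme (one child
per subject, grandchildren per signal component), so identical configs give
bit-identical cohorts.

`simulate_feature_table` exposes the trait/coupling layer directly
(standardized edge features with measurement noise SD 0.1 — the empirical
scale of the subject-level Z estimator — and a threshold coupled at a
requested population R2 across the planted edges); it exists so
selection-scale studies do not pay for optics and filtering per replicate.

What the generator does **not** emulate: motion artifacts, superficial
scalp/systemic contamination, spatially varying optode coupling, 1/f noise
shapes, or photon-transport optics. Passing tests therefore demonstrate
statistical correctness of the chain under a clean but structured forward
model, not robustness to every artifact class of real recordings.

## Problem sizes in the shipped checks

Simulation-based checks use reduced but statistically meaningful sizes
chosen for single-CPU runs: 2x10-subject single-visit cohorts with 3 min
breathing blocks for the 20-replicate group-map and edge-recovery studies;
200 replicates for CI coverage; 500 fits for type-I calibration; 20
replicate datasets at Monte-Carlo CV depth 20 for selection recovery. The
full 2x20 x 2-visit design with 10-minute blocks runs through the same code
paths (and is the generator default).

## Known limitations

* The channel->region table is a stand-in with the correct counts; the
  published montage is schematic, so no claim is made about true anatomical
  channel positions.
* SDNN is time-domain only (no LF/HF, RMSSD, or ectopic-beat handling).
* The robust correlation is an M-estimator, not the full
  skipped/percentage-bend family; its prewhitening is approximate for
  band-limited series (see above).
* Group dof conventions follow the mixed model, not any particular
  published pooling.
* Elastic-net selection at the CV minimum is unstable near the
  detectability boundary; the 1-SE option trades sensitivity for stability.
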