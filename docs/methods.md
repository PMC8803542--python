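# Methods

`motordcm` simulates and analyses crossover tDCS experiments on the
motor network during auditory-cued command following.  This note
documents the generative model, the inference machinery, the defaults
and their rationale, and what the synthetic data do and do not emulate.

## Neural and hemodynamic model

Each of the four regions (left M1, left SMA, left thalamus, right
cerebellum) carries one neural state `x_i` obeying the bilinear
equation

    dx/dt = J(u) x + C u_drive
    J_ij  = A_ij                              (i != j, Hz)
    J_ii  = -0.5 * exp(a_i + u_mod * b_i)     (unitless log-scalings)

The exponential self-connection parameterisation guarantees an
inhibitory diagonal for every finite parameter value, so the rest state
x = 0 is locally stable whenever the off-diagonal couplings do not
overwhelm it (checked explicitly; unstable draws are rejected).  Two
inputs enter: a driving "ping" — a unit-height pulse of 0.5 s at every
move-block onset — with per-region gains `C`, and a modulatory move-
block boxcar acting on the self-connections.  The boxcar is mean-centred
over the run, so `a_i` describes the session-average self-coupling and
`b_i` the task-related departure from it.

Neural activity drives the standard balloon model per region
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q):

    ds/dt = x - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v^(1/alpha)
    tau dq/dt = f (1 - (1-E0)^(1/f)) / E0 - v^(1/alpha) q / v

with BOLD observation `y = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v))`.
Constants default to the canonical values kappa = 0.64 s^-1,
gamma = 0.32 s^-1, tau = 2 s, alpha = 0.32, E0 = 0.4, V0 = 0.04, with
the classic observation coefficients k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.
Per-region log-scalings of kappa and tau can be estimated (tight
N(0, 1/256) priors); the other constants are fixed.

Integration is fixed-step RK4 at dt = TR/16 with inputs held piecewise
constant over each fine step; BOLD is sampled at volume times k*TR.
A numba-compiled batched integrator is the production path; a plain
NumPy implementation of the identical scheme is kept as the reference
and the two agree to machine precision, with step-halving changing the
output by < 1e-7 relative.

## Variational-Laplace inversion

The posterior is fixed-form Gaussian over the free parameters (12
between-region couplings, 4 self log-scalings, 4 modulatory effects,
the configured driving gains, and optionally 8 hemodynamic
log-scalings).  Priors are diagonal: A off-diagonal N(0, 1/16) Hz,
self and modulatory log-scalings N(0, 1/4), driving gains N(0, 1),
hemodynamic log-scalings N(0, 1/256).  Nuisance drifts — a constant
plus the discrete-cosine set with period > 80 s — are projected out of
data, predictions and Jacobians, with the effective degrees of freedom
reduced accordingly.

Each iteration computes the prediction and a forward-difference
Jacobian (step 1e-3 prior sd per parameter) in one integrator batch,
performs exact M-steps for the per-region noise log-precisions
(iterated with the posterior covariance; the residual power is floored
at 1e-8 of the data power so precisions stay finite on noiseless
inputs), and takes a Gauss-Newton step with Levenberg damping.  A step
is accepted only if the free energy increases, making the accepted-step
trace monotone by construction; damping grows eightfold on rejection.
Convergence is declared after three consecutive accepted steps with
|dF| < 1e-2 nats, capped at 64 iterations (non-convergence returns the
best estimate with a warning flag).  In the linear-Gaussian limit the
bound reproduces the conjugate closed-form log evidence to < 1e-6 nats.

## Hierarchical empirical Bayes, BMR and BMA

Lower-level posteriors `(m_i, S_i)` are treated as noisy observations
of a linear group model `theta_i = X_i beta + eps_i`, with
`eps_i ~ N(0, Sigma_b)` and a single diagonal between-level component
`Sigma_b = exp(-gamma) Q`.  By default Q scales each parameter by its
prior variance / 16 (exactly isotropic within a homogeneous parameter
field); `gamma` carries an N(0, 1/16) hyperprior and is optimised by
maximising the closed-form marginal evidence.  When the beta prior is
deliberately vague — as in the within-subject interaction models that
feed the group level — Q must not inherit that scale, so the absolute
between-level variance is passed explicitly there (first-level prior
scale / 16).

The three pairwise polarity-by-time analyses use the 4 sessions of the
two polarities involved.  The within-subject design has columns
[mean, interaction] with the interaction coded (-1, +1, +1, -1)/2 over
(pol1-pre, pol1-post, pol2-pre, pol2-post); a +delta post-only shift in
pol1 therefore appears as a group effect of delta/2.  The group design
adds mean-centred sex, age and handedness covariates (dropped
automatically when the cohort is too small to estimate them).

Bayesian model reduction computes the evidence change of replacing a
parameter's prior with a near-null prior (variance scaled by 1e-8)
analytically from the full posterior; the implementation matches the
1-D conjugate closed form to 1e-6 and is additive over independent
parameters.  The model search is exhaustive over on/off patterns when
at most 8 parameters are in play, otherwise a greedy elimination fixes
clearly-off (or clearly-on) parameters until an exhaustive stage of at
most 256 models remains.  Per-parameter posterior probabilities are the
summed evidence weights of models retaining the parameter; the
Bayesian model average is the evidence-weighted mean of the reduced
posteriors; effects are flagged at Pp > 0.95.

A note on model-space shares: the posterior probability of a *joint*
input configuration is bounded by the between-subject variance
component — each spurious input's removal can gain at most about
0.5 log(prior variance * n / Sigma_b) nats, so with 10 subjects the
true cortical-only driving configuration typically holds ~90% of the
evidence weight while the *per-input* family probabilities (input on
vs off) are far sharper (> 99.9% for the cortical gains).  Larger
cohorts or per-parameter variance components would be needed to push
the joint share itself above 99%.

## GLM, factorial interaction, VOI

The first-level design convolves the move-block boxcar with a
double-gamma HRF (peaks at 6 s and 16 s, undershoot ratio 1/6) on a
0.1 s grid, adds the cosine high-pass set (floor(2 * T / 80) - 1 drift
columns), optional motion nuisance columns, and a constant; fitting is
voxelwise OLS.  The group interaction F uses the repeated-measures
decomposition with the polarity-by-time-by-subject term as error
(df = 2 and 2(n-1)); suprathreshold voxels at uncorrected p < 1e-4 are
restricted to the ROI mask and clusters of a single voxel are discarded
as spurious.

Individual VOI peaks are local maxima (26-neighbourhood) of the
statistic map within 15 mm (M1, SMA, cerebellum) or 9 mm (thalamus) of
the group coordinate, accepted at the most stringent achievable rung of
the p = 0.05, 0.10, ..., 0.25 ladder, with the group coordinate itself
as the flagged fallback.  The VOI timeseries is the first principal
temporal component of the 4 mm sphere, sign-aligned to the sphere mean
and scaled to its variance (the sphere mean is available by flag; the
eigenvariate is the default because it downweights noise voxels at the
sphere edge).

## Kinematics

The joystick displacement is the Euclidean distance from the rest
position (the origin — the device is calibrated every session; a
median-based estimate is available), low-passed with a 4th-order
zero-phase Butterworth at 15 Hz.  Movement segmentation fits the
mean-shift change-point model by penalized optimal partitioning
(dynamic programming, provably equal to exhaustive search under the
same penalty).  The default penalty is 200 * sigma^2 * log n per
change-point with sigma the robust MAD scale of the trial window; the
large factor absorbs the heavy autocorrelation the 15 Hz low-pass
leaves at 1200 Hz sampling.  Trial extraction runs the DP on every 8th
sample and then refines both boundaries at the full rate by walking
outward until the signal re-enters the pre-movement baseline band
(median + 2 MAD of the pre-onset samples).  The refinement corrects
the 15-35 ms systematic onset lag a pure mean-shift model shows on
smooth displacement profiles; with the generator defaults the
run-level reaction-time bias is within +/-10 ms.

Velocity is the first difference of the filtered displacement times the
sampling rate and acceleration the second difference times the rate
squared; trials record the mean absolute velocity and peak absolute
acceleration over [onset, offset], and reaction time is onset minus cue
time.  Trials with no detected change are excluded but counted.  Run
summaries feed a 2 (time) x 3 (polarity) repeated-measures ANOVA
(partial eta squared as effect size); effects with exactly zero
within-subject variance report F = 0.  Blinding uses the exact
two-sided binomial McNemar test on the discordant pairs (p = 1 with a
note when there are none).

## The synthetic-data generator

The generator defines the study conditions: 8 + 8 alternating 20 s
blocks (320 s), 7 cues per move block at uniform 2-3 s intervals with
the first cue 0.5-1.5 s after block onset; TR 2.0 s / 160 volumes or
TR 2.7 s / 119 volumes; 21-subject crossover cohorts (126 sessions)
with age ~ N(25, 4), ~62% female, Edinburgh scores ~ N(80, 15).
Subject baselines are drawn once around the group means (between-
subject sd 0.05 Hz on couplings, 0.1 on self/modulatory/driving terms)
and shared across that subject's six sessions; post sessions add the
polarity's interaction shifts (default magnitude 0.2, signs following
the polarity-specific effect pattern of each montage; sham always 0).
Observation noise is i.i.d. Gaussian (typically specified as a fraction
of the noiseless signal sd), optionally plus slow cosine drift.
Joystick movements are minimum-jerk out-and-back bumps (duration
0.20 s, amplitude 1, additive noise sd 0.01) at latency 0.30 +/-
0.04 s after each cue.

Deliberately not emulated: spatial preprocessing and motion artefacts,
physiological noise spectra, scanner physics, inter-regional
hemodynamic delays, and session-order or carry-over effects.  Passing
tests therefore demonstrate correctness and calibration of the
*inference machinery* under the stated generative assumptions, not
robustness to the artefact structure of real scanner data.

For experiments that need many cohorts (group-level recovery and
calibration at 50 cohorts x 20 subjects), first-level posteriors are
emulated directly as Gaussians centred on the true session parameters
with sd 0.05 — the sharpness a converged single-run inversion attains —
rather than running tens of thousands of full inversions.  Full
variational inversions are still exercised end to end at 4-node scale
(20-run credible-interval coverage) and in the 10-subject model-space
experiment.

## Problem sizes and numerical choices

The test suite runs the full inversion at 160 volumes with 30 free
parameters (about 2 s per run after JIT compilation), 20-run recovery
and 2 x 50-cohort group experiments; the acceptance script runs the
10-subject model-space experiment.  Fixed numerical choices: RK4 at
dt = TR/16 (validated by step halving), forward-difference Jacobians at
1e-3 prior sd, null-prior variance ratio 1e-8 for BMR, damping start
1/128 with x8 growth and at most 8 retries per iteration, gamma search
bounded to [-5, 5], model-search cap 256.

## Known limitations

- Posterior covariances from variational Laplace are conservative under
  strong shrinkage; credible-interval coverage in the recovery tests
  runs near 100% rather than the nominal 95%.
- The single shared between-level variance component ties the
  uncertainty of null and non-null parameters together (see the
  model-space note above).
- The change-point default penalty is calibrated for trial windows in
  which movement occupies a minority of samples; signals that change
  state for half the window (an ideal step) need an explicit penalty.
- No slice-timing, no per-region hemodynamic delay differences, and no
  two-state or nonlinear neural models.
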