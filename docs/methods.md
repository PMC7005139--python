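# Methods

`hbdot` implements a complete resting-state diffuse-optical-tomography
(DOT) analysis chain for high-density fNIRS: a linearized photon-transport
forward model, channel-level preprocessing, three volumetric inverse
solvers, ROI partial-correlation connectivity, and a reproducibility /
similarity comparison battery — together with a synthetic-data generator
that produces multi-subject studies with known cortical connectivity and
known scalp interference, so every stage can be validated against ground
truth.

## Forward model

Photon transport is modelled analytically with the diffusion
approximation in a homogeneous semi-infinite medium.  The fluence
Green's function uses the extrapolated-boundary image-source
construction: an isotropic source one transport mean free path
(z0 = 1/mus') below the surface, mirrored about the plane z = -zb with
zb = 2 D (1+R_eff)/(1-R_eff), R_eff evaluated from the tissue refractive
index n = 1.37.  Baseline optics default to published head-tissue values
(scalp/skull mua = 0.019 mm^-1, mus = 7.8 mm^-1, g = 0.89; CSF
0.004/0.009/0.89; gray matter 0.02/9.0/0.89; white matter
0.08/40.9/0.84); the single-medium half-space uses the scalp/skull
values, since a layered analytic kernel is not available.  This
preserves the banana-shaped sensitivity geometry, its deepening with
source–detector separation, and source–detector reciprocity — the
properties the inverse solvers rely on — but it attenuates deep
signals more steeply than Monte-Carlo transport through a layered head
with a light-piping CSF layer.  Consequences of this are noted under
*Amplitude calibration* below.

The sensitivity matrix follows the Rytov linearization in base-10
optical-density (OD) convention:

    S(ch, v) = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) * voxel_volume / ln 10

mapping absorption changes (mm^-1) in 4-mm voxels to OD changes per
channel.  The reconstruction region is a 28-mm-deep cuboid under each
probe array, laterally extended by a factor 1.5 along the diagonals;
voxel layers: scalp/skull 0–11 mm (the *scalp* compartment), CSF
11–13 mm and gray matter below (the *cortex* compartment).

The default montage is checkerboard 4x4 probe arrays at 13-mm pitch.
All first- and second-nearest source–detector pairs are enumerated:
13-mm "short" channels sampling mostly scalp and sqrt(5)*13 ≈ 29.1-mm
"long" channels reaching cortex.  Four arrays give 96 short + 96 long
channels.  Montages are data (JSON probe coordinates), so a recorded
probe layout with different channel counts can be supplied directly.

Hemoglobin conversion uses a configurable molar-extinction table
(defaults at 780/805/830 nm, in mm^-1 mM^-1, from standard literature
compilations); oxy/deoxy unmixing is the per-voxel least-squares inverse
of the 3x2 extinction matrix.

## Preprocessing

1. Voltage to OD: od(t) = -log10(V(t)/Vbar) with the per-channel
   temporal mean as reference intensity.  Channels with non-positive
   samples are flagged invalid rather than transformed.
2. Channel rejection: coefficient of variation CV = 100 sigma/mu on raw
   voltages; a channel is rejected when CV exceeds 15% at any wavelength
   (strictly — exactly 15.0% is retained) or when it saturates (at the
   ADC ceiling for ≥1% of samples; the ceiling is configurable because
   it is hardware-specific).
3. Band-pass: Butterworth high-pass order 3 at 0.009 Hz cascaded with
   low-pass order 7 at 0.08 Hz.  Zero-phase (forward–backward)
   application is the default so connectivity is not phase-distorted; a
   single-pass mode exists whose gain follows the analytic magnitude
   response, used by the validation suite.
4. Scalp regression (minimum-norm branch only): the global mean of the
   good short channels is taken as the scalp signal and removed from
   every channel by least squares.  The hierarchical-Bayes branch skips
   this step because its model carries an explicit scalp compartment.
5. Motion censoring: time points where any good short channel exceeds
   3 SD from its mean (computed after filtering) are dropped from all
   channels; zero-variance channels never trigger removal.  Points are
   dropped, not interpolated, so downstream analyses run on the retained
   samples only.

## Inverse solvers

All solvers invert Y = S X + noise per wavelength; species are unmixed
afterwards.  Depth compensation uses the spatially variant weights
L_vv = sqrt(rho2_v + beta), with rho2 the squared sensitivity column
norm normalized by its maximum.  The WU variant (MN-WU) fixes
beta = 0.1; the modified minimum-norm (MN) derives beta as the mean of
rho2 over voxels near 20 mm depth (18–22 mm band), which compensates
depth much more aggressively.  The regularization constant alpha of
both minimum-norm solvers maximizes the type-II marginal likelihood of
the Gaussian model y = S~ x + e (x ~ N(0, sI), e ~ N(0, alpha s I)),
profiled over s in closed form via the eigendecomposition of S~S~^T,
searched on a log grid of 61 points spanning ten decades.  The grid is
interpreted relative to the mean Gram diagonal, making the search
invariant to the overall scale of the design; ties prefer the smallest
alpha.

The hierarchical-Bayes (HB) solver reconstructs scalp and cortex
simultaneously in two steps.

*First step.*  The scalp compartment is represented on a smooth
Gaussian basis (kernels on a lateral grid, FWHM 30 mm, uniform across
the scalp depth layers) and fitted first with a light ridge
(0.01 x mean Gram diagonal); a depth-compensated ridge solve of the
cortex (cortex-normalized rho2, 20-mm beta rule, ridge 1.0 x mean Gram
diagonal) then runs on the residual.  The per-voxel temporal mean
squares of this solution are the prior variance means lambda0; the
basis-coefficient mean squares fix the scalp prior.  Three choices here
deserve explanation:

- **Deflation order.**  The superficial layer's sensitivity exceeds the
  cortical one by orders of magnitude, so any jointly minimum-norm
  solution attributes almost everything — including cortical signal —
  to whichever columns are cheapest under the norm penalty.  Fitting
  the scalp basis first and the cortex on the residual resolves the
  degeneracy in the physically motivated direction: smooth
  scalp-representable signal is scalp; what the scalp cannot explain
  (in particular the long-vs-short channel profile of cortical
  activity) seeds the cortical prior.
- **Cortex-normalized depth weights.**  Normalizing rho2 within the
  cortex compartment bounds the depth amplification to the dynamic
  range of cortical sensitivities; normalizing against the global
  (scalp-dominated) maximum would equalize all cortical columns at the
  scalp scale and amplify deep noise by ~10^3.
- **Fixed relative ridges instead of evidence maximization.**  Signals
  band-limited to 0.009–0.08 Hz carry roughly 2 x bandwidth x duration
  independent temporal samples — about 40–90 for 5–10-minute runs —
  which is *fewer than the number of channels*.  The filtered channel
  covariance is therefore rank-deficient and the iid-time marginal
  likelihood degenerates on the deflation residual (it drives alpha to
  the top of any grid and collapses lambda0 to the floor).  Fixed
  fractions of the mean Gram diagonal are scale-invariant, deterministic
  and robust to this regime.

*Second step.*  A variational automatic-relevance-determination (ARD)
iteration refines the image.  With F = [S_cortex, S_scalp B] and
per-latent variances Lambda:

- E-step: posterior mean X = Lambda F^T (F Lambda F^T + sigma2 I)^-1 Y
  and posterior variances diag(Sigma_post);
- M-step (cortex voxels): lambda_v <- (sum_t <x_v,t^2> + 2 gamma0
  lambda0_v) / (T + 2 gamma0), where <x^2> is the posterior second
  moment; scalp-basis variances stay fixed;
- noise: sigma2 <- expected mean squared residual (fit residual plus
  the posterior-variance contribution), updated unless a fixed value is
  supplied.  sigma2 initializes at 0.1 x mean(Y^2) and shrinks — a
  small initialization is a local trap in which the model explains
  noise as signal.

The confidence gamma0 interpolates between the two analytic limits the
implementation is tested against: gamma0 -> infinity reproduces the
fixed-lambda0 ridge solution exactly, and gamma0 = 0 reduces the M-step
to the pure data-driven ARD rule lambda_v = (1/T) sum <x^2>.  The
default is gamma0 = 0.1 L with L the retained sample count; the sweep
values {0.01, 0.001, 0.0001} L are supported and exercised by the
study driver.  All iteration moments are computed from the channel Gram
matrix Y Y^T, so the per-iteration cost is independent of the run
length.  Convergence is declared when the largest variance change falls
below `tol` relative to the largest variance (changes far below the
dominant scale do not move the solution); defaults: 500 iterations
maximum, tol 1e-4, variance floor 1e-12.  Consecutive gamma0 settings
may warm-start from the previous converged variances.

## Connectivity

Reconstructed images are smoothed with an 8-mm-FWHM Gaussian
(sigma = FWHM/sqrt(8 ln 2)); the kernel matrix is built over voxel
center distances, truncated at 3 sigma, row-normalized (constants are
exactly preserved) and restricted within compartments.  Voxels whose
max-normalized cortical sensitivity exceeds 0.5 in every subject are
*sensitive*; ROIs (integer label volumes; the synthetic parcellation
tiles the sensitive cortex into balanced contiguous tiles) with at
least 10 sensitive voxels are *available*.  ROI series are unweighted
means over sensitive member voxels, and connectivity is the partial
correlation read off the inverse sample covariance,
pc_ij = -P_ij / sqrt(P_ii P_jj), which equals the correlation of
residuals after regressing out all other ROIs.  Segments shorter than
3 x R samples engage a small ridge on the covariance diagonal (warned).

## Comparison battery

Similarity between two connectivity matrices: vectorize the strict
lower triangles, Fisher-z transform entrywise (inputs clipped at
1 - 1e-7), Pearson-correlate, Fisher-z the coefficient.
Reproducibility designs follow the split-half scheme: each run's
retained samples are halved at the midpoint (first half keeps the odd
sample), and the four designs intra_run1, intra_run2, inter_FH,
inter_SH are summarized per subject by r, ICC(C,1) and ICC(C,k).  The
ICCs are two-way mixed consistency coefficients computed from the ANOVA
decomposition over Fisher-z connection values (items = ROI pairs,
raters = runs/halves); ICC(C,k) and ICC(C,1) satisfy the
Spearman–Brown identity by construction.  Group comparisons use a
one-way ANOVA followed by Tukey–Kramer pairwise comparisons
(studentized-range distribution, unequal-n form); the intra-run versus
half-length inter-run contrast is an unpaired two-sided equal-variance
t-test on the Fisher-z similarities.

## Synthetic studies

The generator emulates the target acquisition: 18.5 Hz sampling,
two 10-minute resting runs per subject, 20 subjects by default, three
wavelengths, and the default montage above.  Its components:

- **Cortical dynamics.**  A random sparse SPD precision matrix over R
  ROIs (default 19, the available-ROI count of the emulated montage)
  defines the ground-truth partial correlations.  ROI latents are AR(1)
  innovations band-passed to 0.009–0.08 Hz, then *exactly* colored:
  empirical whitening followed by the Cholesky factor of the target
  correlation, so the sample covariance of the latents equals the
  target and the truth matrix is not blurred by finite-sample noise.
  Voxels of a ROI share its latent plus independent voxel noise
  (relative SD 0.3).
- **Scalp interference**, deliberately spatially inhomogeneous: a
  global sinusoid mixture (0.01, 0.04, 0.1 Hz, random phases) with a
  1.1-Hz cardiac tone (40% of the scalp channel variance), plus a
  smooth random field (60%): per-voxel band-limited (0.01–0.1 Hz)
  noise smoothed laterally with a 40-mm correlation length, coherent
  across scalp depth and of full temporal rank, so it can be neither
  removed by global short-channel regression nor conditioned out by
  the partial correlation — the failure mode the HB model's spatial
  scalp compartment addresses.
- **Amplitude calibration** is at the channel level: the cortical
  contribution is scaled so its mean long-channel OD SD equals
  `cortical_od` (default 5e-4), and the scalp contribution to 1.5x
  that.  Calibrating voxel amplitudes instead would make the cortex
  invisible (~1e-6 of channel variance) under the analytic kernel's
  steep depth attenuation, which is a property of the kernel, not of
  cortex physiology; the channel-level convention keeps the
  scalp-to-cortex mixing ratio realistic at the sensors while
  preserving the relative geometry (short channels carry a larger scalp
  share).  Channel noise is white + 1/f (half the variance each) at a
  long-channel SNR of 5.
- **Artifacts**: two high-CV channels (slow OD drift), one saturated
  channel (clipped at the ADC ceiling for ≥5% of samples), and
  Poisson-placed motion spikes (3 per run, 0.5–2 s, 20x channel SD,
  common timing across channels).
- A noiseless **reference modality** (ROI latents + 10% independent
  noise) is exported per run, standing in for a concurrent hemodynamic
  reference measurement.
- Determinism: per-subject, per-run generators are spawned from the
  master seed; regeneration is bit-identical.

What the generator does *not* emulate: subject-specific anatomy (all
subjects share one grid and forward model — the spatial-normalization
step of real multi-subject data is out of scope), wavelength-dependent
baseline optics, physiologically detailed hemodynamic models, and
forward-model mismatch (generation and reconstruction share S by
default, so study results quantify algorithmic behaviour under a
correct model, not robustness to model error; an optional perturbed
optics mode regenerates S with scaled mus' for robustness checks).
Passing tests therefore demonstrate correct and well-ordered behaviour
of the estimators under the stated generative model, not performance on
real recordings.

## Validation problem sizes

The localization phantom uses 2 arrays (96 channels), 6-mm voxels
(~490 voxels), T = 1000 samples, 5% channel noise, scalp field 1.5x the
cortical long-channel amplitude.  The full synthetic study runs
5 subjects x 2 runs x 10 min at 18.5 Hz with 19 ROIs on the four-array
montage, all three algorithms and the gamma0 sweep
{0.1, 0.01, 0.001, 0.0001} L; the study driver composes each solver's
voxel-space operator with the smoothing and ROI-averaging operators, so
full voxel-by-time images are never materialized.  These sizes were
chosen so the whole battery runs on a single CPU at desk scale.

## Known limitations

- **Reproducibility rewards bias on synthetic data.**  Inter-run
  reproducibility correlates two runs' connectivity estimates; its
  value is var(stable)/(var(stable)+var(run noise)).  In a
  shared-truth synthetic world the stable component of the smoother
  minimum-norm estimates is dominated by their mixing bias, which is
  large precisely because they track the truth less faithfully — so
  the less biased hierarchical estimate scores *lower* inter-run
  reproducibility here even while scoring higher similarity to truth.
  This was verified not to be a convergence or operator-instability
  effect (results are unchanged at 4x the iteration cap, and freezing
  one run's operator for the other run does not raise the score).
  Reported empirical reproducibility advantages of hierarchical DOT on
  human data plausibly rest on depth-amplified physiological noise
  entering the deeper sensitive-voxel sets of transport-accurate
  forward models, a mechanism outside this generator's reach.

- The analytic single-medium forward model understates deep
  sensitivity relative to Monte-Carlo transport in layered heads; with
  it, spatially broad cortical activity is nearly degenerate with
  smooth scalp fields, separated only by the short/long channel
  profile.  The first-step design above is what makes that separation
  reliable; with a transport-accurate sensitivity matrix the same code
  path applies unchanged.
- Evidence-based regularization is only trustworthy when the data
  carry broadband noise; on band-limited, rank-deficient data the
  fixed-relative-ridge first step is used instead (see above).
- ICCs are computed on Fisher-z connection values; raw-scale ICCs can
  be obtained by transforming inputs externally.
- The saturation criterion and ADC ceiling are instrument-specific and
  must be configured for real hardware.
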