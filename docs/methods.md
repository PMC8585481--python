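# Methods

## Stimulus synthesis

A stimulus is a broadband carrier multiplied by a non-negative envelope.
Modulators are built in the frequency domain: amplitude ∝ f^(−χ/2) (so power
∝ f^(−χ)), DC bin zeroed, phases i.i.d. uniform from the seed, real inverse
FFT, then a zero-phase 4th-order Butterworth low-pass at 100 Hz and an
affine rescale to [0, 1]. Rescaling to [0, 1] before multiplication gives a
physically meaningful non-negative AM depth and matches the visual
convention; a constant (zero-range) envelope maps to mid-range. Carriers
are Gaussian white noise, zero-phase high-passed at 200 Hz (4th-order
Butterworth). Auditory stimuli are RMS-normalized to 1; visual stimuli are
the envelope itself, resampled (anti-aliased polyphase, line-padded) to the
85 Hz display rate and rescaled to [0.5, 1].

Trials are 4–4.5 s snippets cut at seeded random offsets from 30 s parents.
A snippet's local AM exponent is re-estimated from its own envelope and
generally differs from the parent's nominal χ — this is what produces the
wide trial-wise exponent distribution the analyses rely on.

Targets cross-fade the noise AM toward a sinusoidal AM, (1 + sin)/2 shape
with a seeded random initial phase, inside a 400 ms window with 50 ms
raised-cosine flanks. The blend weight is scaled by the modulation depth,
so depth 0 leaves the stimulus bit-identical and depth 1 yields a pure
sinusoidal AM. Auditory targets re-multiply the stored carrier with the
blended envelope and re-normalize.

Trial-wise AM exponents: the envelope is decimated to 250 Hz (the analysis
band ends at 30 Hz), Welch-estimated on a 0.1 Hz grid using 4 s averaging
windows zero-padded to the grid (pwelch semantics; short snippets are
mirror-padded first), and parameterized over 1–25 Hz with the stimulus
preset. The 4 s window trades frequency-resolution independence for
segment averaging; with 30 s modulators this averages ~14 segments and
keeps single-realization exponent errors below ~0.1.

## Spectral parameterization

The model is log10 P(f) = offset − χ·log10 f + Σᵢ hᵢ·exp(−(f−cᵢ)²/2wᵢ²),
fitted in log10 space ("fixed" aperiodic mode only; no knee):

1. Robust aperiodic fit: ordinary least squares, then a refit using only
   points whose clipped positive residual lies at or below the 2.5th
   percentile — this discounts oscillatory bumps.
2. Iterative peak extraction from the flattened spectrum: the running
   maximum is accepted as a peak only if it exceeds *both* the
   SD-relative threshold (peak_threshold × SD of the current flattened
   spectrum) and the absolute minimum height; the Gaussian guess width
   comes from the half-height span (FWHM/2.355), clamped to half the
   width limits; guesses whose center lies within one SD of a fit-range
   edge are dropped. "Unbounded" peak counts are capped at 16 with a
   warning to guarantee termination.
3. Joint bounded nonlinear least-squares refit of all Gaussians
   (tolerances 1e-8; centers bounded to ±2 SD of the guess, SDs to half
   the width limits).
4. Final robust aperiodic refit on the peak-subtracted spectrum.
5. R² and mean absolute error of the full model in log10 space;
   non-convergence returns a flagged fit with R² = 0.

Presets: `anaesthesia`/`eeg_trial` (range 3–55 Hz, widths [1, 8], max 8
peaks, min height 0.05, threshold 2.0) and `stimulus` (range 1–25 Hz,
widths [0.5, 12], unbounded, min height 0, threshold 2.0). Welch uses a
Hann window with 50 % overlap; 0 Hz is excluded from all fits. Mirror
padding appends time-reversed copies on both sides, tripling the analysis
length for short epochs. QC keeps fits with R² ≥ 0.2. Alpha power is the
tallest detected 8–12 Hz peak's height, or the band-average log power when
no peak was detected (tie-break: tallest wins). The R² gate refers to the
full model (aperiodic + peaks).

## Synthetic experiments

Default session: 12 blocks × 36 trials (432 per subject), attention
alternating between blocks (starting modality alternates across subjects),
stimulus exponents drawn i.i.d. uniform on [0, 3] per modality (sample
correlation |r| < 0.1 at n = 432 by construction).

**Staircase.** Weighted up-down on target modulation depth: after a correct
response depth decreases by step_down, after an error it increases by
step_up, with step_down/step_up = (1−p)/p and p = 0.7, so the stationary
point sits where the observer is 70 % correct. Defaults: initial depth 0.5,
step_up 0.035, floor 0.005, one staircase per modality. The simulated
observer is a logistic psychometric function p = guess +
(1−guess−lapse)/(1+exp(−slope·(depth−threshold))); defaults threshold 0.2,
slope 10, lapse 0.02, guess 0.05. Stationary accuracy converges to 70 ± 5 %
across thresholds 0.05–0.5.

**EEG generator.** Trial-wise exponents are
χ0 + subject offset + attention shift + noise_sd·(b_aud·z_aud + b_vis·z_vis
+ √(1−b²)·ε), where z are z-scored stimulus exponents and ε is standard
normal, shared across electrodes within a trial. The couplings b are
*standardized*: the correlation between trial-wise exponent fluctuations
and the stimulus exponent equals b by construction, at any overall
dispersion noise_sd, so the two-step tracking beta recovers b directly.
Attention shifts the attended modality's ROI (fronto-central for auditory,
parieto-occipital for visual) by −0.1 by default (flattening); a separate
central-ROI override allows asymmetric plants. A small independent
per-electrode jitter (0.1·noise_sd) adds spatial variability. Two fidelity
tiers: `fast` plants exponents in closed form; `full` synthesizes time
series as random-phase mixtures of the aperiodic slope plus an alpha
Gaussian (inverse FFT of √P with log-space noise) and re-estimates
exponents through Welch + parameterization, which adds estimation noise
and slightly dilutes planted couplings.

The montage is a reduced 12-electrode set — the two 6-electrode ROIs —
rather than a full 64-channel cap; nothing in the analyses depends on
channel count.

**TRFs.** Envelope onsets: magnitude of the analytic signal (skipped for
series that already are envelopes), zero-phase low-pass below 20 Hz,
polyphase resample to 250 Hz, first difference, half-wave rectification.
Ridge estimation builds a lag-expanded design matrix over −100…500 ms
(default; configurable), accumulates normal equations across trials, and
selects λ from 10⁻³…10³ (7 log-spaced values) by cross-validated
prediction correlation over trial folds; backward models negate the lag
axis. Leave-one-subject-out reconstruction averages the other subjects'
backward weights and intercepts, reconstructs each trial, and tests each
subject's per-trial correlation distribution against zero. The canonical
kernel is a damped biphasic waveform (positive lobe near 80 ms, negative
near 200 ms, zero by ~400 ms), scaled per attention condition.

**Forward sweep.** `forward_exponent_sweep` probes whether phase-locked
convolution alone couples stimulus and EEG exponents: per trial a fresh
power-law envelope (χ ∈ {0,1,2,3}, 12 s at 250 Hz) is converted to onsets,
convolved with the attention condition's canonical kernel, and the
noise-free one-channel output parameterized exactly like measured EEG. The
swept modality is presented alone: the simulated spectra are dominated by
the kernel roll-off above ~20 Hz, so any additive broadband component
(noise, or a second fixed input stream) interacts with the χ-dependent
signal level and can mask or even invert the link; isolating one stream
measures the convolutional coupling itself. The absolute simulated
exponents are large (the fit range extends past the onset band), but their
*ordering* follows stimulus χ: the 4-bin linear model yields a positive,
highly significant bin coefficient for either modality. Only sign and
significance are meaningful; the magnitude is generator-dependent.

## Inference

Attention contrast: per subject and electrode, single-trial exponents are
residualized on auditory and visual stimulus exponents, alpha power and
trial number; residuals are averaged per attention condition, then per ROI;
a 2×2 within-subject ANOVA (computed from sums of squares; for 2-level
factors F = t² of the paired contrast) gives main effects and interaction
with partial η², plus paired follow-ups with Cohen's d per ROI.

Tracking beta: step 1 regresses the EEG exponent on attention (effect-coded
±0.5; omitted within an attention subset), trial number and the *other*
modality's exponent; step 2 regresses the z-scored residuals on the
z-scored target exponent. The slope equals the residual correlation, so
|β| ≤ 1 and it is invariant to positive rescaling of the EEG exponents.

Permutation contrast: paired t on subject-wise condition means; the null
shuffles epoch-level labels within subject (preserving subject structure);
p = #(|t_perm| ≥ |t_obs|)/n_perm two-sided by default, with a one-sided
tail and a (k+1)/(n+1) variant available. Cluster permutation: one-sample
t per position, threshold |t| > t(0.975, n−1) by default, clusters
connected under the supplied adjacency scored by summed t, positive and
negative clusters separately; the null is the maximum |cluster mass| under
random subject sign flips. Holm and Benjamini–Hochberg decisions delegate
to statsmodels.

Behaviour: per-modality accuracy is residualized across subjects on the
final staircase depth of that modality; response speed (1/RT) is
residualized on trial number within subject and averaged — four features
per subject. In the simulator, reaction times are generated for correct
(detection) responses only.

## Behavioural PLS

R = Spearman correlations of every brain feature (electrode × modality
tracking betas) with every behavioural measure; SVD of the stacked R gives
min(n_features, n_behaviours) latent variables (a per-brain-variable
option runs one SVD per modality block instead). Permutation p values
permute behaviour rows across subjects, comparing each observed singular
value with the null distribution of the same-ranked singular value.
Bootstrap resamples subjects with replacement; each resample's singular
vectors are aligned to the original by maximal |inner product| (order)
and sign agreement before accumulation; BSR = original salience /
bootstrap SE (|BSR| > 2 ≈ robust), and percentile 95 % CIs are reported
for the singular-value-scaled behaviour weights. Degenerate resamples
(zero-variance features) are redrawn and counted.

## What the synthetic data do and do not show

The generators emulate the *structure* of a multisensory tracking study —
trial counts, block alternation, staircase-controlled difficulty, wide
uncorrelated AM exponent distributions, 1/f-plus-alpha spectra, planted
linear couplings — but not volume conduction, spatial covariance,
artifacts, non-stationarity, or realistic between-subject heterogeneity
(which is deliberately small, making synthetic effect sizes much larger
than physiological ones). Passing tests therefore validate the estimators
and their calibration, not any empirical claim about real EEG.

## Numerical choices and problem sizes

Zero-phase filtering throughout (sosfiltfilt); polyphase resampling with
line padding to suppress edge transients; Gaussian refits with 1e-8
tolerances; permutation/bootstrap streams seeded via SHA-256-derived
per-stage seeds (below 2³¹) from a master seed, so identical configurations
reproduce byte-identical outputs. Test and demo problem sizes (e.g. 2 kHz
modulator rate instead of 44.1 kHz, reduced resampling counts, 200–500
calibration replicates) were chosen as the smallest sizes at which the
Monte-Carlo tolerances are meaningful; the CLI's `--paper-scale` flag
restores full resampling counts. Known limitations: the parameterization
supports only the fixed (knee-free) aperiodic mode; the RM-ANOVA is
specialized to the 2×2 within-subject design; multi-channel TRFs are
estimated channel-wise rather than jointly.
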