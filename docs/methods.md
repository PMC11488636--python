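# Methods

This note documents the models, defaults and numerical choices behind
`efpnf`, and what the synthetic study conditions do and do not show
about real recordings.

## Latent arousal and signal synthesis

The ground truth is a latent "arousal" series standing in for right
amygdala activity. It is an Ornstein–Uhlenbeck process
dX = θ(μ − X)dt + σ dW generated with the exact transition density at a
4-Hz internal rate (matching the 4-Hz feature grid of the EFP model)
and linearly interpolated to 250 Hz where the EEG needs it. Defaults
θ = 0.25 s⁻¹, σ = 0.5, μ = 0 give a stationary SD of ~0.7 and a
~4-s correlation time, i.e. slow arousal fluctuations on the timescale
of feedback samples.

**BOLD.** The latent series is convolved with the canonical
double-gamma HRF (gamma shapes 6 and 16, unit rate, undershoot ratio 6,
32-s support, peak-normalized to 1; the positive lobe peaks near 5 s)
and resampled at the TR (default 3 s), plus white noise. The discrete
convolution uses the kernel sampled at the latent rate, so a
unit-impulse latent reproduces the kernel exactly; the series is in
arbitrary units.

**EEG.** The Pz channel is a sum of amplitude-modulated sinusoidal
carriers, pink (1/f-power) background, a 50-Hz line sinusoid, and white
noise. Each carrier sits at the centre of its coupled band with a
seeded random phase, and its instantaneous amplitude is
max(a₀ + a₁·latent, 0). The defaults couple the latent **positively to
theta** (4–8 Hz, a₀ = 2 µV, a₁ = +0.8) and **negatively to beta**
(13–30 Hz, a₀ = 1.5 µV, a₁ = −0.5); the couplings are recorded as
ground truth but never revealed to the model fit, and the fitted weight
signs are checked against them in tests. Sinusoidal carriers were
chosen over narrowband noise because the magnitude S-transform of a
stationary tone is invariant to its phase, which makes the noise-free
limit exactly reproducible (an idle noise-free agent yields a constant
EFP and success indices of exactly zero); real EEG rhythms are
broader-band, so the synthetic bands concentrate spectral energy more
sharply than physiology would.

**Regulating agent.** Arousal relaxes to baseline with time constant
τ = 15 s and, during Regulate, receives an extra downward drift
g·(1 + λ·(s − 1)) for session s, integrated by Euler–Maruyama at 4 Hz
with innovation SD 0.1·√dt. Defaults g = 0.1 units/s and λ = 0.2 per
session (session 10 drifts 2.8× as hard as session 1) were chosen so
that the generator embodies the design premise of reliable learning
over ten sessions at the individual-subject level — a stronger
condition than a group-level trend. During closed-loop runs the current
feedback level ℓ multiplies the drift by (11 − ℓ)/10, so good feedback
(low ℓ) sustains regulation; this is a minimal reinforcement coupling,
not a claim about the mechanism in participants.

**Clinical cohort.** Scores are Gaussian around group trajectory means
with a subject random intercept carrying fraction ICC = 0.6 of the
baseline variance, clipped to instrument ranges (CAPS-5 and PCL-5
totals 0–80, DES-II 0–100). Group sizes (40/15), baseline means/SDs,
the post-treatment CAPS-5 changes (−8.86 / −3.28), PCL-5 endpoints, and
loss-of-diagnosis probabilities (0.40 / 0.15, expected ARR 0.25,
NNT 4) follow the published group summaries; PCL-5 follow-up means
interpolate linearly between the printed pre and 6-month values.
Dropout is independent per timepoint (missing at random; pre never
missing) with probabilities 0.025 / 0.30 / 0.35 / 0.50 at post / 1 / 3 /
6 months, giving follow-up cohort sizes comparable to the reported
per-protocol analyses. MAR dropout is exactly the regime a
likelihood-based mixed model handles; informative dropout is not
modelled, so the tests say nothing about attrition bias.

## The EFP model

Every 3 s the estimate uses the 12-s Pz segment ending at (and
including) the sample time:

1. zero-phase second-order IIR notch at 50 Hz, quality 40 (double-pass
   gain at 50 Hz ≈ 10⁻¹⁰; < 1 dB ripple outside ±2 Hz), with 2 s of
   reflective padding so edge transients are negligible;
2. Stockwell transform via the FFT identity (row n = inverse FFT of the
   n-bin-shifted spectrum tapered by exp(−2π²m²/n²)); only the rows
   inside the band range are computed. The transform is circular in
   time; an O(N²) direct double-sum against the analytically periodized
   Gaussian window serves as an independent oracle (agreement ≤ 10⁻⁸
   relative on 256-sample inputs);
3. band reduction to 10 bands whose edges are the deciles of cumulative
   Welch spectral energy of the notch-filtered calibration recording
   over 0.5–40 Hz (default range: physiological EEG content, excluding
   the line frequency). Welch uses 16 384-sample segments so that steep
   spectra are resolved; each band then holds 10 ± <1% of calibration
   energy by construction. Banding is per-calibration-recording; a
   fitted model freezes its bands;
4. block means over the S-transform time axis onto 48 columns
   (4 Hz × 12 s; block k covers samples ⌊kN/48⌋…⌊(k+1)N/48⌋, i.e. the
   window covers (t − 12 s, t]);
5. prediction = intercept + ⟨weights, features⟩ with a 10 × 48 weight
   matrix.

Amplitude (not power) is band-averaged; this keeps features linear in
carrier amplitude, which is the quantity the generator modulates.

**Fitting.** Ridge regression of the flattened 480-vector on the
HRF-convolved latent sampled at window end times (the estimate targets
hemodynamic-timescale activity; a fixed-lag alternative is a caller
choice). Features are standardized internally and the weights folded
back to raw units. λ is selected from a logarithmic grid 10⁻³…10³ by
blocked cross-validation over three contiguous segments — random folds
would leak temporally autocorrelated samples — and the fit report
stores the held-out Pearson r per λ. With 480 features, exact weight
recovery is only identified when more than 480 windows are available
and the target lies in the feature row space; tests construct that case
explicitly.

## Closed loop and success indices

The training schedule is Rest 180 s then five cycles of Watch 60 s /
Regulate 180 s (1380 s); the fMRI assessment schedule is Rest 54 s then
two cycles of Watch 60 s / Regulate 60 s / Washout 9 s / Fixation 15 s
(342 s; the washout regressor models only the 9-s feedback display).
Each Regulate sample is standardized against the 20 samples of the
immediately preceding Watch block (sample SD); Watch blocks receive no
feedback. The 1–10 mapping is clamp(round-half-up(5.5 + 2Z)), chosen so
±2.25 SD spans the scale, monotone by construction, with degenerate Z
mapped to mid-scale.

Success index SI = (mean Regulate − mean Watch)/SD(Watch); negative
values mean down-regulation. When SD(Watch) falls below 10⁻⁵ of the
signal scale the baseline is flagged degenerate: if the condition means
also agree at that scale the SI is exactly 0 (an idle noise-free agent),
otherwise the large signed ratio is kept (a skilled noise-free agent
regulating against a numerically flat baseline). The threshold sits
about five orders of magnitude above the jitter that zero-phase
filtering leaves on constant windows and far below any real modulation.

Population-scale learning analyses (hundreds of subjects) run at the
agent level — success indices computed on the latent samples directly —
because the qualitative learning behaviour lives in the agent dynamics;
the full EEG → Stockwell → prediction loop is exercised per-session in
dedicated tests, where prediction adds no systematic bias at the
default SNR.

## Statistics layer

- ANCOVA: OLS of post on pre + group with listwise deletion; group F is
  the squared coefficient t; partial η² = SS_group/(SS_group + SS_res).
  A numerically perfect fit (post ≡ pre) reports F = 0, p = 1.
- Intention-to-treat mixed model: REML fit of
  score ~ group + time + group×time with a subject random intercept,
  which is exactly the compound-symmetry covariance for non-negative
  intraclass correlation (negative ICC is outside the parameterization);
  missing cells enter through the likelihood. Time is numeric 0…4 over
  the five assessments (categorical coding available as sensitivity).
  Per-term tests are Wald; optimizer falls back through
  lbfgs/bfgs/powell/nm because boundary fits (σ²_between → 0) can break
  a single method.
- Repeated-measures ANOVAs use the classical sums-of-squares partitions
  (fully-within condition × session; split-plot group × time on
  completers), each effect tested against its own subject-interaction
  error term. The two-level reduction equals the squared paired t
  exactly, and an installed third-party implementation is used as an
  independent cross-check in tests.
- Learning contrast: paired two-tailed t of per-subject means over
  sessions 1–5 vs 6–10, halves averaged over available sessions;
  all-zero differences are a clean null (t = 0), constant non-zero
  differences are flagged degenerate.
- FDR is Benjamini–Hochberg. ARR intervals use the Newcombe hybrid
  score method (Wilson limits per group) — preferable at these group
  sizes; the NNT interval is the reciprocal interval only when the
  whole ARR interval is positive. All p-values are two-tailed.
- The power utility inverts the noncentral-F power function for a given
  partial η²; for η² = 0.16, α = 0.05, power 0.8 it returns 44, inside
  the 42–45 range that standard calculators give depending on design
  assumptions. It is a utility, not an endpoint.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make their verdicts
statistically meaningful at suite scale: 10⁵ samples for OU moments,
600-s calibrations for band quantiles (±1%), 20–25-min calibrations for
model fits, 200 seeded subjects for the learning fraction, 200
replicates of n = 30 cohorts for learning-test power, and 1000
replicates for each type-I calibration (binomial SE ≈ 0.7%, tested
against 0.05 ± 0.02). Every generator takes a seed and reproduces
bit-identical output; the CLI derives all stage seeds from one master
seed via `SeedSequence.spawn`, and artifacts embed the config hash and
seed.

## Known limitations

- Only Pz carries signal; there is no head model, no artifacts
  (ocular, muscle), and no non-stationary line interference, so real
  preprocessing robustness is untested.
- The EEG–amygdala coupling spectrum is a stand-in; real coupling
  weights, their sign structure and SNR are unknown, so learnability
  results bound what this architecture can do under favourable,
  not realistic, coupling.
- The published proprietary weight set is not reproduced (it was never
  printed); the architecture, not the parameters, is what the package
  implements.
- Clinical scores are Gaussian totals with MAR dropout; item-level
  scoring, floor effects and informative attrition are out of scope.
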