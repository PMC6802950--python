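# Methods

This note documents the modelling choices, parameter defaults and known
limitations of `itdcode`, in the order stimulus → neural codes →
psychometrics → synthetic data → numerics.

## Sign and grid conventions

Positive ITD means the left-ear signal leads (the right channel is
delayed); perceptually the image moves toward the left, which maps to
*negative* laterality on the [−1, +1] response scale. The source leaves
the direction of "right" unstated, so the convention is declared once
(in `itdcode.stimuli`) and used everywhere.

The internal-delay grid covers −375 to +375 µs inclusive with 39 taps.
A literal 20 µs step cannot tile 750 µs with both endpoints included;
the endpoints win and the realized step is 750/38 ≈ 19.74 µs. Because
correlogram lags are evaluated exactly in the frequency domain
(cross-spectrum phase rotation), non-integer-sample lags cost nothing at
any sample rate.

## Stimuli

Tokens are uniformly distributed white noise, bandpassed 300–1200 Hz
with a zero-phase Butterworth filter of 36 dB/oct net roll-off: a
3rd-order filter applied forward–backward, each pass contributing
18 dB/oct — the only realization that satisfies "zero phase" and the
stated slope jointly. Corner frequencies are pre-warped so the *net*
response is 3 dB down at 300/1200 Hz. Tokens are 1 s long with 10 ms
squared-cosine ramps, unit RMS before ramping.

ITDs are imposed as exact sub-sample delays by frequency-domain phase
shift (a 20 µs grid is a fractional number of samples at any practical
rate); the shift is circular, which for 1 s noise tokens and ≤ 1 ms
delays has negligible wrap-around effect. Inverse A-weighting is a
zero-phase frequency-sampling filter built from the standard A-curve
rational magnitude (0 dB at 1 kHz); below 150 Hz the gain is clamped to
its 150 Hz value to avoid unbounded low-frequency boost outside the
token's passband.

The behavioral rig's 192 kHz rate is supported but not required; model
simulations default to 16 kHz (≥ 4× the upper band corner, and an order
of magnitude above the periphery's 1.5 kHz low-pass), which keeps the
Monte-Carlo sweeps fast without touching any modelled quantity.

## Labelled-line model

Periphery: 1/3-octave bandpass centred on the 1 kHz best frequency
(891–1122 Hz) at 24 dB/oct net (2nd-order, forward–backward), half-wave
rectification, 1.5 kHz low-pass (2nd-order, forward–backward), then
additive uniform internal noise with mean 5 % of the channel RMS
(U(0, 0.1·RMS) per channel, drawn independently — dichotic).

The correlogram cc(τ) = Σ_t x_L(t)·x_R(t+τ) is affinely rescaled so its
extrema are exactly 300 and 450 spikes/s; the affine constants are fixed
from the 50 dB reference and reused at every level (re-deriving them per
level would not change Pearson correlations or peak positions, both
affine-invariant). The reference correlogram adds U(0, 5) spikes/s
spontaneous discharge on top; degraded correlograms are the pure
cross-correlation of the mixed inputs, as defined.

Level degradation mixes internal noise into each channel,
x̂ = αx + √(1−α²)n. The mixing noise n is zero-centred uniform scaled to
the signal RMS (the energy-preserving convention). Empirically the
decoded-ITD distribution at a matched Pearson target is invariant to the
noise amplitude — the α search absorbs scale — so this choice is purely
a normalization. α is found by bisection (40 iterations) on the achieved
correlation averaged over a fixed bank of 20 noise draws, which makes
the objective monotone in α up to a vanishing Monte-Carlo residue; a
result whose relative error reaches 10 % raises a calibration error
carrying the best α found.

The level → target-r profile is a configurable stand-in (the underlying
coefficients are not reprinted here). The default declines only mildly
with level (0.95 at 10 dB SPL through 1.00 at the 50 dB reference to
0.99 at 70 dB), reflecting that the brainstem coincidence detectors this
emulates are notable for *tolerating* intensity: their delay curves stay
highly correlated with the reference even near threshold. This matters
quantitatively: an argmax decoder applied to a correlogram whose
correlation with the reference falls much below ~0.8 starts to pick
noise peaks, which are symmetric about the midline, so the *mean*
decoded ITD would itself shrink medially — contradicting the
level-invariance that defines the place code. At the reference level the
target r = 1 resolves to α = 1 (no mixing noise); variability there
comes only from the per-repetition stimulus and internal periphery
noise.

`level_sweep` simulates complete trials: each of the (default 100)
repetitions generates a fresh token, imposes the ITD, runs the periphery
and decodes; α is calibrated once per (level, ITD) condition on the
condition's first token. Freshly drawn tokens per repetition make the
residual inward bias of the edge-of-grid argmax (noise can only push an
edge peak inward) common to all levels, so it cancels in the RMS-bias
comparison across levels. The RMS-bias summary uses the highest
simulated level as reference by default.

## Hemifield rate model

Each of the 81 contralateral units is
`rate = spont + s(level)·max(0, intercept + slope·ITD)` with
slope ~ U(0.08, 0.24) spikes/s/µs and intercept ~ U(10, 40) spikes/s —
documented stand-ins chosen to keep driven rates within a plausible
0–150 spikes/s; threshold ~ U(0, 10) dB SPL and spontaneous ~ U(2, 10)
spikes/s as stated. The sigmoid s is a clipped-rescaled logistic whose
5 %/95 % points span the 30 dB dynamic range, snapped to exactly 0 at
threshold and exactly 1 at threshold + 30 dB, so sub-threshold units fire
at precisely their spontaneous rate and saturation is exact. The ipsilateral
population is the exact mirror (rate_ipsi(ITD) = rate_contra(−ITD)),
which makes the hemispheric difference antisymmetric and zero at the
midline by construction. A `level_slope` hook exists in the unit type
but defaults to zero: the original regressions' level dependence is
absorbed by the sigmoid.

The decoder's likelihood pools rates across 0–80 dB SPL in 10 dB steps:
for each (unit, ITD), 20 noisy draws per level (Gaussian observation
noise with variance = rate, floored at 1 — a Poisson-like model) are
summarized by a single Gaussian (mean, variance floored at 1). An
equal-weight Gaussian-mixture-over-levels family is available behind the
same interface; both satisfy the exact self-consistency oracle (a
noise-free observation at a saturating level decodes to its generating
ITD for every grid ITD). Decoding maximizes the summed per-unit log
density over the ITD grid, ties broken toward the midline. Bootstrap
uncertainty resamples units with replacement (default) and redraws
observation noise; resampling of noise only is available. Whether the
original analysis resampled units or trials is unstated; units is the
default because it propagates population-composition uncertainty.

## Psychometric NLME model

The response model is the literal reading of the printed equation,
`A/(1 + e^(−η)) − 0.5` with `A = α_y2·PTA + α_y1·intensity + β_y0` and
`η = α_x2·intensity + α_x1·(ITD − α_x0 − β_x0)`; the alternative
`A·(logistic − 0.5)` reading is available via `form="scaled"` because
the rendered equation is ambiguous about the numerator's scope. ITD and
intensity are z-scored (population SD); PTA enters raw in dB HL, since
only the stimulus parameters are described as normalized.

The equation has no fixed amplitude term, so β_y0 is modelled as
Gaussian with a *free mean* (`amplitude_mean`, the population
lateralization extent) — with a strictly mean-zero β_y0 the predicted
amplitude would be ~0.1 laterality units, degenerate; β_x0 is mean-zero.
Estimation is penalized nonlinear least squares over fixed and random
effects jointly (analytic Jacobian, Levenberg–Marquardt), alternating
with EM-style variance-component updates that include the conditional
spread of the random effects — a Lindstrom–Bates-flavoured
approximation of the marginal likelihood. Starting values come from a
coarse slope scan with the amplitude solved linearly; up to three
seeded, jittered restarts guard against non-convergence, after which a
convergence error carrying the optimization trace is raised. Fits are
deterministic given data and start.

Standard errors are computed from the marginal generalized-least-squares
information Σᵢ XᵢᵀVᵢ⁻¹Xᵢ with Vᵢ = σ²I + ZᵢDZᵢᵀ per listener (Woodbury
inversion) — the conditional (penalized-LS) information would badly
understate the uncertainty of between-listener effects such as the PTA
weight. In 20-seed recovery simulations at the full design the
z-scores (estimate − truth)/SE have spread ≈ 1 per effect, i.e. the SEs
are calibrated. Residual df use the grouped-data convention
`n_obs − n_listeners − n_within_fixed_effects`; of the five fixed
effects, the four ITD/intensity terms vary within listener and PTA is a
between-listener effect, giving 11 000 − 10 − 4 = 10 986 for the full
design. Responses are not clipped during fitting (the touchscreen bound
applies to data generation only), and no multiple-testing correction is
applied. Variance explained is 1 − SS_resid/SS_total with
random-effect-aware predictions.

The training criterion inverts the power function of the Fisher-z test
of ρ = 0. The z statistic's finite-sample mean includes Hotelling's
bias term, atanh(r) + r/(2(n−1)); without it the analytic power is
visibly optimistic at n = 11. The returned criterion at
(n = 11, α = 0.01, power = 0.95) is 0.895, agreeing with the
conventional 0.9 to the reported precision, and a 10 000-rep
bivariate-normal Monte-Carlo simulation of the identical test is the
independent cross-check (realized power ≈ 0.95). A one-sided variant is
exposed; two-sided is the default.

## Synthetic behavioral data

The generator reproduces the testing design exactly: per listener,
20 blocks in each of which all 55 (ITD, SL) combinations appear once in
random order, 11 000 trials in total. Responses are the model mean plus
N(0, σ_resid); defaults σ_resid = 0.1, σ_x0 = 0.1 (normalized-ITD
units), σ_y0 = 0.15 (laterality units), amplitude mean 1.0, and fixed
effects echoing the flat-spectrum study condition (α_x0 = 0.06,
α_x1 = 2.45, α_x2 = 0.02, α_y1 = 0.05, α_y2 = 0.01). Listener PTAs are
drawn once from U(0, 25) dB HL — the study's inclusion criterion bounds
them but the individual values are not reprinted, so this is a labelled
assumption. All randomness flows from one PCG64 seed; identical seeds
give bit-identical datasets.

What the generator deliberately does *not* emulate: response clipping is
off by default (the hard bound biases recovery; switch `clip_responses`
for realism), there is no lapse/attention process, no learning across
blocks, no reaction-time structure, and the adaptive staircase that set
sensation levels is documented only as design metadata. Passing
recovery tests therefore show that the estimator is consistent and its
SEs calibrated *under the model's own assumptions*, not that real
listeners satisfy them.

The model-comparison generator realizes each code's behavioral
signature: the rate-code dataset has amplitude growing with SL
(α_y1 > 0); the place-code dataset has level-independent amplitude
(α_y1 = α_x2 = 0) with response noise scaled up by 1 + 1.5·(relative
distance below the top SL), emulating decode variability that grows
toward threshold.

## Pipeline and problem sizes

`reproduce_fig1` runs 100 labelled-line repetitions per condition over
11 ITDs × 7 levels (≈ 15 s at 16 kHz) and 100 bootstrap resamples per
condition over 11 ITDs × 9 levels for the rate code (≈ 1 s);
`run_synthetic_study` generates and fits both experiments (≈ 2 s). All
acceptance-grade checks run on the CSV/JSON artifacts; plots are
secondary. Every output directory carries a manifest with the seed and
a configuration hash, and reruns are byte-identical.

## Known limitations

- Single best frequency (1 kHz) for the labelled line; no across-channel
  integration.
- The level → r profile and the IC unit coefficient distributions are
  stand-ins; conclusions about *machinery* (calibration, decoding, bias
  structure) are robust to them, absolute decoded values are not.
- The Gaussian pooled likelihood treats level as marginalized rather
  than estimated; an observer that jointly infers (ITD, level) would be
  less medially biased at intermediate levels.
- The NLME estimator targets point estimates and Wald inference; it is
  not a full marginal-likelihood maximizer, and variance components are
  EM-updated rather than profiled (adequate here: truth recovery and SE
  calibration are verified in the test suite).
- Interaural level differences, spectral cues and free-field acoustics
  are out of scope throughout.
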