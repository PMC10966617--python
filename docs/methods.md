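# Methods

## The recovery model

Postictal EEG restoration is summarized by the normalized alpha–delta ratio
ADR = (Pα − Pδ)/(Pα + Pδ) per minute since seizure offset and modelled as a
lag-reparameterized Gompertz curve

    f(t) = (U − A) + A·exp(−exp(1 + (λ − t)/τ)),

chosen because it realizes exactly the quantities of clinical interest: a
lower asymptote `U − A` (the suppressed immediately-postictal state, near −1),
an upper asymptote `U` (the level approached within the first hour, typically
still below the pre-ictal baseline), an initial lag `λ` before recovery
accelerates, and a time constant `τ` governing the transition from rapid to
reduced growth. The derivative

    df/dt = (A/τ)·exp(u − e^u),  u = 1 + (λ − t)/τ,

has a unique maximum at u = 0, giving the moment of fastest restoration
analytically: `T_max = λ + τ` (cross-checked in the fitter against a
brute-force argmax on a 0.01-min grid). `f` is bounded in [U − A, U],
non-decreasing, with a single inflection. The functional form is a pluggable
strategy of `SigmoidRecoveryModel` (a `(f, df/dt, argmax)` triple), so an
alternative sigmoid can be swapped in without touching the fitting, QC or
feature-extraction machinery.

### Fitting

Nonlinear least squares (trust-region reflective, `scipy.optimize
.least_squares`) with bounds A ∈ (0, 2.5], λ ∈ [0, D], τ ∈ [0.5, 60] min,
U ∈ [−1, 1.2], where D is the span of the recorded series (the postictal
duration is taken as the recorded span, not a free parameter). Five
deterministic starts derived from order statistics of the series (U₀ = max,
A₀ = range, λ₀ from the first 10%-rise minute and fixed alternatives, τ₀ from
the half-rise minute); the best-SSE solution is kept. Missing minute bins are
dropped from the loss, never imputed. Sessions with fewer than 40 valid
minutes are excluded. Goodness of fit is R² on the non-missing minutes with
an inclusive QC gate at 0.7; boundary-argmax fits are retained but flagged.
A 30-replicate random-restart audit found no case in which the five
deterministic starts missed the global optimum.

### Estimation precision

At a per-minute noise of σ = 0.05 ADR units on 60 bins of the exemplar curve
(A = 1.0, λ = 5.9, τ = 21, U = 0.1), the Fisher information bounds
sd(T̂_max) at ≈ 1.9 min, i.e. a median absolute error ≈ 1.3 min for any
(near-)unbiased estimator; the least-squares fit attains this bound
(1000-replicate median 1.30 min). Extraction is therefore
information-limited, not optimizer-limited, at that noise level; the
pipeline's actual per-minute noise on clean synthetic EEG is ~0.015–0.05,
where T_max errors are well under a minute.

## Spectral estimation

Welch windows are the 5-s artifact-free segments themselves, advancing 2.5 s
(50% overlap), one Hann-tapered, density-scaled periodogram each (0.2 Hz
resolution). Band powers are trapezoidal integrals on the native grid — no
interpolation — over 0.5–4 Hz (delta) and 8–13 Hz (alpha). Per window, PSDs
are reduced by the frequency-wise median across non-rejected channels (robust
to one bad electrode), then band powers, then the ADR; per-window ADRs are
averaged within minute bins [k, k+1). A bin with fewer than 50% of its
nominal windows valid is missing. The alternative order — average band powers
over the minute, then one ADR — is exposed via `mode="power_first"`. The
channel-median PSD of chi²-distributed noise underestimates mean power by
~ln 2; this cancels exactly in the ratio, which is also invariant under any
positive signal gain. ADR with zero total power is treated as missing (never
−1 or 0), and the division uses no epsilon so the closed-form identities hold
exactly.

## Preprocessing

First-order Butterworth band-pass 0.5–30 Hz, applied forward–backward: the
zero-phase choice avoids shifting band-power timing across minute-bin edges.
Epochs are a contiguous 5-s grid from seizure offset (trailing partial epoch
dropped). Artifact screening is an automated surrogate for visual review:
a channel-epoch is flagged above 200 µV peak amplitude or below 0.1 µV peak
to peak (detached electrode), and channels flagged in > 50% of epochs are
rejected wholesale; all thresholds are configurable. Generalized suppression
is detected on the channel-median of 0.5-s sliding-window RMS: maximal
intervals < 10 µV lasting ≥ 2 s. Annotated seizure markers always take
precedence; suppression detection only proposes an offset when annotations
are missing. All postictal times are minutes relative to seizure offset
(offset = 0.0) with half-open intervals.

## Reorientation scoring

Questions arrive on a 5-min grid (first assessment 5 min after offset by
default — the assessment cadence is stated but not its origin, so the origin
is configurable). Two-question domains average their two first-correct times;
a domain disoriented at baseline is excluded; a question never answered
within the observation window makes the domain ROT missing (censored,
logged) rather than imputed at the window edge. Domain order uses non-strict
comparison so simultaneous recovery does not falsify the classic
person ≤ place ≤ time sequence; under exchangeable continuous domain times
the classic-order rate is 1/6. Domain comparisons are paired Wilcoxon
signed-rank tests on per-subject medians across sessions (a session-level
pairing can be run by passing session rows instead).

## Mixed models

One model per domain: ROT (min) ~ T_max + A + τ + charge + seizure duration
+ midazolam + placement + session number + sex + age, with by-subject random
intercept and random T_max slope, REML estimation (statsmodels `MixedLM`).
Continuous predictors are z-scored — the coefficients are minutes per SD
(binary: minutes per level; references: right-unilateral placement, no
midazolam, female) — since effects on incommensurate raw units (mC, s, years)
are otherwise incomparable; `standardize=False` gives raw units. Confidence
intervals and p-values use a Wald t approximation with df = n_obs − n_fixed
(deliberately not Satterthwaite). A random-effects covariance with an
eigenvalue below 2% of the residual variance is treated as singular and the
model downgraded to intercept-only (logged); statsmodels rarely returns an
exact boundary zero, so a relative threshold stands in for lme4-style
`isSingular`. Data with (numerically) zero residual variance degenerate to
ordinary least squares, reported as such — REML is undefined there and the
GLS solution equals OLS. Residual and random-effect Shapiro–Wilk checks
attach as advisory diagnostics, never hard failures. No multiple-testing
correction is applied (α = 0.05 per coefficient), matching standard practice
for this design. VIF is computed per predictor from auxiliary regressions on
the fixed-effects design; ≥ 5 is flagged, perfect collinearity reports ∞.

## The synthetic-data generator

The generator emulates the repeated-measures structure the analysis assumes,
with defaults set to the study conditions: 32 subjects, ~8.5 sessions each
(272 sessions), seizure duration 58.5 ± 29.9 s, charge 349.3 ± 162.4 mC,
midazolam in 37% of sessions, ~66% bilateral placement, 56% female, age
54.2 ± 13.9 y; recovery-curve truths A ~ N(0.33, 0.27²) (truncated > 0),
λ ~ N(6.3, 3.1²), lower asymptote near −0.95, and mean T_max 29.4 min.

**EEG synthesis.** Each channel is a sum of two independent unit-variance
band-limited Gaussian processes with time-varying gains
g²α(t) = P(1 + f(t))/2 and g²δ(t) = P(1 − f(t))/2 (total band power
P = 900 µV², ~30 µV RMS), so the instantaneous band-power balance equals the
programmed curve exactly in expectation and the ground truth is analytic.
Channels share the gain laws with independent noise, so the channel-median
PSD equals the single-channel expectation. The processes are synthesized by
FFT brick-wall filtering, inset 0.4 Hz (the Hann main-lobe half-width of a
5-s window) from the nominal band edges so the programmed power falls
entirely inside the analysis band integrals; without the inset, ~6% of delta
power leaks past the integration edges and absolute band-power fidelity
cannot be guaranteed at the 10% level. Artifacts are injected as 1-s, 500 µV
transients on a random single channel at 2/min by default, recorded in
metadata, to exercise the screening deterministically. Ictal segments are a
3 Hz harmonic spike-wave surrogate followed by a < 10 µV suppression tail.

**Clinical synthesis.** Latent domain ROT = intercept + β·z(covariates) +
subject intercept + subject slope · z(T_max) + Gaussian residual (SD 8 min);
each question adds N(0, 2²) scatter, is floored at the first assessment, and
is observed as the smallest grid time at or after its latent time. Gaussian
residuals are a modelling assumption adopted for the generator (nothing
stronger is claimed for real data). The generating β are the reported
per-domain coefficients, with unreported (non-significant) effects set to 0;
the person-domain time-constant coefficient is taken as +0.7 (the midpoint of
its interval — the printed point estimate is inconsistent with its own CI).
Random-effect SDs (intercept 5 min, T_max slope 2 min) and the residual SD
are choices at clinically plausible magnitudes; the slope SD is large enough
that the full random-effects specification is identifiable at study scale.
The reorientation observation window (120 min) deliberately exceeds the 1-h
EEG window: assessments continue until the patient reorients, and truncating
at 60 min would differentially censor high-midazolam sessions and attenuate
the largest coefficients. τ is drawn N(23.1, 4²): its dispersion is not
reported, and because T_max ≡ λ + τ, a τ SD matching SD(T_max) = 8.6 with
SD(λ) = 3.1 would force corr(T_max, τ) ≈ 0.93 — a design that fails the
analysis's own VIF < 5 collinearity screen for any λ–τ coupling. The chosen
value keeps corr(T_max, τ) ≈ 0.79 (VIF ≈ 3) at the cost of a generated
SD(T_max) ≈ 5.1 instead of 8.6; the screen is honored over the descriptive
dispersion.

**What the generator does not emulate** (so what passing tests do not show
about real data): realistic EEG morphology (spindles, blinks, anesthesia
burst-suppression), non-Gaussian or heteroscedastic ROT residuals, informative
missingness (artifacts and baseline disorientation are random here), placement
switching within a course, and drug-arm effects. Determinism: one root seed,
split per subject/session via `SeedSequence`, so identical configs reproduce
identical outputs on all paths, and partial re-runs stay reproducible.

## Problem sizes used in the checks

The test suite exercises the full raw-EEG path on 50 sessions (25 subjects ×
2) at the default 12-channel, 60-min, 128-Hz conditions, and the mixed-model
coverage and coefficient-recovery checks on 200 simulated studies at full
study scale; `scripts/acceptance.py` likewise uses 200 studies. Smaller
configurations in unit tests (e.g. 16 × 4 sessions) are explicit parameters
of those tests, not changed defaults.

## Known limitations

- EDF output is minimal EDF (16-bit, 1-s records, integer sampling rates);
  EDF+ annotations are not written. Reading goes through MNE.
- The exact printed algebraic form of the recovery curve in the source
  literature is typeset as an image; the lag-Gompertz form implemented here
  reproduces every textual parameter description and the printed λ/T_max
  arithmetic, and the model slot is pluggable should a variant be preferred.
- T_max extraction at high per-minute noise is information-limited (see
  above); QC-passing fits can still carry ~1–2 min of T_max uncertainty at
  σ = 0.05.
- The mixed models assume the scored ROT is the outcome on its observed
  (grid-censored) scale, as in the original analysis; no interval-censoring
  likelihood is used.
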