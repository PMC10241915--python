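# Methods

## Signal processing

Raw surface EMG (2000 Hz, acquisition band 10–500 Hz) is turned into a
linear envelope by a zero-phase 4th-order Butterworth high-pass at 3 Hz,
full-wave rectification, and a zero-phase 4th-order Butterworth low-pass at
2 Hz, clipped at zero. The nominal processing band extends to 1000 Hz, which
equals the Nyquist frequency at this sampling rate, so the upper edge is
unrealizable and only the high-pass is applied; the acquisition hardware
band already limits the spectrum. Zero-phase (forward–backward) filtering is
used so the envelope stays aligned with the video-coded event timestamps —
the stated cutoffs name no order or phase behavior, so these are package
choices.

Phase segmentation uses half-open intervals `[start, end)` with sample index
`floor(t × rate)`, so the reaching/holding/transport segments of a marble
tile `[reach_start, place)` exactly. Each segment is linearly interpolated
onto 100 equally spaced points (endpoints preserved; the operation is
idempotent on 100-point inputs). Session-level curves are the point-wise
mean across the 15 marbles (a median is available as a robustness switch);
whether per-phase curves should be averaged across marbles or computed on a
concatenated session signal is not externally fixed, and marble-averaging is
the default because it weighs every marble equally regardless of duration.
The three phase curves concatenate, in fixed order, into a 300-point
full-trial curve.

MVC normalization: the reference is the maximum of a 500 ms sliding mean of
the envelope over a ~10 s maximal-contraction block — a windowed statistic
resists single-sample spikes, since the source procedure only states that
maximal contractions are used for normalization. The mean contraction
amplitude of a session is the envelope mean over the union of per-marble
reach-to-place intervals divided by the MVC reference; the envelope chain is
amplitude-homogeneous, so this quantity is scale-free.

## Similarity metric

The Linear Fit Method regresses one curve on the other by ordinary least
squares and reports the coefficient of determination R², which for a simple
regression with intercept equals the squared Pearson correlation. The
implementation computes it from centered cross- and auto-moments, which
makes `lfm_similarity(c, c)` exactly 1.0 in floating point, and makes the
score symmetric and invariant under affine transforms of either curve.
A flat (zero-variance) curve raises an error rather than scoring 0: a flat
envelope indicates a pipeline fault, not zero similarity. Whether a curve is
regressor or response is irrelevant under this definition; slope and
intercept are not part of the score.

## Behavioral scores

GA counts every chopstick–marble contact, including the successful grasp
(an ideal trial scores the number of marbles) and re-grasp contacts after a
drop. FL counts drops during transport. Per-marble phase durations exclude
failure time: reaching runs to the *first* contact, holding from the
successful grasp to the first lifting, and transport over the final
successful lift-to-place interval, with aborted transports excluded; MD is
the sum of the three phase means, making it independent of GA and FL by
construction. Baseline correction subtracts each subject's S1 score;
standardized improvement is Δ = (S6 − S1)/(S6 + S1), bounded in [−1, 1] and
negative when an error or duration metric improves. Similarity is already a
bounded fraction, so its standardized gain is the plain difference S6 − S1.

## Statistics

Two-sample t-tests pool variances by default (between-group df
n1 + n2 − 2 = 70 for full cohorts), Welch by flag. The mixed
repeated-measures ANOVA uses the classical split-plot decomposition —
between-subject SS into Group and subject-within-group error, within-subject
SS into Time, Time×Group and residual — with no sphericity correction by
default (Time df (m−1, (N−g)(m−1)), e.g. (5, 350) for 72 × 6) and
Greenhouse–Geisser by flag; it accepts unequal group sizes, which arise when
unstable channels are excluded (a subject is dropped only from that muscle's
analyses). Standardized regression β is computed on z-scored variables, so
β² = R² for a simple regression. The 9-cell (muscle × phase) regression
battery is corrected with Benjamini–Hochberg step-up FDR at q = 0.05
(Benjamini–Yekutieli by flag); the multiple regression enters all 9
similarity gains with an intercept on df (9, 26) at n = 36. Degenerate
inputs (zero-variance groups, zero-variance paired differences) return
t = 0, p = 1 when the mean difference is zero rather than NaN. All tests are
two-sided at α = 0.05.

## Synthetic-study generator

**Convergence model.** Each subject owns an idiosyncratic activation curve
per (muscle, phase) — a baseline plus 2–4 Gaussian bumps, the same family as
the expert templates. The envelope produced at session *s* is the convex
combination `w_s·template + (1−w_s)·idiosyncratic + ε`, clipped at zero, so
the mixing weight maps monotonically onto the measured LFM R². Per-marble
noise ε is Gaussian with sd `envelope_noise_sd` (default 0.1) times the
template mean. Group schedules of `w_s` are the central dial: the defaults
(AOT 0.330 → 0.370 linear, CTRL flat at 0.330) are calibrated so the
study-mean full-trial R² is ≈ 0.36 at S1 with an AOT gain of ≈ +0.05 by S6
and a flat control group — the reported group-level profile of the emulated
study. Subjects differ in a lognormal convergence gain (sd 0.4) scaling the
rise of their schedule, and the effective weight wobbles between sessions
(sd 0.05, shared across the phases of a muscle) to emulate electrode and
day-level state; without that wobble, paired S1-vs-S6 t statistics come out
implausibly large (|t| ≈ 12 instead of ≈ 2–3).

**Raw traces.** Raw EMG is band-limited Gaussian noise (10–500 Hz)
amplitude-modulated by the time-stretched envelope. The carrier is
gain-normalized by its own slow (2 Hz) amplitude profile and scaled to unit
mean absolute value, so the trace's true linear envelope equals the
programmed modulation; without the normalization, rectified Gaussian noise
leaks ~10 % multiplicative noise into every recovered envelope. The
processing chain recovers a noise-free programmed envelope with LFM R² ≥ 0.9
for phases of roughly 1.5 s and longer; much shorter phases are smoothed by
the 2 Hz envelope filter itself, a resolution limit of the chain, not of the
generator. MVC blocks are 10 s with a smooth 3 s plateau at the subject's
programmed maximum.

**Behavior.** Extra grasping attempts follow a negative-binomial count model
(dispersion 3, giving S1 GA ≈ 51 with SD ≈ 22 — far over-dispersed relative
to Poisson, matching the emulated baseline) whose mean decays log-linearly
across sessions with group-specific decay (AOT 0.25, CTRL 0.12, so the AOT
decrease in GA is roughly double). Drops are rare per-marble Bernoulli
events (≈ 1.2 per session, mildly decaying); phase durations are lognormally
jittered around session-decaying means summing to ≈ 3.9 s at S1. Per-subject
baseline and learning-rate multipliers are lognormal, keeping rates
positive. Trials exceeding the 3-minute limit are resampled. With
`behavior_coupling` λ > 0, a subject's GA decay scales as (convergence
gain)^λ, coupling behavioral improvement to similarity gain; with
`convergence_cells` set, the weight schedule rises only in the designated
(muscle, phase) cells — together these create the "local" similarity →
improvement structure that the regression battery is meant to detect.

**Fidelities and problem sizes.** Two generator routes exist.
`generate_study` writes a full on-disk bundle with raw 2000 Hz traces and is
used at small cohort sizes (a full 72-subject raw bundle would be several
gigabytes of CSV); `simulate_study` produces session-level curves in memory
and is the route for replicate (Monte-Carlo) studies. At the envelope
fidelity, per-marble noise enters through its across-marble average
(sd/√15) and the session curve is clipped at zero once — equivalent to
averaging individually clipped marble curves except for rare negative
excursions, which are negligible at the calibrated noise. Monte-Carlo checks
use 50 replicate studies at full scale (convergence recovery), 500
replicates at a reduced 8+8 cohort (null calibration of every test), and 100
replicates at full scale (regression locality); these sizes keep each check
to tens of seconds while leaving the binomial acceptance regions meaningful.

**Randomness.** One root seed sequence per study, spawned hierarchically per
subject, makes every artifact bit-reproducible for a fixed config and seed;
identical configs produce byte-identical on-disk bundles.

## What the generator does not emulate

Real EMG contains motor-unit structure, movement artifacts, crosstalk
between adjacent muscles, and non-stationary noise; the generator's
amplitude-modulated Gaussian carrier exercises rectification and filtering
realistically but carries none of that structure. Video-coded timestamps are
taken as ground truth (no annotation error model). Observation periods carry
no data. Passing tests therefore demonstrate that the pipeline measures
convergence correctly *when the generative assumptions hold*, and that its
tests are calibrated under the generator's null — not that the specific
effect sizes would replicate in new human data.

## Known limitations

- The envelope fidelity bypasses the raw-signal chain; agreement between the
  two routes is checked at small scale only.
- The mixed ANOVA requires complete within-subject data (subjects missing a
  session are rejected, not imputed).
- With heavy-tailed count outcomes at very small cohorts (n = 8), t-tests
  are mildly conservative (empirical type-I error ≈ 0.04 at α = 0.05).
- The standardized improvement Δ is undefined when S1 + S6 = 0 (flagged as
  missing, excluded from regressions).
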