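# Methods

## The experiment being modelled

A participant swallows 5 ml water boluses while holding one of three
head positions (chin-down, chin-neutral, chin-up, ±15° from neutral).
Sessions consist of four blocks; within a block the participant holds
each position for one contiguous segment of eight swallows, one every
38 s (the bolus pump runs on a 35 s cadence and delivers over 3 s; both
cadences are independent parameters because instrument cadence and
swallow cadence need not coincide). Blocks are separated by 210 s rests.
A default session therefore contains 96 swallows, 32 per position.
Cortical activity is measured with continuous-wave fNIRS at 790/830 nm
and 50 Hz over ten 3 cm emitter–detector pairs (five per hemisphere:
premotor, 2× precentral, 2× postcentral); swallow timing is measured
with a laryngeal accelerometer at 4 kHz gated by respiratory
plethysmography at 1 kHz.

## Synthetic sessions

The generator is a forward model of everything the analysis inverts.

**Hemodynamic response.** A single gamma-variate kernel
h(t) = (t/t_p)^a · exp(a(1 − t/t_p)) with unit peak at t_p = 5 s; the
shape a is solved in closed form so that h equals 5% of peak at the
return time t_r = 25 s (a = ln 0.05 / (ln r + 1 − r), r = t_r/t_p).
This respects the physiological landmarks (peak 4–6 s, return to
baseline 20–30 s) without asserting a particular biophysical form.
Per-swallow ΔHbO amplitudes default to 0.6 / 0.9 / 1.4 µM for
down / neutral / up — the same order of magnitude as published
median-window summaries for this task. ΔHbR is a fixed −1/3 of the
ΔHbO event component, a standard adult ratio; only ΔHbO is analysed
downstream.

**Noise.** Cardiac (1.1 Hz), respiratory (0.25 Hz) and Mayer-wave
(0.1 Hz) oscillations with random phases; white sensor noise; random-walk
drift; Laplacian single-sample motion spikes and step shifts that
persist to the end of the block; a shared superficial (scalp) component
that is the only signal in the 0.8 cm short-separation channels; and
band-limited (0.01–0.5 Hz) low-frequency hemodynamic fluctuations —
one component shared across cortical channels (sd 0.8 µM) and one
independent per channel (sd 0.3 µM), both carrying the −1/3 HbR ratio
so they pass CBSI the way real hemodynamics do. Without the in-band
fluctuations the synthetic baselines are far quieter than real
recordings, whose between-participant summary spreads are ≈1 µM.
Short-separation channels are simulated even though a minimal 10-pair
montage may not include them physically, so the regression stage is
exercisable; sessions can be generated without them, in which case the
stage skips with a warning.

**Accelerometer.** Gaussian movement noise whose instantaneous amplitude
is modulated per swallow: during the 0.6 s before onset the amplitude
decays exponentially (rate 20 s⁻¹, floor 10⁻⁴) — laryngeal quiescence
during the swallow apnea — and from the onset a gamma-shaped movement
burst rises to 10× baseline within 0.25 s and subsides by 1 s. The
rectified, Bartlett-smoothed envelope therefore has its trough at the
true onset followed by a steep rise, which is the waveform feature the
detector's derivative zero-crossing keys on. The decay rate matters:
the envelope-derivative noise after a 201-tap smoother at 4 kHz has a
standard deviation of a few baseline-sd per second, and the
deterministic downslope must dominate it throughout the pre-onset
window or noise-driven crossings fire early. At the default shape the
detector recovers >99% of onsets within ±0.2 s.

**Respiration.** A 0.25 Hz sinusoid whose phase clock freezes during
each apnea window ([onset − 0.5 s, onset + 1.0 s]), flattening the
trace at its current value, plus 0.5% sensor noise. A zero-amplitude
signal degenerates to a constant record, which the apnea detector
reports as one full-length apnea with a warning.

**Cohort-level generator.** Inference simulations need many cohorts of
26 participants; simulating ~70 min of multi-rate signal per participant
for those is pointless. `simulate_cohort_hdr` draws the per-cell
median-window ΔHbO summaries directly: cell mean = position amplitude
(interpreted on the summary scale, where published task values are
0.5–1.5 µM), plus a participant random intercept (sd 0.5 µM) and
residual noise (sd 1.0 µM), matching the ≈1.1 µM per-cell spread of
real data. The signal-level generator remains the per-session forward
model and is what the detection, optics and epoching stages are tested
on.

## Onset detection

Apneas are maximal intervals where |smoothed d(resp)/dt| stays below
0.1× the record's median absolute derivative for ≥0.75 s (0.2 s
triangular smoothing of the derivative). The accelerometer is
rectified, smoothed with a 201-tap unit-sum Bartlett window (zero lag,
reflected edges, centre weight 2/(N+1)), and differentiated with the
central first difference. Within each apnea the first derivative
sample that crosses from ≤0 to >0 and stays positive for 25 samples is
the onset; one onset per apnea, and onsets within 2 s of an earlier one
are discarded. The persistence requirement suppresses the dense
zero-crossing chatter of a rectified-noise derivative. Every step is
threshold-free in amplitude, so detection is invariant to positive
rescaling of the accelerometer. Onsets are labelled by the position
segment containing them ([start, end) intervals); onsets in inter-block
rests are kept but flagged unverified and excluded downstream (the
original workflow's human/video verification is replaced by ground-truth
comparison in synthetic mode and a `verified` flag in the data model).

## Optical processing

- ΔOD(t) = −ln(I(t)/Ī) per channel and wavelength, with Ī the record
  mean. Concentrations are therefore referenced to the record mean;
  absolute offsets are not recoverable (and are irrelevant after
  baseline normalisation).
- Band-pass: Butterworth order 3, applied forward–backward
  (zero phase, squared magnitude). At 1.1 Hz the two-pass response is
  ≈−42 dB; at 0.1 Hz ≈1.000. Spectral assertions in tests trim 1/low
  = 100 s from the record edges; data passed downstream are not
  trimmed.
- Beer-Lambert inversion solves the 2×2 system per sample with
  extinction coefficients (cm⁻¹ mM⁻¹) at 790/830 nm from the standard
  in-vitro hemoglobin compilation and DPF = 6.0 at both wavelengths
  (common adult default); all three are configuration, not constants,
  and ill-conditioned systems (condition number ≥10⁶) are rejected with
  the condition number in the message.
- Short-separation regression subtracts β·short from each long channel
  per chromophore, β being the full-record least-squares coefficient
  ("static" regression; a sliding-window variant would be a
  configuration extension, not the default). Output is orthogonal to
  the regressor; zero-variance regressors are skipped with a warning.
- CBSI: α = sd(HbO)/sd(HbR), HbO* = (HbO − α·HbR)/2, HbR* = −HbO*/α.
  The output pair is exactly anti-correlated; common-mode (motion)
  content is annihilated; a signal already satisfying the assumed
  anti-correlation is a fixed point.

Stage order is OD → band-pass → Beer-Lambert → short-sep → CBSI.
With noise off, the forward model composed with this chain reproduces
injected concentrations (mean-referenced) to <1e−6 µM without the
band-pass, and event-locked amplitudes within the 15% passband
distortion budget with it.

## Epoching and summaries

Epochs span [−10, +20] s around onset (1501 samples at 50 Hz; +30 s is
available for plotting). Baseline is the half-open window [−10, 0) —
the onset sample belongs to neither baseline nor statistic window — and
is subtracted per epoch and channel, making the baseline mean exactly
zero. The response statistic is the median over the closed window
[5, 20] s, computed per channel per event; "across all channels" is
resolved as per-channel median over time, then arithmetic mean across
each hemisphere's channels, consistent with averaging hemisphere
channels separately. Timing groups use within-segment ordinals: first
= {1, 2}, last = {7, 8}, all = every swallow. Grand averages report the
pointwise mean per position with the across-event standard error as the
dispersion band.

**Baseline-consistency check.** Per position, participant-level mean
baselines of the first vs last swallows are compared with a paired
two-sided t-test, without multiplicity correction; drift-free data pass
(degenerate zero-variance case counts as a pass), while an injected
5 µM drift is detected essentially always at n = 26. One caveat the
simulations expose: the 0.01 Hz high-pass leaves a small settling
offset (≈0.02–0.05 µM, largest for the largest response amplitude)
between the first and last baselines of a segment, because the filter's
response-train undershoot has not equilibrated at segment start. This
is a property of the processing chain, not an injected drift; with
realistic baseline noise it is usually invisible to the test at modest
cohort sizes, but a sufficiently large, quiet cohort will flag it.

## Inference

The mixed model is fitted by REML (statsmodels `MixedLM`) with a
participant random intercept; candidate fixed effects are position,
timing (first/last only — the "all" rows are descriptive), hemisphere
and their three two-way interactions (no three-way term). Term
significance uses Wald chi-square tests on each term's coefficient
block; the degrees-of-freedom treatment is the large-sample normal
approximation, recorded in the fit log (a Satterthwaite approximation
is not available in the fitting backend; for this design — 312
observations, 26 groups — the approximations agree closely, and the
fit is cross-checked against lme4 in the test suite). Backward
elimination removes the removable term with the largest p-value above
α = .05, never removing a main effect while an interaction containing
it remains, and refits until all retained terms are significant; a
likelihood-ratio criterion is available via configuration. Elimination
is deterministic given the data.

Tukey contrasts compare estimated marginal means — model predictions
averaged over a balanced grid of the other retained factors — for all
position pairs, with family-wise adjustment from the studentized-range
distribution at residual degrees of freedom (n_obs − k_fe); for a
two-level family this reduces exactly to the unadjusted t-test. On
balanced designs the mixed model's fixed effects coincide with ordinary
least squares regardless of the intercept variance, which the tests use
as an oracle.

Published group-level numbers for this paradigm (cell means, contrast
magnitudes) derive from participant data that are not available, and
the printed pairwise differences are not mutually consistent with the
cell means; they are treated as directional anchors only. What the
simulations verify is the structure: backward elimination retains head
position and the chin-up vs chin-down contrast is positive and
significant in ≥80% of seeded cohorts at the default effect sizes,
while a null generator retains position at roughly the nominal α rate.

## Problem sizes and limitations

Tests run reduced protocols (1–2 blocks) where the full session adds
nothing; the acceptance script and the protocol-fidelity test use the
complete default session (~72 min of simulated signal, ~10 s to
generate and detect). Inference simulations use 50 cohorts of 26
participants at the summary level.

Known limitations: the generator has no optode-coupling or anatomical
light-transport model and no systematic inter-participant response
heterogeneity at the signal level (the cohort generator carries that
role); motion shifts are idealised steps; respiratory influence on the
fNIRS channels is sinusoidal rather than coupled to the simulated
breathing trace; and passing tests on synthetic sessions demonstrate
correctness of the inversion chain under the stated assumptions, not
performance on real recordings with uncooperative artifacts.
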