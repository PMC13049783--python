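# Methods

`cpet-acoustics` estimates two exercise-capacity indices from tracheal
breath sounds recorded at the suprasternal notch during a stepwise
cycle-ergometer cardiopulmonary exercise test (CPET): the ventilatory
anaerobic threshold (AT) and oxygen uptake (VO2 / VO2peak).  This note
documents the models, the numerical choices, and what the built-in
simulator does and does not establish.

## Physiological model

At the anaerobic threshold, buffering of lactic acid releases excess CO2;
minute ventilation (VE), which tracks CO2 output, therefore accelerates:
VE as a function of time (or VO2) is approximately two-segment linear with
a slope increase at the AT.  Tracheal sound intensity — the average
acoustic power of a breath — is approximately proportional to airflow, so
the ventilatory breakpoint reappears as a breakpoint in the sound-intensity
trace.  That chain of proportionalities is the entire basis of the method:
the acoustic AT estimate is the knee of a continuous two-segment
least-squares fit to the intensity trace over the exercise phase.

The reference AT uses the ventilatory-equivalents criterion: VE/VO2
reaches its minimum (nadir) at the AT while VE/VCO2 is still flat or
decreasing (VE/VCO2 falls until the later respiratory-compensation point,
which this package does not model).

## Acoustic processing chain

1. **Band-pass** 100–3000 Hz (the tracheal breath-sound band), order-4
   Butterworth applied forward–backward.  Zero-phase filtering preserves
   breath-onset timing.
2. **Downsample** to 6000 Hz (polyphase, rational-ratio approximation to
   within 1e-6; output length `round(n·target/rate)`).
3. **Ambient denoising**: short-time Fourier transform (50 ms Hann frames,
   75 % overlap), per-frequency stationary noise floor estimated as the
   10th percentile of power over time rescaled by `1/−ln(0.9)` (a low
   quantile of exponentially distributed power underestimates its mean by
   exactly that factor), soft spectral subtraction
   `g = sqrt(max(floor², 1 − 2·N/|X|²))` with floor gain 0.05.  Gains never
   exceed one, so no frame gains energy.
4. **Spike removal**: short-time RMS envelope (100 ms windows) against a
   rolling median + 5·scale threshold over a 10 s baseline.  The scale is
   the larger of 1.4826·MAD and the upper-quartile spread: on a strongly
   bimodal envelope (bursts/silence near 50 % duty) the MAD alone collapses
   to zero and would flag every burst; with the floor the detector degrades
   to a no-op instead.  The baseline must span several breaths — on a
   window comparable to one breath the median sits at the silence floor.
   Flagged runs are linearly interpolated.

**Which signal feeds which stage.**  Breath-phase detection runs on the
denoised signal: what matters there is the burst's margin over the noise
floor.  The features are integrated on the band-passed, despiked but *not*
denoised signal: spectral suppression is level-dependent (weak bursts lose
proportionally more energy than loud ones), which bends the feature trace
that the breakpoint fit assumes piecewise-linear, whereas stationary
ambient noise adds only a constant offset to mean-power intensity, which
the fit absorbs into its intercept.

## Breath segmentation

Sound bursts (one inspiratory and one expiratory per breath) are detected
by dual-threshold hysteresis on the 10·log10 short-time power envelope
(50 ms frames, 25 ms hop): a phase opens above baseline + 6 dB and closes
below baseline + 3 dB, where the baseline is a rolling 20th percentile over
15 s.  Because the baseline adapts, segmentation is invariant to global
gain.  Phases shorter than 150 ms are dropped; gaps shorter than 100 ms are
merged.

Phases are paired into breath cycles by relative gap length: within a
breath the inspiratory–expiratory pause is shorter than the pause between
breaths, so a phase is paired with its successor when their gap is no
longer than the following gap (plus a 100 ms tie tolerance — measured gaps
are quantized to the envelope hop).  When one phase of a breath is missed
the rule emits a single-phase cycle and stays in register.  Cycle
onset-to-onset intervals define the instantaneous breath duration.

## Features

Per breath *b* (span = onset to next onset, so every sample belongs to
exactly one breath and the result does not depend on how deeply the
hysteresis thresholds cut into the burst ramps):

* **sound energy** `E_b = Σ x[n]²` over the span (unitless; the device
  gain is uncalibrated, so all energies are relative);
* **sound intensity** `I_b = E_b / T_b` — the breath's mean acoustic
  power.  `T_b` is the 5-breath rolling median of the onset-to-onset
  duration rather than each breath's raw one: detected onsets jitter by a
  few tens of milliseconds (threshold crossings on a noisy envelope) and
  dividing by the raw duration would inject that jitter into the
  intensity, while true durations change only smoothly.  The two
  definitions coincide in the noiseless limit.
* **respiratory rate** `RR = 60 / (onset-to-onset interval)` (breaths/min);
* **acoustic ventilation** `AV = RR × I` — the acoustic analogue of minute
  ventilation (rate × volume-per-breath).

Channels are median-smoothed over 5 breaths and linearly interpolated to a
1 s grid labeled with the protocol stage; grid points farther than 10 s
from any breath are flagged missing, never silently zeroed.  AV is
recomputed pointwise on the grid so the identity `AV = RR × I` is exact.

For breakpoint *detection* the cohort-study driver rebuilds the trace with
no median smoothing: the median rounds the knee over a few breaths, and
the two-segment fit pools information across the whole trace anyway, so
pre-smoothing only costs localization accuracy (measured on 48 simulated
subjects: mean |error| 7.5 s unsmoothed vs 9.2 s with the 5-breath
median).  The exported series keeps the smoothed defaults, which is what
the VO2 regression and any visual inspection want.

## AT detection

`fit_two_segment` exhaustively tries every interior sample (3-sample end
margins) as the knee of the hinge model `a + b·(t−t_b) + c·max(t−t_b, 0)`
(the hinge parameterization forces the segments to meet at the knee),
solves each candidate by least squares, and keeps the SSE minimizer, ties
broken toward the earliest time.  Exhaustive search is deterministic and
directly comparable against a brute-force oracle.

A detection is valid only if (a) the two-segment fit improves on the
single line by ≥ 20 % of SSE, (b) the slope increases at the knee
(ventilation accelerates at AT, never the reverse), and (c) the knee is
≥ 60 s from either end of the exercise phase.  The fit excludes warmup,
recovery, and the last 15 s of exercise (around test termination the
subject settles into the final steady state, and the flat tail drags the
fitted knee early by several seconds).

The reference AT median-smooths VE/VO2 over 15 breaths, takes its global
minimum (boundary minima rejected; VE/VCO2 must be flat or decreasing
there, else the earliest interior minimum satisfying the check is used),
then localizes the nadir precisely with a continuous two-segment V-fit of
the *raw* ratio within ±120 s — pooling every breath in the window beats
picking one noisy minimum sample, while wider windows pick up bias from
the hyperbolic pre-AT trend — and finally snaps to the raw minimum within
±3 breaths of the fitted vertex, so the noise-free nadir is recovered
exactly at breath resolution.

Agreement metrics per subject: same protocol stage (the clinically
relevant workload agreement), signed time difference, |difference| ≤ 20 s,
and the relative error of 10-s-averaged VO2 at the two times.

## Protocol model

3-min unloaded warmup, 2-min stages, 2-min recovery; stage intervals are
half-open `[start, end)`, warmup is stage 0, recovery a sentinel.  The
per-stage workload increment is the Wasserman ramp
`(predicted peak VO2 − unloaded VO2)/100` W/min — with unloaded
VO2 = 150 + 6·weight and the standard sedentary peak-VO2 formulas
(men: `weight·(50.72 − 0.372·age)`; women:
`(weight+43)·(22.78 − 0.17·age)`) — doubled for the 2-min stages and
rounded to 5 W.  Every coefficient is configurable.  Tests terminate at
85 % of (220 − age), so measured peaks are protocol-limited, not VO2max.

## VO2 regression

Targets are mass-normalized (mL/kg/min), smoothed to a 1 s grid by bin
means.  Reference VO2peak is the peak 10-s-window mean.  Predictor sets:
`respiratory` (RR, energy, AV), `resp_hr_wl` (+ HR and workload),
`all_acoustic` (the four sound features).  Backends: random-forest
regression (500 trees by default, seeded) and ordinary least squares (with
a condition-number guard).  Subject-specific validation splits each
subject's series into five *contiguous* time blocks (random rows would
leak temporal autocorrelation across the split; seeded random assignment
remains available); subject-independent validation is leave-one-subject-out.
Predicted VO2peak is the maximum of the predicted trace.

A structural caveat found while validating on the simulator: when the
underlying physiology is piecewise-linear (as it is in the generator, and
to first order in humans), ordinary least squares on the HR+workload
feature set is close to well-specified, and the random forest's advantage
shrinks to a weak tendency — the forest wins the leave-one-subject-out
peak-correlation comparison in only a modest majority of simulated
cohorts, handicapped at the peak by its inability to extrapolate beyond
the training range.
The forest's superiority on real recordings therefore reflects real-data
nonlinearity and noise structure that the generator's stated laws do not
include.

## The synthetic CPET generator

The generator encodes exactly the physiology the estimators assume, so
that they are unbiased under its assumptions — that is its scope.

* Demographics match the study population: age ~ N(31, 9.1²) years
  (clipped 18–65), 75 % female, BMI ~ N(23.5, 3.3²), VO2peak ~
  N(27.1, 6.7²) mL/kg/min (clipped 15–60).
* The stage count follows from the universal ~10 mL/min/W aerobic
  efficiency (clipped 3–7 stages): the subject tops out when the stepped
  workload demands their VO2peak.  This also ties workload and HR to VO2
  across subjects the way real incremental tests do.
* VO2 rises linearly from the unloaded value (150 + 6·weight mL/min) to
  the subject's absolute peak, with a 15 s steady-state plateau at the end
  of the final stage (so the 10-s-averaged reference peak is exact in the
  noise-free limit); VCO2 = 0.85·VO2 below the AT and gains 1.25 per unit
  VO2 above it; VE = 0.025·VCO2 + 5 L/min (dead-space offset).  These
  choices make VE/VO2 strictly decreasing before the AT and increasing
  after it — a unique nadir exactly at the AT — while VE/VCO2 is still
  decreasing there.
* True AT time ~ uniform within 45–70 % of the exercise phase; HR ramps
  linearly from 90 to 85 % of (220 − age) at exercise end; respiratory
  rate ramps linearly between per-subject endpoints (12–16 to
  28–35 breaths/min).  Breath onsets integrate the rate trajectory; the
  breath nearest the AT is snapped onto it so the threshold is
  identifiable at breath resolution in the noise-free limit.
* Breath-by-breath variability is a multiplicative lognormal breath-size
  factor (CV 5 %) shared by VO2, VCO2 and VE — gas volumes scale together
  with breath size, so the ventilatory equivalents stay comparatively
  clean, as they do on real metabolic carts.  An independent per-channel
  sensor noise knob exists for robustness experiments and is off by
  default.
* Audio: per breath an inspiratory (35 % of the period) and expiratory
  (45–75 %) burst of 100–3000 Hz band-limited noise with Tukey ramps;
  burst amplitude = coupling·sqrt(VE) — acoustic *power* linear in airflow,
  which is the physical law that makes the intensity breakpoint coincide
  with the ventilatory one.  The coupling is calibrated so peak burst
  envelopes land near 0.18 (±15 % between subjects; the noise carrier's
  crest factor is ~4, so this leaves headroom and no saturation, and
  subject-independent regression from acoustic features alone is possible,
  as observed on real same-device recordings).  Stationary white ambient
  noise is added at a configured segmental SNR (default 10 dB, measured
  against the mean within-burst clean power) and sparse 30 ms motion
  spikes at 2/min.  Native rate 15,277 Hz, exercising the resampler.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: realistic tracheal-sound spectra (bursts
are shaped noise, not physiological sound), cardiac sounds, adventitious
sounds, VO2 on-kinetics at stage transitions, the respiratory-compensation
point, irregular breathing and talking, device detachment, and any
real-data relation between body size and acoustic coupling.  Performance
numbers on the synthetic cohort are analogues of the published figures,
not reproductions of them.

## Accuracy floor and the same-stage criterion

Per-breath intensity of a noise-carrier burst has an irreducible relative
SD of about 1.7–2 % (energy of band-limited noise with ~2·B·T degrees of
freedom), which puts the two-segment knee localization at a statistical
floor of roughly ±8 s (SE) under the default conditions.  With AT times
uniform inside 120 s stages, about one boundary straddle per 24-subject
cohort is expected even at that floor, so 100 % same-stage agreement is a
favorable-draw outcome rather than a robust property — for the published
cohort as much as for simulated ones (±12.25 s SD errors give roughly a
one-in-seven chance of a clean sweep over 23 subjects).

## Problem sizes

Cohort-level results in the tests and the reproduction script use
24 subjects with full audio synthesis (~12–14 minutes of audio per subject
at 15,277 Hz).  The regression-ordering experiment uses ten 12-subject
cohorts on the generator's direct feature traces (the audio stage is not
under test there) with 100-tree forests.
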