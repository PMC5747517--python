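# Methods

## Scope and model

`circalux` quantifies circadian rhythms in four kinds of recordings:
pixel-wise bioluminescence movies of SCN explants carrying a
PER2::luciferase reporter, single-well luminometer traces, binned
locomotor activity records, and short cycloheximide-chase protein decay
courses. Every trace is treated as a (possibly damped, drifting, noisy)
single-component oscillation

    y(t) = M(t) + A(t) cos(2π (t − φ) / P) + ε(t),

with slowly varying baseline `M(t)`, period `P` (h), acrophase `φ`
(hours after recording start at which the fitted cosine peaks), and
additive noise `ε`. No mechanistic transcription–translation feedback
model is fitted; the statistics are purely descriptive of the waveform,
which is what the supported comparisons (period and phase dispersion
between genotypes, oscillating-cell fractions, waveform asymmetry,
decay rates) require.

## Conditioning

* **Smoothing** — centered moving average, window converted to the
  nearest odd sample count, shrinking at the edges so no data are
  padded in. Default window 3 samples (≈2.75 h at the 55-min frame
  cadence) where smoothing is used at all; it is the front end for
  waveform/extrema analysis and for display, not for period statistics.
* **Detrending** — subtraction of a one-cycle (24 h default) moving
  average. A window matched to the period passes the circadian
  component nearly unchanged: the residual gain at the period is
  `1 + 1/w` for a `w`-sample window (≈4% at hourly sampling), which is
  irrelevant to period/phase statistics and acceptable for amplitude
  summaries.
* **Normalization** — z-score or min–max. Both are affine; the
  periodogram statistic and all cosinor phases are invariant, so
  normalization only equalizes scales across pixels and displays.
* The movie pipeline runs detrend → periodogram → cosinor per pixel;
  smoothing before the periodogram is off by default but available
  (`AnalysisConfig.smoothing_window_h`).

## Chi-squared periodogram

Period detection uses the chi-squared periodogram. For a trial period
`P`, samples are folded by phase into `B = round(P/dt)` bins of one
sampling interval (Enright's phase-binned formulation, so `P` need not
be an integer number of samples), and

    Qp = Σ_h n_h (M_h − M̄)² / s²,    s² = Σ_i (x_i − M̄)² / N,

with `M_h` the bin means over `n_h` samples and `M̄` the grand mean.
Under white noise `Qp` is approximately chi-square with
(occupied bins − 1) degrees of freedom. When `P` is an integer number
of samples and the record holds complete cycles this reduces to the
familiar balanced-fold statistic `N·K·Σ(M_h−M̄)²/Σ(x−M̄)²`. The
phase-binned form was chosen because integer-sample folding quantizes
the period grid to the frame interval (~0.92 h at 55-min frames),
far too coarse to resolve the 0.1–0.4 h period dispersions of interest.

**Multiplicity.** A trace is called *oscillating* when any trial period
in the search range (default 20–28 h, 0.1 h steps) is significant at
`alpha = 0.10`. Scanning ~80 trial periods with a single per-period
threshold would inflate the family false-positive rate far above the
nominal level (measured ≈0.6 on white noise at the movie geometry), so
per-period p-values are Šidák-adjusted for the number of trial periods
by default. Neighbouring trial periods are strongly dependent, making
the adjustment conservative (measured family FPR 0.01–0.07 depending on
conditioning); detection of genuinely rhythmic traces at the
signal-to-noise ratios of reporter imaging is unaffected. Raw
per-period p-values are available with `correction=None`.

**Resolution.** The location of the `Qp` maximum is a less efficient
period estimator than a least-squares sinusoid fit; discriminating
0.1-h grid steps reliably needs on the order of 7–10 cycles of data.
Tests therefore use 10-day records for fine period-recovery checks and
14-day actograms for free-running periods, which are ordinary record
lengths for those assays.

## Cosinor

At fixed period the cosine fit is linear in
`(M, β1, β2) = (M, A cos ωφ, A sin ωφ)` and solved by least squares;
`A = √(β1²+β2²) ≥ 0` and `φ = atan2(β2, β1)/ω` reduced into
`[0, P)`. Per-series cosinor periods are fixed at the periodogram's
best significant period; pixels without one are fitted at the slice
reference period so acrophase maps stay defined, but they are excluded
from oscillating-fraction counts and distribution summaries. The
reference phase of a movie is the cosinor acrophase of the unweighted
mean of all in-mask pixel traces, at that mean trace's own best period;
pixel acrophases are reported relative to it, wrapped into half a
reference period either way. Phase distributions are summarized with
circular statistics (circular mean; circular SD
`√(−2 ln R̄)·P/2π` in hours), since acrophases wrap.

## Extrema and half-periods

Candidate peaks and troughs are local extrema with a minimum
separation; runs of same-kind extrema collapse to the most extreme
member (ties: earliest wins) so kinds strictly alternate, and each
extremum time is refined by 3-point parabolic interpolation (clipped to
±half a sample). Half-periods are the successive intervals between
alternating extrema starting from the first trough (or peak); their sum
always equals the span from the first to the last extremum used, and
alternating long rise / short fall intervals quantify waveform
asymmetry. Extrema at the very first or last sample of a record cannot
be detected (no flanking points), so counts refer to interior extrema.

## Behavior and metabolic rhythms

Free-running periods come from the chi-squared periodogram applied to
the binned counts of a constant-darkness segment (≥7 days required;
20–28 h search at 0.01 h steps by default). Daily acrophases are
24-h cosinor fits per calendar day, in clock hours for light-dark
records and hours after record start for constant darkness; under free
run they drift by `τ − 24` h/day. The phase delay between two
physiological rhythms is the circular difference of their 24-h cosinor
acrophases (positive = delay), guarded by a periodogram rhythmicity
check whose maximum trial period is capped at half the record span so
the guard stays defined on the minimum 48-h input; non-rhythmic inputs
produce a warning and a best-effort estimate.

## Desynchrony

Ensemble synchrony is tracked by a sliding-window Kuramoto order
parameter: in each window (default 24 h, stride 6 h) every rhythmic
pixel is phased by cosinor at the fixed slice reference period, and
`R = |mean_j exp(2πi φ_j/P)| ∈ [0, 1]`. Synchronized tissue holds
`R ≈ 1`; independent phases approach the `1/√n` noise floor. A fixed
common period is used across windows so phases remain comparable;
period heterogeneity therefore appears as (correctly) accelerating
phase dispersion rather than being absorbed into per-pixel periods.

## Protein decay

Chase courses are normalized per replicate to the t = 0 level, and
first-order decay is fitted by least squares on `ln(level)` vs time,
pooling replicates; `rate = −slope`, `half-life = ln 2 / rate`
(infinite when the fitted rate is non-positive). With only three chase
timepoints the log-linear fit is far more stable than a nonlinear
exponential fit and is exact for clean first-order decay. Conditions
are compared per post-zero timepoint with two-sided Student's t-tests
on the normalized levels.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses face:

* **Cell traces** — damped cosine, linear baseline trend, additive
  Gaussian noise, and a per-step Gaussian phase random walk whose
  accumulated value desynchronizes uncoupled oscillators. Gaussian
  noise was chosen over photon-count Poisson noise because it keeps the
  variance controllable for recovery tests; at the photon fluxes of
  typical reporter imaging the two are practically indistinguishable.
* **Movies** — 60×60 field, two-lobed elliptical mask, 55-min frames
  for five days (131 frames); per-pixel periods `N(24, 0.2²)` h and
  initial phases `N(0, 1²)` h by default; a tunable arrhythmic-pixel
  fraction (amplitude 0, same baseline/noise); optional mean-field
  Kuramoto coupling `dθ_i = [ω_i + K sin(Θ̄ − θ_i)] dt` toward the
  circular mean phase, used only as a synchronized-tissue contrast
  condition — no spatial kernel, no cell bodies. Default amplitude 100,
  baseline 100, noise SD 5 ("high SNR"), mild damping (0.005/h) and a
  small negative baseline trend mimic substrate depletion.
* **Actograms** — a clock of period τ drives Poisson counts, rate 20/h
  during subjective night and 5× lower during subjective day (10-min
  bins, 14 days by default); a light schedule can mask activity to
  darkness. Nightly activity centers and per-day acrophases are
  recorded as truth.
* **Metabolic pairs** — two 24-h cosines sampled hourly for 48 h
  (mesor 3000, amplitude 400, peak at clock hour 18, emulating
  hourly-averaged oxygen consumption of a nocturnal animal), the second
  offset by the configured delay; the "noisy" test design uses noise
  SD 40 (10% of amplitude), the residual scatter of an hourly-averaged
  metabolic trace.
* **Decay courses** — `exp(−rate·t)·(1 + N(0, σ))` per replicate at
  0/3/6 h, floored at a tiny positive value so log fits stay defined.

Not emulated: optical blur and pixel crosstalk, cell movement and focus
drift, segmentation ambiguity (the analysis is pixel-based, as is the
pipeline), non-stationary noise, light-driven masking structure beyond
a hard on/off schedule, and any transcriptional feedback dynamics.
Passing recovery tests therefore show that the statistics are
implemented correctly and are well-calibrated for this noise family —
not that they are robust to every artifact of real recordings.

## Numerical choices and degenerate inputs

* Zero-variance traces yield `Qp = 0`, p = 1 everywhere, no best
  period, and are excluded from oscillation counts; z-scoring them is
  an error.
* Periodogram preconditions: the record must cover at least two cycles
  of the longest trial period; cosinor requires ≥3 samples and coverage
  (n·dt) of at least one period.
* `wrap_phase_h` maps hour differences into `(−P/2, +P/2]`, so a
  12-hour difference at a 24-h period is reported as +12, not −12.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical datasets.
* Problem sizes in the test-suite Monte-Carlo checks (100–400
  replicates; 16×16 movies for repeated-analysis studies, full 60×60
  geometry for single-shot recovery) were chosen to keep binomial
  envelopes tight while the whole suite stays fast.

## Known limitations

* The Šidák adjustment is conservative under the strong dependence of
  neighbouring trial periods; exact family-level calibration would need
  permutation nulls, which the package does not implement.
* Acrophases of pixels fitted at different best periods are compared on
  the reference cycle; for period spreads ≫1 h relative phase becomes
  ill-defined, as it does for any phase map of heterogeneous
  oscillators.
* The order parameter uses a fixed reference period; tissues whose mean
  period drifts over days will show inflated desynchrony.
* Activity onset/offset detection is not provided; phase is quantified
  by acrophase only. Re-entrainment-day counting and "splitting"
  decomposition of actograms are out of scope, as no algorithmic
  definition exists for them in this context.
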