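# circalux

Circadian rhythm quantification for bioluminescence imaging, luminometer
traces, locomotor activity records, and protein-decay assays.

Mutations that perturb clock-protein turnover — for instance loss of a
kinase that phosphorylates and destabilizes PER2 — show up as a
characteristic constellation of phenotypes: a longer free-running period
and more variable activity phase in behavior, phase-delayed metabolic
rhythms, fewer oscillating cells and progressive desynchrony in SCN
explants imaged through a PER2::LUC reporter, distorted
(asymmetric-half-period) reporter waveforms in culture, and a slower
cycloheximide-chase decay of the stabilized protein. `circalux`
implements the analysis chain used to quantify each of those readouts,
for chronobiologists who have the recordings and want the numbers, plus
a synthetic-data generator with recorded ground truth so the whole chain
is verifiable by parameter recovery.

## What it computes

* **Chi-squared periodogram** (phase-binned fold): for trial period *P*,
  *Q*<sub>P</sub> = Σ<sub>h</sub> n<sub>h</sub>(M<sub>h</sub> − M̄)² / s²
  referred to χ²(bins − 1), with Šidák control of the rhythmicity call
  across the period grid (default 20–28 h, α = 0.10).
* **Cosinor regression** at fixed period: y = M + A·cos(2π(t − φ)/P) via
  its linearization; mesor M, amplitude A, acrophase φ, with circular
  mean/SD summaries and relative-phase maps.
* **Pixel-wise movie analysis**: detrend → periodogram → cosinor per
  in-mask pixel; period and relative-acrophase maps, oscillating-pixel
  fraction, period/phase dispersion statistics, and a sliding-window
  Kuramoto order parameter R for desynchrony.
* **Waveform analysis**: alternating peak/trough detection with
  parabolic refinement and successive half-periods (trough-to-peak vs
  peak-to-trough asymmetry).
* **Behavior**: free-running period of DD actograms, per-day cosinor
  acrophases, averaged daily activity profiles, and cosinor phase delay
  between paired physiological rhythms.
* **Decay**: per-replicate t₀ normalization, log-linear first-order
  fits (rate, half-life, SE), per-timepoint Student's t comparisons.
* **Group statistics**: Student's t, two-sided variance F-test, Tukey
  HSD.
* **Synthetic data**: SCN-like movies (heterogeneous, optionally
  coupled oscillators with a tunable arrhythmic fraction), nocturnal
  Poisson actograms, metabolic rhythm pairs, and decay courses — all
  seeded and with ground truth saved alongside.

See `docs/methods.md` for formulas, defaults, and limitations.

## Worked example

```python
import numpy as np
import circalux as cx

# a 5-day, 55-min-cadence SCN-like movie: 15% arrhythmic pixels,
# 1.5 h between-cell phase scatter
movie, truth = cx.generate_scn_movie(
    cx.MovieParams(arrhythmic_fraction=0.15, phase_sd_h=1.5, seed=8))
maps = cx.analyze_movie(movie)
print(f"oscillating: {cx.oscillating_fraction(maps):.1f}% of {int(movie.mask.sum())} pixels")
d = cx.distribution_stats(maps, "period")
print(f"period: {d.mean:.2f} +/- {d.sd:.2f} h (n={d.n})")
d = cx.distribution_stats(maps, "acrophase")
print(f"relative acrophase: {d.mean:+.2f} h, circular SD {d.sd:.2f} h")
r = cx.desynchrony_course(movie, maps=maps)
print(f"order parameter R: {r.values[0]:.3f} -> {r.values[-1]:.3f}")

rec, _ = cx.generate_actogram(tau_h=24.17, n_days=14, seed=4)
print(f"free-running period: {cx.free_running_period(rec, step_h=0.01):.2f} h")

course = cx.generate_decay_course(rate_per_h=np.log(2)/3, noise_sd=0.08, seed=2)
fit = cx.fit_decay(course)
print(f"decay: rate {fit.rate_per_h:.3f}/h, half-life {fit.half_life_h:.2f} h (R^2={fit.r_squared:.3f})")
```

prints

```
oscillating: 85.2% of 1092 pixels
period: 23.89 +/- 0.25 h (n=930)
relative acrophase: +0.04 h, circular SD 1.60 h
order parameter R: 0.932 -> 0.908
free-running period: 24.16 h
decay: rate 0.214/h, half-life 3.24 h (R^2=0.938)
```

85.2% of in-mask pixels pass the α = 0.10 periodogram call (the
generator made 85% rhythmic); their period distribution recovers the
generating 24 ± 0.2 h; the relative-phase map is centered on the slice
mean with the injected ~1.5 h scatter; the order parameter stays high
because these oscillators do not phase-diffuse. The actogram estimate
recovers the generating 24.17-h free run, and the chase fit recovers
the generating 3-h half-life within the replicate noise.

The same stages are scriptable from a shell:

```sh
circalux simulate-movie --out-dir sim --seed 1 --arrhythmic-fraction 0.15
circalux analyze-movie sim/movie.tif sim/movie.json --out sim/maps.csv --summary sim/summary.json
circalux report sim/maps.csv --out sim/report.json
```

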