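# serialdep

Serial dependence in orientation perception: when two similar stimuli are
viewed in quick succession, the report of the second is attracted toward the
first. `serialdep` is a complete, tested pipeline for studying how stimulus
uncertainty modulates this effect in orientation-adjustment experiments. It
is aimed at visual psychophysicists who want to simulate such experiments
with known ground truth, validate the analysis chain, or run the analyses on
their own trial tables.

The package covers the whole workflow:

* **Stimulus synthesis** — orientation-filtered 1/f noise patches: the
  Fourier amplitude spectrum of white noise is shaped to 1/f and passed
  through an orientation filter with a double-angled von Mises profile
  `W(φ) ∝ exp(κ·cos 2(φ − φ₀))`. Concentration κ = 4 gives low-noise
  (narrowband) stimuli, κ = 0.5 high-noise stimuli, κ = 0 isotropic masks.
  An orientation-energy estimator provides a round-trip self-test.
* **Synthetic observers** — adjustment-task sessions with wrapped-normal
  response noise per noise level, a global rotational bias, an
  orientation-dependent (oblique) bias, lapses, and a derivative-of-Gaussian
  (DoG) attraction toward the previous percept or previous response whose
  amplitude can depend on the noise-level transition; plus binary
  left/right sessions governed by a cumulative Gaussian. Noise-level
  sequences balance the four transition types (LL, LH, HL, HH) to ±1 trial.
* **The analysis chain** — preprocessing (circular-mean debiasing,
  per-noise-level 3-SD outlier removal, participant exclusion rules);
  sum-of-sines oblique-bias correction for response-contingent analyses;
  conditioning errors on the previous stimulus or previous response; a 20°
  moving average; DoG fits

  `y(x) = x·a·w·c·exp(−(w·x)²) + b`, `c = √2·e¹ᐟ² ≈ 2.3316`,

  where the amplitude `a` equals the curve's peak height (degrees), the
  width `w` (1/deg) is constrained to [0.02, 0.2], and positive `a` means
  attraction; sign-flip and condition-label-swap permutation tests; a
  model-free ±45° median-difference bias statistic with a 2×2
  repeated-measures ANOVA (previous × current noise); a probit analysis of
  the binary task; and two control analyses (t+1 conditioning and the
  alternate-flip-trial shuffle).

## Worked example

Render a low-noise stimulus and check the synthesis round trip:

```
$ serialdep stimgen --orientation 45 --kappa 4 --seed 7 --out stim.png
wrote stim.png: energy peak 41.5 deg, concentration 0.933
```

The estimated orientation-energy peak (41.5°) sits within the expected 3–4°
of the nominal 45°, and the energy concentration (resultant length of the
doubled angles, 0.93) is characteristic of κ = 4; masks (κ = 0) sit near 0.

Simulate a small cohort with a known 2.5° attraction toward the previous
response, then run the model-based analysis:

```
$ serialdep simulate adjustment --participants 6 --trials 400 --seed 1 \
      --amplitude 2.5 --out demo/
wrote demo/trials.csv (2400 rows)
$ serialdep analyze dog demo/trials.csv --nperm 2000 --seed 42
response_contingent pooled: a = 1.801 deg (w = 0.040, rmse = 0.304), p = 0.028
```

The fitted pooled amplitude (1.80°) recovers the generative attraction
after the attenuation produced by the 20° moving-average window and the
current-trial percept noise; the sign-flip permutation test (2,000
resamples) rejects the no-serial-dependence null at p = 0.028.

A full study — simulation, preprocessing, all analyses, controls, and the
binary task — runs from one config and writes CSVs, figures and a manifest:

```
$ serialdep run-all --seed 1 --out results/
```

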