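# Methods

This note documents the models, numerical choices and limitations behind
`serialdep`. All public angles are in degrees; orientations are axial
(180°-periodic) and every circular statistic works on doubled angles.

## Axial statistics

Orientations live in [0, 180), signed differences and response errors in
[−90, 90). The interval is half-open by convention: an exact ±90° tie maps
to −90, which makes boundary behaviour deterministic and testable (e.g. the
circular mean of {+85°, −85°} is reported as −90°). The circular mean
doubles the angles, takes the resultant direction, and halves it; a
resultant length ≈ 0 (uniform errors) has no defined mean and is treated as
an error condition that excludes the participant with a logged reason.
Stimulus–response association uses the Fisher–Lee circular–circular
correlation on doubled angles: it is exactly 1 for identical samples,
invariant to rotating either sample, and ≈ 0 under independence. The
exclusion threshold (0.5) is configurable; note that a correlation computed
linearly on raw angle values would differ near the wrap boundary.

## Stimulus synthesis

A patch is built in the Fourier domain: white Gaussian noise is reweighted
to a 1/f amplitude spectrum (DC removed), multiplied by an orientation
filter `W(φ) ∝ exp(κ(cos 2(φ − φ₀) − 1))` with φ₀ perpendicular to the
requested image-plane orientation, inverse-transformed, scaled to a fixed
RMS contrast (default 0.15), windowed by a circular Gaussian envelope
(default SD 1.5° of visual angle at 32 px/deg; an envelope wider than a
quarter of the raster is rejected), shifted to mid-gray and clipped to
[0, 1] with the clipped fraction logged. The filter acts on amplitude, not
power, and is symmetrised across the Nyquist row/column so that
W(−f) = W(f) holds exactly and the filtered field is real. Default raster:
256 × 256. κ defaults: 4 (low noise), 0.5 (high noise), 0 (mask).

The orientation-energy estimator marginalises Fourier power into 1°
orientation bins. Two stabilisations matter: power is pre-whitened by f²
(undoing the 1/f amplitude weighting, so every frequency annulus
contributes in proportion to its coefficient count rather than the lowest
frequencies dominating through their enormous 1/f² power), and the
histogram is smoothed with a circular Gaussian kernel (SD 3°) before the
argmax, because the κ = 4 passband is flat-topped over roughly ±10° and the
raw per-bin argmax wanders. With these choices the round trip
(synthesise at θ, estimate the peak) lands within 3° of θ for ≈ 98% of
seeds at 256², and the resultant length orders strictly with κ.

## The synthetic observer

An adjustment trial is generated as

    percept   p_t = wrap(θ_t + ε_t),   ε_t ~ wrapped normal, SD σ(noise_t)
    pull      = DoG(Δ(r_{t−1}, p_t); a(transition), w)
    response  = wrap(p_t + pull + global bias + oblique(θ_t)), or a uniform
                lapse with probability λ

with Δ the signed axial difference and r the previous percept or previous
response (the latter makes the simulation genuinely sequential; the
implementation falls back to a fully vectorised path whenever the pull does
not depend on previous responses). The first trial carries no pull. The
noise-level sequence is a seeded Eulerian path on the two-state transition
graph, so the four transition counts differ by at most one (821 trials give
exactly 205 of each); the spatial position index steps 45° counterclockwise
per trial and is carried as metadata only.

Defaults, chosen once as study conditions: 20 participants × 821 trials;
σ_low = 4°, σ_high = 8° (reproducing the roughly 1.5× accuracy gap between
noise levels); global bias 1°; lapse rate 0.01 (which gives the 3-SD
outlier filter a realistic target); DoG width w = 0.05/deg; per-transition
amplitudes 1.7° for current-low and 3.0° for current-high trials — a
current-noise-only pattern, which is precisely the ground-truth structure
the 2×2 ANOVA is meant to detect. The oblique bias is a k = 2 harmonic
(period 90°) with peak amplitude 6° for low-noise and 8° for high-noise
trials: noisy orientation stimuli produce peak oblique biases of roughly
5–15° in human observers, uncertainty is known to enlarge them, and an
oblique bias of this size produces a clearly detectable spurious amplitude
in the alternate-flip control — the regime the control analysis exists
for. With much weaker oblique biases (≲ 3°) the spurious effect shrinks
toward the detection floor of a 15-participant design and the
before-correction arm of the control loses power; the correction arm is
unaffected.

The binary-task generator draws signed orientations uniformly on ±3
generative spreads (capped at ±89°) and chooses "right" with probability
Φ(x/spread). Cohort spreads default to 4.23° (low) and 25.24° (high) with
20% log-normal between-participant variation.

What the generator does not emulate: reaction times, memory decay across
the mask interval, repulsive adaptation sidebands at large orientation
differences, sequential effects beyond lag 1, and any dependence of lapses
on the stimulus. Passing tests therefore demonstrate that the analysis
chain recovers the structure this generator produces — not that human data
contain no further structure (real data notoriously add sidebands that a
DoG does not model).

## Preprocessing

Fixed order: compute errors → participant exclusion (stimulus–response
correlation < 0.5) → subtract each participant's circular mean error →
remove trials beyond 3 SDs of their participant × noise-level cell mean.
The 3-SD rule uses the linear SD of the already-acute errors (well behaved
on [−90, 90)), runs once (not iteratively), and a zero-SD cell removes
nothing. It is applied after debiasing; since debiasing shifts all of a
participant's errors equally, cell means absorb most of the difference and
the rule is insensitive to the ordering in practice. Binary-task exclusion
(fitted spread > 60°) is applied independently of adjustment-task
exclusion. Under the default generator ≈ 0.7% of trials are removed — the
lapses plus the ~0.27% normal tail.

## Oblique-bias correction

Per participant and per noise level (uncertainty changes the oblique
pattern), errors are regressed on sin/cos harmonics of orientation with
period 180°/k, k = 1..K; K defaults to 2 — the k = 2 harmonic carries the
classic four-fold oblique pattern, k = 1 any 180°-periodic asymmetry — and
is configurable because the harmonic content of real oblique biases varies.
The fit is ordinary least squares (the basis is nearly orthonormal on
uniform orientations, so no predictor scaling is needed; rank deficiency
from clustered orientations is flagged). Predicted bias is subtracted from
each error; residualisation is idempotent. The correction is applied only
to response-contingent analyses: in stimulus-contingent analyses it could
inject artifacts through uncertainty-dependent differences in the oblique
pattern, while leaving it out is harmless there because the current trial's
orientation is independent of the previous trial's stimulus.

## Model-based analysis

Errors are conditioned on Δ(reference at t+offset, stimulus at t), with the
reference the neighbour's stimulus (stimulus-contingent) or response
(response-contingent); offset −1 is the main analysis and +1 the acausal
control. Transition labels are (neighbour noise → current noise). The
moving average evaluates the mean error in a 20° window at 1° steps on
−89..89, wrapping at ±90; windows are aligned to integer-degree bins, which
makes the binned implementation exact (verified against a brute-force
masked mean). Empty windows are flagged and excluded from fitting.

The DoG `y = x·a·w·c·exp(−(w·x)²) + b`, `c = √2·e^{1/2}`, is fit by
sweeping a dense grid of widths (91 points over [0.02, 0.2]) with the
closed-form least-squares (a, b) at each width, then polishing with a
bounded trust-region refinement. The grid makes the fit immune to the local
minima that plague joint three-parameter starts; a width landing on a bound
is flagged, since bound-pinned widths signal unstable fits during
resampling. `b` is a free nuisance parameter and is reported. The exponent
uses the squared form (w·x)²: together with the stated constant this is the
parameterisation in which `a` equals the curve's peak height above
baseline, i.e. half the peak-to-trough excursion.

Permutation tests are vectorised: each participant's 1°-bin window sums and
counts are precomputed, so a sign-flip permutation is one matrix product
and a closed-form width sweep (61 grid points). The observed statistic is
computed through the identical grid route as the permuted statistics, which
keeps the test exchangeable; the polished fit is attached for reporting
only. The amplitude test flips each participant's errors independently with
probability 1/2 (a uniform draw over participant subsets) and reports
p = #{|a_perm| ≥ |a_obs|}/n_perm; a p of 0 is displayed as < 1/n_perm. The
condition-difference test swaps the two condition labels within each
participant with probability 1/2 (trial-wise swapping is available as an
option), refits both pooled curves per permutation, and compares
|difference|. Pooling is trial-weighted by default (participant-weighted
pooling is a config option). Defaults: 10,000 permutations for reported
analyses; the calibration tests in the suite use 1,000 to fit their time
budget. Simulation and permutation RNG streams are spawned independently
from the master seed.

The alternate-flip control reverses the order of the even-numbered trials
within each participant (trial 2 ↔ last even trial, and so on), destroying
temporal adjacency while keeping each trial's own orientation–response
pairing; a "serial dependence" that survives is artifactual — in practice
the shared oblique bias — and must disappear after residualisation. The
flip is an involution, which the suite checks.

## Model-free analysis

Per participant and condition cell, the bias is the median error over
trials with Δ in (0°, 45°] minus the median over [−45°, 0°); Δ = 0 belongs
to neither window, |Δ| = 45 is included, medians use the midpoint rule, and
a window with fewer than 5 trials marks the cell missing (the participant
is then excluded listwise from the ANOVA, with a log line). Positive bias =
attraction. The 2×2 repeated-measures ANOVA (previous × current noise,
participants as the random blocking factor) is computed via statsmodels'
AnovaRM and cross-checked in the suite against a hand-computed
sums-of-squares oracle; with two-level factors no sphericity correction
exists to apply.

Why the selectivity test runs response-contingently: under
stimulus-contingent conditioning the generative process itself attenuates
the measured bias in proportion to the previous trial's percept noise (the
observed curve is the true tuning convolved with that noise), so a
generator whose amplitudes depend only on current noise still shows a
spurious previous-noise effect through the analysis route. The
response-contingent route conditions on the actual reference the observer
used and is free of that confound — the same argument that makes
response-contingent analysis the preferred route for uncertainty studies.

## Binary-task analysis

P(clockwise | x) = Φ((x − pse)/spread) is fit per participant × noise level
by trial-level Bernoulli maximum likelihood (probit regression), avoiding
binning choices; a binned mode exists for comparison. No lapse parameter by
default (configurable). Perfect separation drives the ML spread to 0: the
fit is flagged and the spread floored at 0.01°. Choices carrying no
orientation information drive the slope to ≤ 0: flagged, spread reported at
a 10⁴° ceiling, which is what the > 60° exclusion rule then catches.
Spreads are compared with a within-participant label-swap permutation test
on the paired mean difference, plus a paired Cohen's d (mean difference /
SD of differences).

## Determinism and problem sizes

Every stochastic stage draws a 31-bit child seed from the master seed via a
seed sequence; a run is byte-identical given its config, and the manifest
records the config, its hash, the package version and all child seeds. The
test suite runs the study-scale checks at 15 participants × 821 trials with
1,000-permutation tests and 20–200 Monte-Carlo repetitions per property;
the full default study in `scripts/acceptance.py` uses 20 participants and
10,000 permutations and completes in well under a minute on one CPU.

## Known limitations

* The DoG fit assumes errors are flat outside the serial-dependence range;
  generators (or data) with repulsive sidebands will degrade fit quality
  and destabilise permutation fits — the model-free statistic is the
  robust alternative, which is exactly why both are provided.
* The moving-average window and percept noise attenuate fitted amplitudes
  below their generative values (a ≈ 1.8–2.0 recovered from a_sim = 2.5 at
  the default noise levels); amplitude comparisons are therefore made
  within a fixed analysis configuration, never across window sizes.
* The sign-flip test assumes per-participant error symmetry under the null;
  heavy asymmetric contamination surviving preprocessing would distort its
  calibration.
* Fisher–Lee correlation is O(n²) in trials per participant; fine at
  hundreds of trials, noticeable at tens of thousands.
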