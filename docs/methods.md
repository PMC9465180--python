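# Methods

This note documents the models, numerical choices and limitations of
the `mozear` analysis pipeline.

## Oscillator model and best-frequency extraction

The flagellar ear under broadband stimulation is treated as a linear
forced damped harmonic oscillator. The fitted velocity-amplitude model
is

    v(omega) = A * omega^e / sqrt((omega0^2 - omega^2)^2 + (omega*omega0/Q)^2)

- `A` (amplitude ratio, arbitrary velocity units): the ratio of
  driving-force strength to apparent flagellar mass. Force and mass are
  not separately identifiable from a single spectrum, so only their
  ratio is fitted; likewise the damping constant is never stored — it
  is recoverable as `gamma = m*omega0/Q` only up to the unknown mass.
- `f0 = omega0/2pi` (Hz): the mechanical best frequency, the quantity
  the whole injection analysis is built on.
- `Q` (dimensionless): resonance sharpness; mosquito flagella sit
  around Q ≈ 1–3.
- `e` (velocity exponent, 1 or 2, default 2): the numerator power of
  omega. The literature typesets both the textbook velocity response
  (omega^1) and an omega^2 form; both are supported because the choice
  does not move the extracted `f0` (it rescales the amplitude shape
  only weakly), and the default follows the form used in the
  mosquito-hearing papers this pipeline targets. The square root over
  the full denominator is required for dimensional consistency.

Fitting minimises the sum of squared residuals on raw velocity
amplitudes (no weighting; an optional log-amplitude loss is available
for spectra with large dynamic range) over the closed band
[125, 1000] Hz. Bins below 125 Hz are excluded as noise-dominated.
Initialisation is deterministic: `f0` starts at the peak of a 5-bin
moving-average-smoothed in-band spectrum, `Q` at 1.5, and `A` at its
closed-form least-squares value given those two. The optimizer
(trust-region least squares) runs with bounds `f0` ∈ (0, 2000] Hz,
`Q` ∈ [0.1, 50], `A` > 0 (enforced via a log parameterisation); a fit
that ends on a bound, fails, or faces a constant in-band spectrum is
reported `converged=False` rather than raising, so batch processing
can skip bad recordings explicitly. At least 8 in-band bins are
required (up to 4 free parameters plus headroom).

## Loess smoothing

All time-series and profile smoothing uses classical loess: at each
evaluation point the `q = floor(span*n)` nearest observations are fit
by weighted linear or quadratic regression with tricube weights scaled
by the distance to the q-th neighbour; the fitted value is the local
intercept. No robustness iterations are applied. Defaults are span
0.75, degree 2 — the conventional loess defaults. Two exact
reproduction properties anchor the tests: any weighting reproduces
constants, and degree-1 fits reproduce straight lines exactly.
Evaluation never extrapolates: grids are truncated to the observed
time/frequency range, and minute grids are built in integer arithmetic
to avoid floating-point drift.

## Injection summaries

Baseline tuning is the median of the ≥3 pre-injection fits (robust to
a single bad fit). Median ΔFrequency smooths only the post-injection
points (the baseline enters as a scalar), evaluates at t = 1, 2, …,
floor(T) minutes, subtracts the baseline and takes the median of the
per-minute deltas; no re-smoothing of deltas occurs. The evaluation
window is exposed as a parameter (default: the full observed span, up
to 35 min).

For two-injection protocols the phase-1 curve (points in (0, t2],
t2 = 10 min by protocol) provides both the phase-1 median ΔFrequency
and the reference level, defined as the smoothed value at t2 — i.e.
the tuning level reached under serotonin just before the second
injection. Min ΔFrequency is the minimum of the phase-2 smoothed curve
(points in (t2, t2+30], window parameterised, default 30 min) minus
that reference. Where the protocol description is ambiguous about the
reference level and the phase-2 window length, these two choices are
fixed here and pinned by tests.

## Phonotaxis

Net responders per tone are `max(landed_during - landed_before, 0)`;
males leaving the net are not negative responders. Normalization
divides by the maximum net count across *all tones and all tested
days/conditions* of a cage, so day-to-day comparisons within a cage
remain on one scale (a day's own maximum does not necessarily map
to 1). An all-zero cage is a degenerate repeat and is excluded with an
error rather than silently producing 0/0.

AUC is the trapezoidal integral of normalized response over the
observed tone range (units Hz·normalized-response; a constant response
of 1 over 350–750 Hz gives 400). The response range smooths the
profile, evaluates on a 1-Hz grid, takes the arg-max as the peak (ties
broken toward the lowest frequency), sets the threshold at 25 % of the
peak value, and scans outward: the lower boundary is one grid step
above the last below-threshold point left of the peak, the upper
boundary one step below the first below-threshold point right of it;
ends that never cross the threshold keep 350/750 Hz. Because the
threshold is relative, rescaling a profile moves its AUC linearly but
leaves its response range unchanged.

The default profile smoother is span 0.75/degree 2. Note that wide
spans flatten sharply peaked profiles and, with a relative threshold,
push the boundaries outward; validation of the boundary rule against
analytic piecewise-linear profiles therefore uses a local smoother
(span 0.3, degree 2), under which quadratic local fits reproduce the
linear segments exactly and the crossings land at their analytic
positions.

## Expression

Technical triplicates collapse to their median (a configurable policy
may average two values when one is missing; the default is to error).
ΔCt subtracts the within-group *rps7* median; ΔΔCt subtracts the head
ΔCt within each (sex, repeat, gene); fold expression is `2^(-ddCt)`,
assuming 100 % amplification efficiency. Head rows are exactly 0 / 1
by construction — this identity is the pipeline's built-in sanity
check. Group comparisons use the one-way repeated-measures ANOVA
(tissue within repeat, sphericity assumed, no correction) followed by
Bonferroni-adjusted paired-t contrasts against head.

The ELISA standard curve is a four-parameter logistic on
blank-corrected absorbance (450 − 620 nm) versus concentration — the
de-facto standard for competitive ELISAs. The fit is gated on
back-calculation: every standard must recover within 15 % (relative)
of nominal or the curve is rejected. Samples outside the curve's
invertible range are flagged censored, never silently dropped;
accepted estimates are divided by the dilution factor (×10 at the
0.1× homogenate dilution).

## Statistics

ART ANOVA follows the canonical aligned-rank-transform recipe: for
each effect, subtract the cell/marginal-mean estimates of every other
effect, rank the aligned values with mid-ranks, run a full factorial
ANOVA on the ranks, and report only that effect. Balanced designs use
the classical sums-of-squares decomposition; unbalanced two-factor
designs fall back to a type-II linear-model ANOVA. One-factor ART
reduces exactly to ANOVA on ranks (alignment by a constant preserves
ranks).

The Wilcoxon signed-rank test drops zero differences by default and
uses the exact sign-flip null distribution for n ≤ 25, built by
dynamic programming on doubled mid-ranks so tied magnitudes are exact
too; larger samples use the normal approximation with continuity
correction. The rank-sum test is exact (enumeration-equivalent) for
combined n ≤ 20 without ties, otherwise tie-corrected normal.
Bonferroni adjustment is `min(1, m*p)`.

## Synthetic data

The generators emulate the study conditions of a serotonin-modulation
hearing experiment: oscillator spectra on a 1-Hz grid over 1–2000 Hz
(default f0 = 450 Hz, Q = 1.8, 5 % lognormal multiplicative noise,
plus a low-frequency noise shelf below 125 Hz to exercise band
filtering); injection series with 3 baseline points over 5 min and
post-injection points every 2–3 min over 35 min (effects of ±50–150 Hz
as step, decaying-step or ramp profiles, Gaussian 8-Hz measurement
noise); phonotaxis counts as Binomial(30, p(f)) draws from a Gaussian
tone-preference curve (center 625 Hz, sd 75 Hz, peak response
probability 0.6, small binomial pre-landed counts); Ct tables with the
housekeeping gene at Ct 20, a head ΔCt of 6 cycles and 0.05-cycle
technical noise across 7 repeats; and ELISA plates from a 4PL with
IC50 45 ng/ml. ELISA standards (7.5–270 ng/ml) deliberately sit within
about one decade either side of the IC50: outside that window the
curve is nearly flat and read noise cannot be inverted into
concentration with useful precision, so standards there would test the
noise floor, not the pipeline.

Every generator is a pure function of (seed, parameters) with no
global state; identical calls are byte-identical.

What the generators do *not* emulate — and hence what passing recovery
tests cannot show: active auditory amplification and its
nonlinearities, compound pharmacokinetics (onset/washout dynamics
beyond the chosen effect profiles), day/time-of-day behavioural
structure beyond a per-condition scale factor, plate-position and
batch effects in qPCR/ELISA, and inter-animal variance structure.
Recovery results demonstrate correctness of the estimators under the
stated noise models, not robustness to every artefact of real
recordings.

## Problem sizes

The validation suite runs entirely at desk scale: 12-point noiseless
and 50-replicate noisy oscillator grids, 100 replicates per effect
size for ΔFrequency recovery, a 1000-replicate null simulation for ART
calibration, and grid-search oracles at 0.5 Hz × 0.01 resolution over
f0 ∈ [300, 600] Hz × Q ∈ [0.5, 5]. These sizes were chosen so the
whole suite completes in well under a minute of compute per criterion
while leaving Monte-Carlo margins (e.g. ±2 percentage points on a 5 %
rejection rate at 1000 replicates) comfortably inside the asserted
bands.

## Known limitations

- The oscillator model is linear; near-threshold active ears violate
  it and the fit quality (SSE) should be inspected.
- Loess behaviour at range ends is variance-prone (one-sided
  neighbourhoods); the no-extrapolation rule limits but does not
  remove this.
- The repeated-measures ANOVA assumes sphericity; with only three
  tissue levels the risk is modest but nonzero.
- ΔΔCt assumes equal (100 %) amplification efficiency across genes; no
  dilution-series efficiency estimation is provided.
- The exact rank-sum branch requires tie-free pooled samples; tied
  data silently use the corrected normal approximation, which is
  anti-conservative for tiny n.
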