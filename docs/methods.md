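# Methods

## Coordinate model

Fixation positions arrive in screen pixels with the origin at the top-left
corner and y increasing downward. Analysis happens in signed degrees of
visual angle (dva) from screen center, x positive rightward and y positive
upward, so that "more superior gaze" is a positive vertical bias. The
conversion is a linear map with one constant degrees-per-pixel factor per
axis, derived from the screen's total angular extent (default 1920×1080 px ↔
50×24 dva at 80 cm viewing distance). A linear map is used rather than the
arctangent projection because the geometry is specified as a single angular
extent for the whole screen, which implies a constant angular pitch; at
these eccentricities the difference is well below the measurement noise of a
consumer eye tracker, and the linear map makes px↔dva an exact bijection
(round-trips reproduce inputs to 1e-9 px). Off-screen pixels extrapolate
linearly rather than erroring, since blink artifacts and tracker noise
routinely place samples slightly outside the panel.

Note that the default extents (50×24 dva for a 27″ panel at 80 cm) are taken
at face value from the hardware description they model even though a 16:9
27″ panel at 80 cm geometrically subtends closer to 41°; the geometry config
is a plain YAML file, so users with calibrated setups should supply their
own extents.

## Inclusion and aggregation

Fixations that started before image onset are removed first; the survivors
are re-indexed from 1 and truncated to the first nine (~4 s of viewing).
Trimming happens before truncation — the "first nine fixations" are the
first nine *post-onset* fixations. Participants are retained when aged 5–65
inclusive (integer years; no fractional-age interpolation, since aggregation
is per year of age) and when at least nine post-onset fixations remain.
Exclusions are tallied per reason, with the age rule checked first.

Included biases are averaged per integer year of age and per fixation index,
giving a (61 age years × 9 fixations × 2 axes) matrix of means. Internally
participants are sorted into a canonical order before averaging so the
floating-point mean is exactly invariant to input order.

## Correlation layer

For each fixation index and axis, the per-year means are correlated with age
across the n = 61 age years. Pearson's r is the default (it is what the
reference results tabulate, and what the printed confidence intervals match
under the Fisher z-transform with n = 61); Spearman's ρ — Pearson on
midranks — is available for monotone-but-nonlinear trends. Two-sided
p-values use t = r·√(n−2)/√(1−r²) on n−2 df for both methods (the usual
large-sample approximation in the Spearman case). 95% CIs use the Fisher
z-transform, tanh(atanh r ± z₀.₉₇₅/√(n−3)); empirical coverage at n = 61 is
within [0.94, 0.96] for true ρ ∈ {0, 0.4, 0.8} (checked by simulation in the
test suite). |r| = 1 is handled by convention: p = 0 and a degenerate
interval [r, r], both logged. No multiple-testing correction is applied
across the 18 (fixation, axis) cells; the bootstrap layer serves as the
control analysis instead.

## Stratified bootstrap with a paired permutation null

Per-year sample sizes in a convenience cohort differ by an order of
magnitude, so a pooled regression over-weights well-sampled ages. The
control analysis equalizes them: in each of 10,000 iterations, 20
participants are drawn with replacement from every age year and the OLS
slope of the chosen fixation's bias on age (dva/year) is fit to the sampled
participant-level points. The age labels of those *same* points are then
permuted uniformly at random and the slope refit. Reported per (fixation,
axis): the mean bootstrap slope, its 2.5th–97.5th percentile range, the mean
shuffled slope, and a paired p-value — the proportion of iterations in which
the bootstrap slope was smaller than or equal to its same-iteration shuffled
slope (ties count against rejection). The default comparison is one-sided in
the positive direction, matching the directional hypotheses (rightward and
superior shifts with age); `direction="two_sided"` compares absolute slopes.

Because each age year contributes exactly 20 draws, the participant-level
OLS slope is algebraically identical to the slope fit to the per-age means
of the draws; this structural equivalence is verified to 1e-10 in the tests,
so fitting on points (rather than on means) is a presentation choice, not a
statistical one.

Slopes are computed via centered dot products against the fixed stratified
age vector, with the response centered per iteration so that a constant
response yields an exactly zero slope (exact ties matter for the "smaller
than or equal" rule). Each (fixation, axis) cell derives its own RNG
substream from the master seed via `SeedSequence((seed, fix_index, axis))`,
so cells are reproducible and independent of evaluation order, and two runs
with the same seed are byte-identical.

### Calibration of the paired p-value

The paired p-value is *not* a classical permutation p-value and is
conservative under the null. For a given cohort, the bootstrap slopes center
on the cohort's empirical slope b̂ and the shuffled slopes on zero, so the
reported p approximates Φ(−b̂/√(v_boot + v_shuf)). Under the null b̂ varies
across cohorts with variance v_cohort, and v_boot + v_shuf (slope
variability at 20 resampled draws per age, entering twice) exceeds v_cohort
whenever the cohort holds at least as many participants per age as are
resampled. The p distribution therefore concentrates toward 0.5: at 30
participants per age year with participant SD 1.5 dva and fixation SD
1.0 dva, the measured type-I error at α = 0.05 is ≈ 0.005 (400 simulated
null cohorts, 250 iterations each — the same computation
`scripts/acceptance.py` reports as `null_rejection_rate_alpha05`). The test
is therefore valid (it never exceeds its nominal level) but under-powered
relative to an exact permutation test; this mirrors the procedure it
reimplements, where the paired comparison is the stated method. The
implementation was cross-checked against an independent brute-force loop
(object-level resampling, explicit OLS, explicit label permutation, separate
RNG), agreeing in p, mean slope, and percentile range within Monte Carlo
error.

## Synthetic cohorts

The generator draws, for participant i of age aᵢ at post-onset fixation f
and per axis,

    bias = b₀[f] + β[f]·(aᵢ − 35) + uᵢ + e_{i,f},
    uᵢ ~ N(0, σ_p²),  e_{i,f} ~ N(0, σ_f²),

a Gaussian random-intercept model: the simplest structure consistent with
large inter-individual variation on top of a strictly linear age effect.
Defaults, chosen once as plausible for free-viewing gaze data (the reference
results report no effect magnitudes in dva/year):

| parameter | default | meaning |
|---|---|---|
| ages | 5–65, unimodal counts peaking at ~25 (≈3,700 total) | convenience-sample age profile |
| β horizontal | 0, 0, **0.020**, 0.018, 0.012, 0.010, 0.008, 0, 0 dva/yr | zero on fixations 1–2, peak at 3, gone by 8–9 |
| β vertical | 0.015, 0.025, **0.035**, 0.030, 0.025, 0.015, 0, 0, 0 dva/yr | positive on fixations 1–6, peak at 3 |
| b₀ horizontal | −0.3 … −0.1 dva (trough −0.8 at fixation 2) | early leftward bias relaxing over fixations |
| b₀ vertical | +0.4 … +0.1 dva | mild superior bias |
| σ_p | 1.5 dva | between-participant SD (shared across fixations) |
| σ_f | 1.0 dva | within-participant fixation noise |
| pre-onset fraction | 0.08 | participants with 1–2 fixations before image onset |
| few-fixations fraction | 0.03 | participants with < 9 post-onset fixations |

The generator emulates the statistical structure the analysis assumes — not
real gaze: there is no image-content-driven saliency, no saccade dynamics,
no gender effects, and noise is Gaussian rather than heavy-tailed. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline recovers
known parameters under its own model assumptions, not that those assumptions
hold for any particular dataset.

## Decade bins

Descriptive curves aggregate ages into consecutive ten-year bins starting at
the inclusion minimum — 5–14, 15–24, …, 55–65, the top age joining the last
full bin rather than forming a one-year stub (edges are configurable; no
canonical choice exists). Per (bin, fixation, axis) the mean of
per-participant biases and its SEM (sample SD/√n) are reported; SEM is
undefined and reported as absent for single-participant bins. No inference
is run on bins.

## Numerical and design notes

- Correlations on per-year means use n = number of age years, not number of
  participants; this is what makes the Fisher-z intervals reproduce the
  reference values exactly.
- A constant per-age mean series (possible in noise-free synthetic data with
  a zero slope) raises an explicit zero-variance error rather than returning
  NaN.
- All randomness in an analysis run flows from the single manifest seed; the
  manifest's config hash covers every analysis-relevant field (geometry,
  inclusion, method, resampling, binning) but not the output directory or
  log level.
- Problem sizes in the test suite and acceptance script (e.g. 250–10,000
  bootstrap iterations, 30–50 participants per age in simulation studies,
  400 null replicates) were chosen to give stable Monte Carlo estimates at
  desk scale; all are parameters, not constants.

## Known limitations

- The pipeline starts from compiled fixations; it performs no fixation
  detection from raw gaze samples, no calibration-quality metrics, and no
  vendor-format parsing.
- Gender is carried as a descriptive label only; no gender-stratified
  inference is implemented.
- The paired bootstrap/permutation p-value is conservative (see above);
  users wanting exact size should run a conventional permutation test on the
  cohort-level slope instead.
- Absolute biases from a single, non-symmetric stimulus are not
  interpretable as attention biases per se; only their modulation with age
  is.
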