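# gazebias

Age trends in horizontal and vertical gaze biases from free-viewing fixation
data.

Neurologically healthy people attend slightly more to the left than the right
("pseudoneglect") and more to the upper than the lower visual field
("altitudinal pseudoneglect"). Both biases are visible in where people fixate
when freely viewing an image, and both appear to shift with age. `gazebias`
is a reusable pipeline for quantifying that shift from fixation-level data:
it is aimed at eye-tracking researchers and neuropsychologists who have a
table of fixations (participant, age, fixation index, onset-relative timing,
screen position) and want normative, per-fixation age curves of gaze bias
with defensible inference.

## What it computes

For each participant, the signed displacement of every fixation from screen
center is expressed in degrees of visual angle (dva), x positive rightward
and y positive upward, via a linear pixel-to-angle map (default screen:
1920×1080 px spanning 50×24 dva). After dropping fixations that started
before image onset and keeping the first nine, participants aged 5–65 with at
least nine fixations are retained, and biases are averaged per integer year
of age and per fixation index.

Two layers of inference run on the per-age means and on the participant-level
data:

- **Correlation per fixation and axis.** Pearson (or Spearman) correlation
  `r` between the per-year mean bias and age over the `n = 61` age years,
  with a two-sided p-value from `t = r·√(n−2)/√(1−r²)` and a 95% CI from the
  Fisher z-transform, `tanh(atanh r ± z₀.₉₇₅/√(n−3))`.
- **Stratified bootstrap against a permutation null.** Because per-year
  sample sizes are unequal, each iteration draws 20 participants with
  replacement from every age year, fits the OLS slope of bias on age (in
  dva/year), then shuffles the age labels of those same points and refits.
  Over 10,000 iterations the mean slope, the 2.5th–97.5th percentile range,
  and a paired p-value — the proportion of iterations in which the bootstrap
  slope was smaller than or equal to its shuffled counterpart — are reported
  per fixation and axis.

A synthetic cohort generator with a Gaussian random-intercept model
(`bias = b₀[f] + β[f]·(age − 35) + participant offset + fixation noise`)
provides ground truth for every stage, so the whole pipeline runs and is
tested without any data download. Decade-binned descriptive curves
(mean ± SEM per ten-year age bin) round out the outputs.

## Worked example

```bash
gazebias generate --out cohort.csv --seed 1
gazebias analyze cohort.csv --out results --seed 1
gazebias report results
```

prints (abridged):

```
wrote 33371 fixations for 3701 participants to cohort.csv
analysis complete: outputs in results
{"included": 3611, "age": 0, "too few fixations": 90}
cohort: n=3611, mean age 26.77, SD 11.78
exclusions: {'age': 0, 'included': 3611, 'too few fixations': 90}
config hash: 2dc43e561c71c353, seed 1
horizontal: significant age association at fixations [3, 4, 5, 6]
vertical: significant age association at fixations [1, 2, 3, 4, 5, 6, 7, 9]
```

The generator emitted 3,701 synthetic participants; 90 were excluded for
having fewer than nine post-onset fixations. On this cohort the age effect
peaks at fixation 3 on both axes (the horizontal per-age correlation reaches
r = 0.59, the vertical r = 0.85), mirroring the injected effect profiles:
the horizontal slope is zero for the first two fixations, peaks at fixation
3, and decays to zero by fixations 8–9, while the vertical slope is positive
for fixations 1–6. `results/` contains `table1.csv` (per-fixation
correlations with CIs), `resampling.csv` (bootstrap slopes, percentile
ranges, and paired p-values), `binned.csv` (decade-bin means ± SEM), and
`manifest.json` (seed, config hash, exclusion tally, cohort descriptives).

The same machinery is available as a library:

```python
from gazebias import SyntheticConfig, generate_cohort, trim_to_post_onset, \
    apply_inclusion, per_age_fixation_means, correlate_by_fixation

cohort = [trim_to_post_onset(p) for p in generate_cohort(SyntheticConfig(seed=1))]
included, tally = apply_inclusion(cohort)
agg = per_age_fixation_means(included)
for res in correlate_by_fixation(agg)[:2]:
    print(res.fix_index, res.axis, round(res.r, 3), round(res.p, 4))
```

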