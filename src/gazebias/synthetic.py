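"""Synthetic free-viewing cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: ages 5
to 65 with non-uniform per-year participant counts peaking in the twenties, a
per-fixation-index mean-bias profile per axis, a linear age effect that (for
the horizontal axis) is absent on the first two fixations, peaks around
fixation 3 and vanishes by fixations 8-9, large between-participant variance,
independent within-participant fixation noise, and — to exercise trimming and
exclusion — a configurable fraction of participants with pre-onset fixations
and a fraction with fewer than the nominal number of post-onset fixations.

Per participant *i* of age :math:`a_i`, axis-wise bias at post-onset fixation
*f* is

.. math:: b_{i,f} = b_0[f] + \\beta[f]\\,(a_i - a_{ref}) + u_i + e_{i,f}

with participant offset :math:`u_i \\sim N(0, \\sigma_p^2)` and fixation noise
:math:`e_{i,f} \\sim N(0, \\sigma_f^2)`, both Gaussian and independent.  The
same seed always yields the identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from gazebias.fixation_io import (
    FixationRecord,
    ParticipantRecord,
    ScreenGeometry,
    dva_to_px,
)

AXES = ("horizontal", "vertical")

# Default mean-bias profiles (dva) over the first nine post-onset fixations.
# Horizontal: early leftward bias strongest around fixations 2-3, relaxing
# toward zero; vertical: mild superior bias early on.
DEFAULT_BASELINE = {
    "horizontal": (-0.3, -0.8, -0.7, -0.5, -0.35, -0.25, -0.15, -0.1, -0.1),
    "vertical": (0.4, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15, 0.1, 0.1),
}

# Default age slopes (dva per year).  Horizontal: zero on fixations 1-2,
# peak at fixation 3, decayed to zero by fixations 8-9.  Vertical: positive
# on fixations 1-6, peak at fixation 3, zero afterwards.
DEFAULT_AGE_SLOPE = {
    "horizontal": (0.0, 0.0, 0.020, 0.018, 0.012, 0.010, 0.008, 0.0, 0.0),
    "vertical": (0.015, 0.025, 0.035, 0.030, 0.025, 0.015, 0.0, 0.0, 0.0),
}


def default_counts_per_age(age_min: int = 5, age_max: int = 65) -> dict[int, int]:
    """Unimodal per-year participant counts peaking in the mid-twenties.

    A discretised Gaussian (mode 25, SD 13, peak 120, floor 5) over the age
    range; with the default 5-65 range the cohort totals roughly 4,000
    participants, comparable to a large public-installation sample.
    """
    counts = {}
    for a in range(age_min, age_max + 1):
        counts[a] = max(5, round(120.0 * np.exp(-((a - 25.0) ** 2) / (2 * 13.0**2))))
    return counts


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for a synthetic cohort.

    ``counts_per_age`` may be a mapping year -> count or a single integer
    applied to every year in ``[age_min, age_max]``; ``None`` selects the
    default unimodal profile.  ``baseline_bias`` and ``age_slope`` map axis
    name to a length-``n_fixations`` vector (dva and dva/year).
    """

    age_min: int = 5
    age_max: int = 65
    counts_per_age: Mapping[int, int] | int | None = None
    n_fixations: int = 9
    baseline_bias: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    age_slope: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SLOPE)
    )
    age_ref: float = 35.0
    sigma_participant: float = 1.5
    sigma_fixation: float = 1.0
    frac_few_fixations: float = 0.03
    frac_pre_onset: float = 0.08
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if self.sigma_participant < 0 or self.sigma_fixation < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.frac_few_fixations <= 1 or not 0 <= self.frac_pre_onset <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_fixations < 1:
            raise ValueError("n_fixations must be at least 1")
        for axis in AXES:
            for name in ("baseline_bias", "age_slope"):
                vec = getattr(self, name).get(axis)
                if vec is None or len(vec) != self.n_fixations:
                    raise ValueError(
                        f"{name}[{axis!r}] must be a length-{self.n_fixations} vector"
                    )

    def resolved_counts(self) -> dict[int, int]:
        """Per-year counts with defaults and the constant shorthand expanded."""
        if self.counts_per_age is None:
            return default_counts_per_age(self.age_min, self.age_max)
        if isinstance(self.counts_per_age, int):
            return {a: self.counts_per_age for a in range(self.age_min, self.age_max + 1)}
        counts = {int(a): int(c) for a, c in self.counts_per_age.items()}
        if any(c < 0 for c in counts.values()):
            raise ValueError("counts must be non-negative")
        return counts


def truth_of(config: SyntheticConfig) -> dict:
    """Ground-truth expectations implied by a config.

    Returns ``slopes[axis][f-1]`` (the injected dva/year age slope per
    fixation) and ``expected_mean(age, fix_index, axis)``, the expected
    per-age mean bias ``b0[f] + beta[f] * (age - age_ref)``.
    """
    slopes = {axis: np.asarray(config.age_slope[axis], dtype=float) for axis in AXES}
    baselines = {axis: np.asarray(config.baseline_bias[axis], dtype=float) for axis in AXES}

    def expected_mean(age: float, fix_index: int, axis: str) -> float:
        f = fix_index - 1
        return float(baselines[axis][f] + slopes[axis][f] * (age - config.age_ref))

    return {
        "slopes": slopes,
        "baselines": baselines,
        "expected_mean": expected_mean,
        "age_ref": config.age_ref,
    }


def generate_biases(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ages and the post-onset bias tensor without building records.

    Returns ``(ages, bias)`` with ``ages`` shape ``(n,)`` and ``bias`` shape
    ``(n, n_fixations, 2)`` in dva, axis 0 horizontal / axis 1 vertical.
    This is the vectorised core of :func:`generate_cohort` and is also useful
    directly in large simulation studies.
    """
    counts = config.resolved_counts()
    ages = np.repeat(
        np.fromiter(counts.keys(), dtype=int),
        np.fromiter(counts.values(), dtype=int),
    )
    n = ages.size
    if n == 0:
        raise ValueError("empty cohort: counts_per_age yields zero participants")

    b0 = np.stack([config.baseline_bias[a] for a in AXES], axis=1)  # (F, 2)
    beta = np.stack([config.age_slope[a] for a in AXES], axis=1)  # (F, 2)
    centered = (ages - config.age_ref).astype(float)  # (n,)

    u = rng.normal(0.0, config.sigma_participant, size=(n, 1, 2))
    e = rng.normal(0.0, config.sigma_fixation, size=(n, config.n_fixations, 2))
    bias = b0[None, :, :] + beta[None, :, :] * centered[:, None, None] + u + e
    return ages, bias


def generate_cohort(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Generate a full synthetic cohort as participant records.

    Biases are drawn from the random-intercept model, converted to pixel
    positions, and wrapped in fixation records with strictly increasing start
    times.  A ``frac_pre_onset`` share of participants receive one or two
    extra fixations starting before image onset (positions near center plus
    fixation noise); a ``frac_few_fixations`` share keep fewer than
    ``n_fixations`` post-onset fixations, so downstream exclusion rules have
    something to act on.  Identical configs (including seed) yield identical
    cohorts.
    """
    rng = np.random.default_rng(config.seed)
    ages, bias = generate_biases(config, rng)
    n = ages.size
    F = config.n_fixations

    few_mask = rng.random(n) < config.frac_few_fixations
    n_kept = np.full(n, F, dtype=int)
    if F > 1:
        n_kept[few_mask] = rng.integers(1, F, size=int(few_mask.sum()))
    pre_mask = rng.random(n) < config.frac_pre_onset
    n_pre = np.zeros(n, dtype=int)
    n_pre[pre_mask] = rng.integers(1, 3, size=int(pre_mask.sum()))
    pre_bias = rng.normal(0.0, config.sigma_fixation, size=(n, 2, 2))
    durations = rng.uniform(180.0, 320.0, size=(n, F + 2))
    onset_lag = rng.uniform(0.0, 60.0, size=n)
    genders = rng.choice(["male", "female"], size=n, p=[0.55, 0.45])

    geometry = config.geometry
    cohort: list[ParticipantRecord] = []
    for i in range(n):
        fixations: list[FixationRecord] = []
        idx = 0
        # pre-onset fixations: near-center positions, negative start times
        for k in range(n_pre[i]):
            idx += 1
            start = -150.0 * (n_pre[i] - k)
            x_dva, y_dva = pre_bias[i, k]
            x_px, y_px = dva_to_px(x_dva, y_dva, geometry)
            fixations.append(
                FixationRecord(
                    index=idx,
                    start_ms=start,
                    duration_ms=float(durations[i, k]),
                    x_px=x_px,
                    y_px=y_px,
                    x_dva=float(x_dva),
                    y_dva=float(y_dva),
                )
            )
        t = float(onset_lag[i])
        for f in range(n_kept[i]):
            idx += 1
            x_dva, y_dva = bias[i, f]
            x_px, y_px = dva_to_px(x_dva, y_dva, geometry)
            dur = float(durations[i, 2 + f])
            fixations.append(
                FixationRecord(
                    index=idx,
                    start_ms=t,
                    duration_ms=dur,
                    x_px=float(x_px),
                    y_px=float(y_px),
                    x_dva=float(x_dva),
                    y_dva=float(y_dva),
                )
            )
            t += dur + 30.0  # saccade gap
        cohort.append(
            ParticipantRecord(
                participant_id=f"S{i:05d}",
                age_years=int(ages[i]),
                gender=str(genders[i]),
                fixations=tuple(fixations),
            )
        )
    return cohort
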