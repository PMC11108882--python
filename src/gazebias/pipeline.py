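"""Inclusion rules and per-year-of-age aggregation of gaze biases.

The analysis keeps participants aged 5-65 (inclusive) with at least nine
post-onset fixations, drops fixations that started before image onset, uses
only the first nine remaining fixations, and averages the signed biases
across participants per integer year of age and per fixation index.  The
resulting (age x fixation x axis) matrix of means is what the correlation
and plotting stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from gazebias.fixation_io import ParticipantRecord
from gazebias.synthetic import AXES


class EmptyCohortError(ValueError):
    """No participants survive the inclusion rules."""


@dataclass(frozen=True)
class InclusionConfig:
    """Cohort inclusion rules: inclusive age bounds and fixation counts.

    ``min_fixations`` is the minimum number of post-onset fixations required
    for inclusion; ``n_fixations_used`` is how many of them the analysis
    keeps (defaults: both 9, i.e. roughly 4 s of free viewing).
    """

    age_min: int = 5
    age_max: int = 65
    min_fixations: int = 9
    n_fixations_used: int = 9

    def __post_init__(self) -> None:
        if not 1 <= self.n_fixations_used <= self.min_fixations:
            raise ValueError("need 1 <= n_fixations_used <= min_fixations")
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")


@dataclass(frozen=True)
class AgeAggregate:
    """Per-year-of-age mean biases: shape (n_ages, n_fixations, 2).

    ``matrix[i, f, k]`` is the arithmetic mean over included participants of
    age ``ages[i]`` of their fixation-``f+1`` bias on axis ``AXES[k]``
    (0 horizontal, 1 vertical), in dva.  ``counts[i]`` is the number of
    participants contributing at that age.
    """

    ages: tuple[int, ...]
    matrix: np.ndarray
    counts: tuple[int, ...]

    @property
    def n_fixations(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: age_years, fix_index, axis, mean_bias_dva, n_participants."""
        rows = []
        for i, age in enumerate(self.ages):
            for f in range(self.n_fixations):
                for k, axis in enumerate(AXES):
                    rows.append(
                        {
                            "age_years": age,
                            "fix_index": f + 1,
                            "axis": axis,
                            "mean_bias_dva": self.matrix[i, f, k],
                            "n_participants": self.counts[i],
                        }
                    )
        return pd.DataFrame(rows)


def trim_to_post_onset(
    participant: ParticipantRecord, n_keep: int = 9
) -> ParticipantRecord:
    """Drop pre-onset fixations, re-index from 1, keep at most ``n_keep``.

    Fixations with ``start_ms < 0`` (started before image onset) are removed;
    the survivors are re-indexed 1..k in start-time order and truncated to the
    first ``n_keep``.  May return a participant with zero fixations.
    """
    kept = [f for f in participant.fixations if f.start_ms >= 0][:n_keep]
    reindexed = tuple(replace(f, index=i + 1) for i, f in enumerate(kept))
    return replace(participant, fixations=reindexed)


def apply_inclusion(
    cohort: Sequence[ParticipantRecord], cfg: InclusionConfig | None = None
) -> tuple[list[ParticipantRecord], dict[str, int]]:
    """Apply age and fixation-count rules; return survivors and a tally.

    Assumes pre-onset trimming has already been applied.  The tally counts
    exclusions per reason (``"age"`` checked first, then
    ``"too few fixations"``) plus the ``"included"`` total.

    Raises
    ------
    EmptyCohortError
        If nobody survives.
    """
    cfg = cfg or InclusionConfig()
    included: list[ParticipantRecord] = []
    tally = {"included": 0, "age": 0, "too few fixations": 0}
    for p in cohort:
        if not cfg.age_min <= p.age_years <= cfg.age_max:
            tally["age"] += 1
        elif len(p.fixations) < cfg.min_fixations:
            tally["too few fixations"] += 1
        else:
            included.append(p)
            tally["included"] += 1
    if not included:
        raise EmptyCohortError("empty cohort after inclusion")
    return included, tally


def per_age_fixation_means(
    cohort: Sequence[ParticipantRecord], n_fixations_used: int = 9
) -> AgeAggregate:
    """Average biases across participants per year of age and per fixation.

    Every participant must have at least ``n_fixations_used`` fixations
    (guaranteed after :func:`apply_inclusion` with defaults).  Ages are
    listed ascending; each matrix cell is the plain arithmetic mean.
    """
    # canonical participant order makes the float mean exactly
    # order-invariant with respect to the input sequence
    cohort = sorted(cohort, key=lambda p: (p.age_years, p.participant_id))
    ages = np.array([p.age_years for p in cohort], dtype=int)
    bias = np.empty((len(cohort), n_fixations_used, 2), dtype=float)
    for i, p in enumerate(cohort):
        if len(p.fixations) < n_fixations_used:
            raise ValueError(
                f"participant {p.participant_id} has {len(p.fixations)} fixations, "
                f"needs {n_fixations_used}"
            )
        for f in range(n_fixations_used):
            bias[i, f, 0] = p.fixations[f].x_dva
            bias[i, f, 1] = p.fixations[f].y_dva

    unique_ages = np.unique(ages)
    matrix = np.empty((unique_ages.size, n_fixations_used, 2), dtype=float)
    counts = np.empty(unique_ages.size, dtype=int)
    for i, a in enumerate(unique_ages):
        sel = ages == a
        counts[i] = int(sel.sum())
        matrix[i] = bias[sel].mean(axis=0)
    return AgeAggregate(
        ages=tuple(int(a) for a in unique_ages),
        matrix=matrix,
        counts=tuple(int(c) for c in counts),
    )


def cohort_summary(cohort: Sequence[ParticipantRecord]) -> dict:
    """Descriptives: N, mean/SD of age (sample SD), and gender counts.

    For an empty cohort the moments are reported as ``None``; with a single
    participant the SD is ``None`` (undefined for n=1 with the n-1 divisor).
    """
    n = len(cohort)
    ages = [p.age_years for p in cohort]
    gender_counts: dict[str, int] = {}
    for p in cohort:
        gender_counts[p.gender] = gender_counts.get(p.gender, 0) + 1
    mean_age = float(np.mean(ages)) if n else None
    sd_age = float(np.std(ages, ddof=1)) if n > 1 else None
    return {
        "n": n,
        "mean_age": mean_age,
        "sd_age": sd_age,
        "gender_counts": gender_counts,
    }


def cohort_bias_arrays(
    cohort: Sequence[ParticipantRecord], n_fixations: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Extract ``(ages, bias)`` arrays from an included cohort.

    ``bias`` has shape ``(n, n_fixations, 2)`` in dva.  Shared fast path for
    the resampling and binning stages.
    """
    ages = np.array([p.age_years for p in cohort], dtype=float)
    bias = np.empty((len(cohort), n_fixations, 2), dtype=float)
    for i, p in enumerate(cohort):
        for f in range(n_fixations):
            bias[i, f, 0] = p.fixations[f].x_dva
            bias[i, f, 1] = p.fixations[f].y_dva
    return ages, bias
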