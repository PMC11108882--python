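"""Fixation tables, screen geometry, and pixel ↔ visual-angle conversion.

Gaze positions are recorded in screen pixels (origin top-left, y increasing
downward) and analysed as signed *biases* from screen center in degrees of
visual angle (dva): x positive rightward, y positive **upward** (superior), so
that a positive vertical bias means gaze above center.  The conversion is a
linear map using a constant degrees-per-pixel factor per axis, matching a
setup specified by a single angular extent for the whole screen.

The on-disk format is a plain CSV with one row per fixation (see
:data:`REQUIRED_COLUMNS`) plus a YAML screen-geometry config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Columns a fixation CSV must provide, in canonical order.
REQUIRED_COLUMNS = (
    "participant_id",
    "age_years",
    "gender",
    "fix_index",
    "start_ms",
    "duration_ms",
    "x_px",
    "y_px",
)

GENDER_LABELS = ("male", "female", "other/unknown")


class FixationTableError(ValueError):
    """Malformed fixation table (missing column, bad value, or empty file)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry linking pixel coordinates to visual angle.

    Defaults describe a 1920x1080 px monitor subtending 50x24 degrees of
    visual angle viewed from 80 cm.  ``viewing_distance_cm`` is metadata
    only; the conversion uses the stated angular extents directly.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_dva: float = 50.0
    height_dva: float = 24.0
    viewing_distance_cm: float = 80.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_dva", "height_dva"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenGeometry":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "width_dva": self.width_dva,
            "height_dva": self.height_dva,
            "viewing_distance_cm": self.viewing_distance_cm,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: ordinal index, timing, and position in px and dva.

    ``index`` is the 1-based position in the participant's sequence;
    after pre-onset trimming it is the position in the post-onset sequence.
    ``start_ms`` is relative to image onset and may be negative before
    trimming.
    """

    index: int
    start_ms: float
    duration_ms: float
    x_px: float
    y_px: float
    x_dva: float
    y_dva: float


@dataclass(frozen=True)
class ParticipantRecord:
    """A participant's age, gender label, and ordered fixation sequence."""

    participant_id: str
    age_years: int
    gender: str
    fixations: tuple[FixationRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        starts = [f.start_ms for f in self.fixations]
        if starts != sorted(starts):
            raise ValueError("fixations must be sorted by start_ms")


def px_to_dva(
    x_px: float, y_px: float, geometry: ScreenGeometry
) -> tuple[float, float]:
    """Convert a pixel position to signed dva from screen center.

    Linear (small-angle) map with constant degrees-per-pixel per axis.  The
    vertical axis is flipped so the superior direction is positive.  Off-screen
    pixels extrapolate linearly (a debug message is logged).
    """
    if not (0 <= x_px <= geometry.width_px and 0 <= y_px <= geometry.height_px):
        logger.debug("off-screen pixel (%s, %s) extrapolated", x_px, y_px)
    x_dva = (x_px - geometry.width_px / 2) * (geometry.width_dva / geometry.width_px)
    y_dva = (geometry.height_px / 2 - y_px) * (geometry.height_dva / geometry.height_px)
    return x_dva, y_dva


def dva_to_px(
    x_dva: float, y_dva: float, geometry: ScreenGeometry
) -> tuple[float, float]:
    """Exact inverse of :func:`px_to_dva`."""
    x_px = x_dva * (geometry.width_px / geometry.width_dva) + geometry.width_px / 2
    y_px = geometry.height_px / 2 - y_dva * (geometry.height_px / geometry.height_dva)
    return x_px, y_px


def read_fixation_table(
    path: str | Path, geometry: ScreenGeometry
) -> list[ParticipantRecord]:
    """Read a fixation CSV into one :class:`ParticipantRecord` per participant.

    Fixations are sorted by start time within each participant; both pixel
    and dva coordinates are populated.  Participants are returned in order
    of first appearance in the file.

    Raises
    ------
    FixationTableError
        If a required column is missing (the message names it), a coordinate
        fails to parse (the message gives the CSV line number), or the file
        holds no records.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        raise FixationTableError(f"no records in {path}: file is empty") from None

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FixationTableError(
            f"missing required column(s) in {path}: {', '.join(missing)}"
        )
    if df.empty:
        raise FixationTableError(f"no records in {path}: header only")

    numeric_cols = ("age_years", "fix_index", "start_ms", "duration_ms", "x_px", "y_px")
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise FixationTableError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line} of {path}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise FixationTableError(
                f"missing value in column {col!r} at line {line} of {path}"
            )
        df[col] = coerced

    participants: list[ParticipantRecord] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values(["start_ms", "fix_index"], kind="mergesort")
        fixations = []
        for row in grp.itertuples(index=False):
            x_dva, y_dva = px_to_dva(row.x_px, row.y_px, geometry)
            fixations.append(
                FixationRecord(
                    index=int(row.fix_index),
                    start_ms=float(row.start_ms),
                    duration_ms=float(row.duration_ms),
                    x_px=float(row.x_px),
                    y_px=float(row.y_px),
                    x_dva=x_dva,
                    y_dva=y_dva,
                )
            )
        first = grp.iloc[0]
        participants.append(
            ParticipantRecord(
                participant_id=str(pid),
                age_years=int(first["age_years"]),
                gender=str(first["gender"]),
                fixations=tuple(fixations),
            )
        )
    return participants


def write_fixation_table(
    cohort: Sequence[ParticipantRecord], path: str | Path
) -> None:
    """Write participants back to the fixation CSV dialect (pixel positions)."""
    rows = []
    for p in cohort:
        for f in p.fixations:
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "age_years": p.age_years,
                    "gender": p.gender,
                    "fix_index": f.index,
                    "start_ms": f.start_ms,
                    "duration_ms": f.duration_ms,
                    "x_px": f.x_px,
                    "y_px": f.y_px,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def with_fixations(
    participant: ParticipantRecord, fixations: Sequence[FixationRecord]
) -> ParticipantRecord:
    """Copy a participant with a replaced fixation sequence."""
    return replace(participant, fixations=tuple(fixations))
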