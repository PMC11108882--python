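"""Decade-binned descriptive curves and end-to-end orchestration.

The binned view averages each participant's per-fixation bias within ten-year
age bins and reports the mean ± SEM per (bin, fixation, axis).  It is
descriptive only — no inference is run on bins.  :func:`run_full_analysis`
chains the whole pipeline (read → trim → include → aggregate → correlate →
resample → bin) and writes three CSVs plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gazebias.fixation_io import ParticipantRecord, ScreenGeometry, read_fixation_table
from gazebias.pipeline import (
    InclusionConfig,
    apply_inclusion,
    cohort_bias_arrays,
    cohort_summary,
    per_age_fixation_means,
    trim_to_post_onset,
)
from gazebias.resampling import ResamplingConfig, resampling_table, run_resampling_suite
from gazebias.stats import correlate_by_fixation, correlation_table
from gazebias.synthetic import AXES

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class BinnedSummary:
    """Mean ± SEM of bias within one ten-year age bin, fixation, and axis.

    ``sem`` is the sample SD across participants divided by sqrt(n); it is
    ``None`` for a single-participant bin.
    """

    bin_label: str
    fix_index: int
    axis: str
    mean_bias: float
    sem: float | None
    n: int


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run needs, in one place."""

    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    inclusion: InclusionConfig = field(default_factory=InclusionConfig)
    method: str = "pearson"
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    bin_width: int = 10
    out_dir: str | Path = "gazebias_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "geometry": vars(self.geometry).copy(),
            "inclusion": vars(self.inclusion).copy(),
            "method": self.method,
            "resampling": {
                "n_per_age": self.resampling.n_per_age,
                "n_iterations": self.resampling.n_iterations,
                "seed": self.resampling.seed,
                "direction": self.resampling.direction,
            },
            "bin_width": self.bin_width,
        }

    def config_hash(self) -> str:
        # out_dir and log_level are run environment, not analysis config
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def decade_bins(age_min: int, age_max: int, width: int = 10) -> list[tuple[int, int]]:
    """Consecutive width-year bins from ``age_min``; the top age joins the
    last full bin rather than forming a stub (e.g. 5-65 → 5-14, ..., 55-65)."""
    bins = [
        (lo, min(lo + width - 1, age_max))
        for lo in range(age_min, age_max + 1, width)
    ]
    if len(bins) > 1 and bins[-1][1] - bins[-1][0] + 1 < width:
        bins[-2] = (bins[-2][0], bins[-1][1])
        bins.pop()
    return bins


def bin_by_decade(
    cohort: Sequence[ParticipantRecord],
    age_min: int = 5,
    age_max: int = 65,
    width: int = 10,
    n_fixations: int = 9,
) -> list[BinnedSummary]:
    """Mean ± SEM of per-participant bias within ten-year age bins.

    Assumes inclusion has been applied.  Bins partition
    ``[age_min, age_max]`` without overlap; empty bins are omitted.
    """
    ages, bias = cohort_bias_arrays(cohort, n_fixations)
    out: list[BinnedSummary] = []
    for lo, hi in decade_bins(age_min, age_max, width):
        sel = (ages >= lo) & (ages <= hi)
        n = int(sel.sum())
        if n == 0:
            continue
        label = f"{lo}–{hi}"
        sub = bias[sel]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1) if n > 1 else None
        for f in range(n_fixations):
            for k, axis in enumerate(AXES):
                sem = float(sds[f, k] / math.sqrt(n)) if n > 1 else None
                out.append(
                    BinnedSummary(
                        bin_label=label,
                        fix_index=f + 1,
                        axis=axis,
                        mean_bias=float(means[f, k]),
                        sem=sem,
                        n=n,
                    )
                )
    return out


def binned_table(summaries: Sequence[BinnedSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_label": s.bin_label,
                "fix_index": s.fix_index,
                "axis": s.axis,
                "mean_bias": s.mean_bias,
                "sem": s.sem,
                "n": s.n,
            }
            for s in summaries
        ]
    )


def run_full_analysis(cohort_path: str | Path, cfg: RunConfig | None = None) -> dict:
    """Run the whole pipeline on a fixation CSV and write the report bundle.

    Outputs in ``cfg.out_dir``: ``table1.csv`` (per-fixation correlations),
    ``resampling.csv`` (bootstrap/permutation outcomes), ``binned.csv``
    (decade-binned descriptives), and ``manifest.json`` (seed, config hash,
    exclusion tally, cohort summary).  Identical inputs and seed give
    byte-identical outputs.  Any stage failure raises
    :class:`PipelineStageError` naming the stage, after removing partial
    outputs.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_files = [
        out_dir / "table1.csv",
        out_dir / "resampling.csv",
        out_dir / "binned.csv",
        out_dir / "manifest.json",
    ]
    try:
        stage = "read"
        cohort = read_fixation_table(cohort_path, cfg.geometry)
        stage = "trim"
        trimmed = [
            trim_to_post_onset(p, cfg.inclusion.n_fixations_used) for p in cohort
        ]
        stage = "include"
        included, tally = apply_inclusion(trimmed, cfg.inclusion)
        stage = "aggregate"
        agg = per_age_fixation_means(included, cfg.inclusion.n_fixations_used)
        stage = "correlate"
        correlations = correlate_by_fixation(agg, cfg.method)
        stage = "resample"
        outcomes = run_resampling_suite(
            included, cfg.resampling, cfg.inclusion.n_fixations_used
        )
        stage = "bin"
        binned = bin_by_decade(
            included,
            cfg.inclusion.age_min,
            cfg.inclusion.age_max,
            cfg.bin_width,
            cfg.inclusion.n_fixations_used,
        )
        stage = "write"
        correlation_table(correlations).to_csv(out_dir / "table1.csv", index=False)
        resampling_table(outcomes, cfg.resampling).to_csv(
            out_dir / "resampling.csv", index=False
        )
        binned_table(binned).to_csv(out_dir / "binned.csv", index=False)
        manifest = {
            "seed": cfg.resampling.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "exclusion_tally": tally,
            "cohort_summary": cohort_summary(included),
            "n_age_years": len(agg.ages),
        }
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        for f in out_files:
            f.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc

    return {
        "correlations": correlations,
        "resampling": outcomes,
        "binned": binned,
        "aggregate": agg,
        "manifest": manifest,
    }
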