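"""Per-subject community resilience after an antibiotic perturbation.

For each subject, every post-baseline sample is scored by its Aitchison
distance ``d(t)`` to the subject's own baseline (CID1) sample.  With
``dmax`` the subject's largest such distance (empirically attained right
after the antibiotic course), resilience is

    R(t) = (dmax − d(t)) / (dmax + d(t))

R is 0 at the visit of maximal displacement and approaches 1 as the
community returns to its baseline composition.  Distances use the full
(unfiltered) genus set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CLRMatrix, aitchison_distance, clr_transform
from .config import AnalysisConfig
from .tables import (
    Arm,
    GenusCountTable,
    SampleRecord,
    Timepoint,
    ValidationError,
)

logger = logging.getLogger("microresilience")

__all__ = [
    "SubjectTrajectory",
    "distance_from_baseline",
    "resilience_score",
    "resilience_trajectories",
    "trajectories_to_frame",
    "median_split",
]


class UndefinedResilienceError(ValueError):
    """dmax is zero: the subject never left baseline, R is undefined."""


@dataclass
class SubjectTrajectory:
    """Ordered distances from baseline and resilience values for one subject."""

    subject_id: str
    arm: Arm
    timepoints: list[Timepoint]
    d: dict[Timepoint, float]
    dmax: float = field(init=False)
    R: dict[Timepoint, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.d:
            raise ValidationError(f"subject {self.subject_id}: no post-baseline samples")
        self.dmax = max(self.d.values())
        if self.dmax <= 0:
            raise UndefinedResilienceError(
                f"subject {self.subject_id}: identical to baseline at every visit"
            )
        self.R = {t: resilience_score(dt, self.dmax) for t, dt in self.d.items()}


def distance_from_baseline(
    clr: CLRMatrix, meta: dict[str, SampleRecord]
) -> dict[str, list[tuple[Timepoint, float]]]:
    """Aitchison distance of each post-baseline sample to the subject's CID1.

    Subjects without a baseline sample are skipped with a warning; missing
    intermediate visits simply yield no entry (no imputation).
    """
    by_subject: dict[str, dict[Timepoint, str]] = {}
    for sid, rec in meta.items():
        if sid not in clr.values.index:
            continue
        by_subject.setdefault(rec.subject_id, {})[rec.timepoint] = sid

    out: dict[str, list[tuple[Timepoint, float]]] = {}
    skipped = 0
    for subject, visits in sorted(by_subject.items()):
        if Timepoint.CID1 not in visits:
            logger.warning(
                "distance_from_baseline: subject %s has no CID1 sample — skipped",
                subject,
            )
            skipped += 1
            continue
        baseline = clr.values.loc[visits[Timepoint.CID1]]
        series = []
        for tp in sorted(visits, key=lambda t: t.value):
            if tp is Timepoint.CID1:
                continue
            series.append(
                (tp, aitchison_distance(clr.values.loc[visits[tp]], baseline))
            )
        if series:
            out[subject] = series
    if not out:
        raise ValidationError("no subjects with a baseline sample — empty result")
    if skipped:
        logger.warning("distance_from_baseline: %d subject(s) skipped", skipped)
    return out


def resilience_score(d: float, dmax: float) -> float:
    """R = (dmax − d) / (dmax + d), in [0, 1] for 0 ≤ d ≤ dmax."""
    if dmax <= 0:
        raise UndefinedResilienceError("dmax must be positive")
    if d < 0:
        raise ValidationError("distance from baseline cannot be negative")
    if d > dmax * (1 + 1e-12):
        raise ValidationError(f"d={d} exceeds dmax={dmax}")
    return (dmax - d) / (dmax + d)


def resilience_trajectories(
    table: GenusCountTable, config: AnalysisConfig | None = None
) -> list[SubjectTrajectory]:
    """Full pipeline: CLR transform → per-subject distances → R per visit.

    Subjects whose dmax is zero are excluded with a warning.
    """
    config = config or AnalysisConfig()
    clr = clr_transform(table, pseudocount=config.pseudocount)
    distances = distance_from_baseline(clr, table.meta)
    arm_of = {rec.subject_id: rec.arm for rec in table.meta.values()}
    trajectories = []
    for subject, series in distances.items():
        try:
            trajectories.append(
                SubjectTrajectory(
                    subject_id=subject,
                    arm=arm_of[subject],
                    timepoints=[t for t, _ in series],
                    d=dict(series),
                )
            )
        except UndefinedResilienceError:
            logger.warning(
                "resilience_trajectories: subject %s never left baseline — excluded",
                subject,
            )
    return trajectories


def trajectories_to_frame(trajectories: list[SubjectTrajectory]) -> pd.DataFrame:
    """Long-format (subject, arm, timepoint, d, dmax, R) for the mixed models."""
    rows = []
    for tr in trajectories:
        for tp in tr.timepoints:
            rows.append(
                dict(
                    subject_id=tr.subject_id,
                    arm=tr.arm.value,
                    timepoint=tp.name,
                    week=tp.week,
                    d=tr.d[tp],
                    dmax=tr.dmax,
                    R=tr.R[tp],
                )
            )
    return pd.DataFrame(rows)


def median_split(
    baseline_values: pd.Series, within: pd.Series | None = None
) -> pd.Series:
    """Split subjects at the (within-group) median of a baseline metric.

    Values strictly above the median are labelled ``HIGH``; values at or
    below the median are ``LOW`` (deterministic tie rule).  If all values
    in a group are identical the split is degenerate: everyone is LOW and
    a warning is logged.
    """
    labels = pd.Series(index=baseline_values.index, dtype=object)
    groups = (
        baseline_values.groupby(within)
        if within is not None
        else [(None, baseline_values)]
    )
    for name, vals in groups:
        if len(vals) < 2:
            raise ValidationError(
                f"median_split: group {name!r} has fewer than 2 subjects"
            )
        med = vals.median()
        if vals.nunique() == 1:
            logger.warning(
                "median_split: all values identical in group %r — degenerate split",
                name,
            )
            labels.loc[vals.index] = "LOW"
            continue
        labels.loc[vals.index] = np.where(vals > med, "HIGH", "LOW")
    return labels
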