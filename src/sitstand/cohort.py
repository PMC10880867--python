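"""Severity classification and group-pool assembly.

Subjects are stratified along two WOMAC subscales:

* stiffness — mild if 0 < score < 4, severe if score >= 4;
* physical function — mild if 0 < score < 35, severe if score >= 35.

A score of exactly 0 falls outside both printed intervals (the study cohort
contained no asymptomatic subjects) and is rejected by default;
``zero_as_mild=True`` opts in to binning it as mild for reuse on broader
populations.

Osteoarthritic and healthy knees behave differently, so group pools respect
the affected side: a subject's left-hip and left-knee curves enter a pool
only if the left knee is affected, and likewise for the right. Bilateral
subjects contribute both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    ClassificationError,
    FormatError,
    IncompleteRecordError,
)
from .preprocess import NormalizedSeries, mean_curve

__all__ = [
    "STIFFNESS_CUTOFF",
    "FUNCTION_CUTOFF",
    "Dimension",
    "Level",
    "SubjectRecord",
    "GroupedPools",
    "classify_stiffness",
    "classify_function",
    "classify",
    "build_pools",
    "group_mean_curves",
    "read_roster_csv",
    "write_roster_csv",
]

#: WOMAC stiffness subscale cut-off: score >= 4 is severe.
STIFFNESS_CUTOFF: float = 4.0
#: WOMAC physical-function subscale cut-off: score >= 35 is severe.
FUNCTION_CUTOFF: float = 35.0

Dimension = Literal["stiffness", "function"]
Level = Literal["mild", "severe"]

_SIDE_SITES = {
    "left": ("left_hip", "left_knee"),
    "right": ("right_hip", "right_knee"),
}


@dataclass
class SubjectRecord:
    """Roster entry tying one subject's curves to their WOMAC scores.

    ``series`` maps site -> length-normalized curve; it must cover the
    ipsilateral hip and knee of every affected side before pooling.
    ``kl_grade`` (radiographic severity per knee) is carried as metadata
    only.
    """

    subject_id: str
    womac_stiffness: float
    womac_function: float
    affected_sides: frozenset[str]
    series: dict[str, NormalizedSeries] = field(default_factory=dict)
    kl_grade: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.affected_sides = frozenset(self.affected_sides)
        if not self.affected_sides or not self.affected_sides <= {"left", "right"}:
            raise ValueError(
                "affected_sides must be a nonempty subset of {'left','right'}"
            )
        if self.womac_stiffness < 0 or self.womac_function < 0:
            raise ValueError("WOMAC scores must be non-negative")


@dataclass
class GroupedPools:
    """Per-(site, level) lists of normalized curves for one grouping."""

    dimension: Dimension
    pools: dict[tuple[str, Level], list[NormalizedSeries]]

    @property
    def counts(self) -> dict[tuple[str, Level], int]:
        return {key: len(curves) for key, curves in self.pools.items()}


def _classify(score: float, cutoff: float, zero_as_mild: bool, label: str) -> Level:
    if score < 0:
        raise ClassificationError(f"negative WOMAC {label} score {score}")
    if score == 0:
        if zero_as_mild:
            return "mild"
        raise ClassificationError(
            f"WOMAC {label} score 0 lies outside both severity intervals; "
            "pass zero_as_mild=True to bin it as mild"
        )
    return "severe" if score >= cutoff else "mild"


def classify_stiffness(score: float, zero_as_mild: bool = False) -> Level:
    """Classify a WOMAC stiffness score: mild (0 < s < 4) or severe (s >= 4)."""
    return _classify(score, STIFFNESS_CUTOFF, zero_as_mild, "stiffness")


def classify_function(score: float, zero_as_mild: bool = False) -> Level:
    """Classify a WOMAC function score: mild (0 < s < 35) or severe (s >= 35)."""
    return _classify(score, FUNCTION_CUTOFF, zero_as_mild, "function")


def classify(
    subject: SubjectRecord, dimension: Dimension, zero_as_mild: bool = False
) -> Level:
    """Classify a subject along one grouping dimension."""
    if dimension == "stiffness":
        return classify_stiffness(subject.womac_stiffness, zero_as_mild)
    if dimension == "function":
        return classify_function(subject.womac_function, zero_as_mild)
    raise ValueError(f"unknown dimension {dimension!r}")


def build_pools(
    subjects: list[SubjectRecord],
    dimension: Dimension,
    zero_as_mild: bool = False,
) -> GroupedPools:
    """Assemble per-(site, severity) curve pools respecting affected sides.

    For each subject and each affected side, the ipsilateral hip and knee
    curves join the pool of the subject's severity level; curves from
    unaffected sides never enter any pool.

    Raises
    ------
    IncompleteRecordError
        A subject lacks the series for one of its affected sides.
    ClassificationError
        A score cannot be classified (propagated from ``classify``).
    """
    pools: dict[tuple[str, Level], list[NormalizedSeries]] = {
        (site, level): []
        for site in ("left_hip", "right_hip", "left_knee", "right_knee")
        for level in ("mild", "severe")
    }
    for subject in subjects:
        level = classify(subject, dimension, zero_as_mild)
        for side in sorted(subject.affected_sides):
            for site in _SIDE_SITES[side]:
                if site not in subject.series:
                    raise IncompleteRecordError(
                        f"subject {subject.subject_id!r} is {side}-affected "
                        f"but has no {site!r} series"
                    )
                pools[(site, level)].append(subject.series[site])
    return GroupedPools(dimension=dimension, pools=pools)


def group_mean_curves(
    pools: GroupedPools, allow_empty: bool = False
) -> dict[tuple[str, Level], np.ndarray]:
    """Average each pool into one group mean curve per (site, level)."""
    means: dict[tuple[str, Level], np.ndarray] = {}
    for key, curves in pools.pools.items():
        if not curves:
            if allow_empty:
                continue
            raise AggregationError(
                f"empty pool for site={key[0]!r}, level={key[1]!r} "
                f"({pools.dimension} grouping)"
            )
        means[key] = mean_curve(curves)
    return means


def write_roster_csv(subjects: list[SubjectRecord], path: str | Path) -> Path:
    """Write a roster CSV (scores, affected sides, series file references).

    The ``series_file`` column holds the path of the subject's angle-series
    CSV as written by :func:`sitstand.keypoint_io.write_angle_series_csv`,
    or an empty string when curves are kept in memory only.
    """
    path = Path(path)
    rows = [
        {
            "subject_id": s.subject_id,
            "womac_stiffness": s.womac_stiffness,
            "womac_function": s.womac_function,
            "affected_sides": ";".join(sorted(s.affected_sides)),
            "series_file": "",
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_roster_csv(path: str | Path) -> list[SubjectRecord]:
    """Read a roster CSV into :class:`SubjectRecord` objects (no curves).

    Curves referenced by ``series_file`` are not loaded here; attach them via
    :func:`sitstand.preprocess.normalize_angle_series` after reading the
    angle files.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"subject_id", "womac_stiffness", "womac_function", "affected_sides"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: roster missing column(s) {sorted(missing)}")
    subjects = []
    for _, row in frame.iterrows():
        sides = frozenset(
            part.strip() for part in str(row["affected_sides"]).split(";") if part.strip()
        )
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                womac_stiffness=float(row["womac_stiffness"]),
                womac_function=float(row["womac_function"]),
                affected_sides=sides,
            )
        )
    return subjects
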