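"""Arithmetic of the IHI visual-rating protocol.

Incomplete hippocampal inversion (IHI) is rated on four ordinal anatomical
criteria per hemisphere:

* **C1** — verticality and roundness of the hippocampal body,
* **C2** — verticality and depth of the collateral sulcus,
* **C3** — medial position of the hippocampus,
* **C5** — sulci of the fusiform gyrus exceeding the level of the subiculum.

C1–C3 are scored on a 0–2 scale in steps of 0.5; C5 on a 0–2 scale in steps
of 1.  (A fifth protocol criterion, subiculum bulging, is deliberately not
representable here: it is nearly constant in the population and unreliable
to rate, and the composite score is built without it.)

The composite IHI score is the plain sum of the four criteria (range 0–8);
a hemisphere is classified as exhibiting IHI when the composite is >= 4.

Continuous model predictions are snapped onto the criterion grids with
:func:`round_prediction` before composites and agreement statistics are
computed, mirroring how a human rater can only emit on-grid scores.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Criterion",
    "CRITERIA",
    "IHI_THRESHOLD",
    "criterion_grid",
    "round_prediction",
    "composite_score",
    "classify_ihi",
    "RatingRecord",
    "records_to_frame",
    "frame_to_records",
    "read_ratings_tsv",
    "write_ratings_tsv",
]


class Criterion(enum.Enum):
    """The four rated IHI criteria.  C4 is intentionally absent."""

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C5 = "C5"

    @property
    def step(self) -> float:
        """Grid step of this criterion's rating scale."""
        return 1.0 if self is Criterion.C5 else 0.5


#: Canonical criterion order used throughout tables and reports.
CRITERIA: tuple[Criterion, ...] = (
    Criterion.C1,
    Criterion.C2,
    Criterion.C3,
    Criterion.C5,
)

#: Composite score at or above which inversion is deemed incomplete.
IHI_THRESHOLD: float = 4.0

_SCALE_MAX = 2.0


def criterion_grid(criterion: Criterion) -> tuple[float, ...]:
    """Valid score values for *criterion*, ascending."""
    step = criterion.step
    n = int(round(_SCALE_MAX / step))
    return tuple(i * step for i in range(n + 1))


def round_prediction(raw: float, criterion: Criterion) -> float:
    """Snap a continuous prediction onto the criterion's rating grid.

    The nearest grid point wins; exact midpoints round up (toward the
    higher score, i.e. toward flagging IHI rather than missing it), and
    the result is clamped to [0, 2].

    Raises
    ------
    ValueError
        If *raw* is NaN or infinite.
    """
    raw = float(raw)
    if not math.isfinite(raw):
        raise ValueError(f"prediction for {criterion.value} is not finite: {raw!r}")
    step = criterion.step
    snapped = math.floor(raw / step + 0.5) * step  # round half up on the grid
    return min(max(snapped, 0.0), _SCALE_MAX)


def _check_on_grid(value: float, criterion: Criterion) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{criterion.value} score is not finite: {value!r}")
    if abs(value - round_prediction(value, criterion)) > 1e-9:
        raise ValueError(
            f"{criterion.value} score {value} is not on its rating grid "
            f"(step {criterion.step})"
        )
    return value


def composite_score(scores: Mapping[Criterion, float]) -> float:
    """Sum the four criterion scores into the composite IHI score.

    Raises
    ------
    KeyError
        If any criterion is missing from *scores*.
    ValueError
        If a score is off its grid.
    """
    missing = [c.value for c in CRITERIA if c not in scores]
    if missing:
        raise KeyError(f"incomplete record, missing criteria: {missing}")
    return float(sum(_check_on_grid(scores[c], c) for c in CRITERIA))


def classify_ihi(composite: float) -> bool:
    """True iff *composite* meets the IHI threshold (>= 4)."""
    composite = float(composite)
    if not math.isfinite(composite) or not 0.0 <= composite <= 8.0:
        raise ValueError(f"composite score out of range [0, 8]: {composite!r}")
    return composite >= IHI_THRESHOLD


_COVARIATE_KEYS = ("age", "sex", "weight", "height", "handedness", "centre", "cohort")


@dataclass
class RatingRecord:
    """One subject x hemisphere's criterion scores plus covariates.

    ``composite`` is always derived from ``scores``; construct records via
    :meth:`from_scores` so the invariant cannot drift.
    """

    subject_id: str
    hemisphere: str  # "left" | "right"
    scores: dict[Criterion, float]
    composite: float
    rater_id: str = "unknown"
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        expected = composite_score(self.scores)
        if abs(self.composite - expected) > 1e-9:
            raise ValueError(
                f"composite {self.composite} != sum of criteria {expected}"
            )

    @classmethod
    def from_scores(
        cls,
        subject_id: str,
        hemisphere: str,
        scores: Mapping[Criterion, float],
        rater_id: str = "unknown",
        covariates: Mapping[str, object] | None = None,
    ) -> "RatingRecord":
        scores = {c: float(scores[c]) for c in CRITERIA}
        return cls(
            subject_id=subject_id,
            hemisphere=hemisphere,
            scores=scores,
            composite=composite_score(scores),
            rater_id=rater_id,
            covariates=dict(covariates or {}),
        )

    @property
    def ihi(self) -> bool:
        return classify_ihi(self.composite)


#: Column order of the ratings TSV dialect.
RATINGS_COLUMNS = [
    "subject_id",
    "hemisphere",
    "c1",
    "c2",
    "c3",
    "c5",
    "composite",
    "ihi_flag",
    "rater_id",
    "age",
    "sex",
    "weight",
    "height",
    "handedness",
    "centre",
    "cohort",
]


def records_to_frame(records: Iterable[RatingRecord]) -> pd.DataFrame:
    """Tabulate records in the ratings TSV dialect."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "hemisphere": r.hemisphere,
            "c1": r.scores[Criterion.C1],
            "c2": r.scores[Criterion.C2],
            "c3": r.scores[Criterion.C3],
            "c5": r.scores[Criterion.C5],
            "composite": r.composite,
            "ihi_flag": int(r.ihi),
            "rater_id": r.rater_id,
        }
        for key in _COVARIATE_KEYS:
            row[key] = r.covariates.get(key)
        rows.append(row)
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[RatingRecord]:
    """Inverse of :func:`records_to_frame`; validates grids and composites."""
    records = []
    for _, row in frame.iterrows():
        scores = {
            Criterion.C1: float(row["c1"]),
            Criterion.C2: float(row["c2"]),
            Criterion.C3: float(row["c3"]),
            Criterion.C5: float(row["c5"]),
        }
        covariates = {
            k: row[k] for k in _COVARIATE_KEYS if k in frame.columns and pd.notna(row[k])
        }
        records.append(
            RatingRecord.from_scores(
                subject_id=str(row["subject_id"]),
                hemisphere=str(row["hemisphere"]),
                scores=scores,
                rater_id=str(row.get("rater_id", "unknown")),
                covariates=covariates,
            )
        )
    return records


def read_ratings_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(RATINGS_COLUMNS[:8]) - set(frame.columns)
    if missing:
        raise ValueError(f"ratings table {path} lacks columns: {sorted(missing)}")
    return frame


def write_ratings_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
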