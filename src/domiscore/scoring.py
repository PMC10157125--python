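"""The Domiscore scoring engine.

Scoring one dwelling assessment proceeds in a fixed order:

1. *Vulnerability penalties* — for each occupant vulnerability present and
   each matrix rule it triggers (pre-penalty score >= trigger threshold),
   one point is added to the variable's score.  Adjusted scores are not
   capped: a variable rated 3 can become 4.
2. *Thematic scores* — each category takes the highest (poorest) score of
   its scored variables (aspiration-level aggregation); a category with no
   scored variable is *blank*.  Colors: 0 green, 1 yellow, 2 orange,
   >= 3 red.
3. *Missing-data penalty* — if any category is blank, the mean of the
   completed thematic scores is added, on the assumption that missing
   information more likely hides a poor situation.  Kept as an exact
   fraction until the final rounding.
4. *Global score* — sum of completed thematic scores plus the penalty,
   rounded to the closest whole number (ties away from zero).
5. *Equivalence class* — the global score is sorted into one of four
   traffic-light classes; for ``n`` themes the yellow/orange/red lower
   bounds are ``(floor(n/2)+1) * (1, 2, 3)``, i.e. 8/16/24 for 15 themes.
   The red class has no upper bound (penalties can exceed 3 * n).
6. *Alerts* — every scored variable at or above its alert threshold is
   flagged for reporting; scoring always continues past alerts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .grid import (
    SCORE_LEVELS,
    GridDefinition,
    Vulnerability,
    VulnerabilityMatrix,
)

MissingReason = Literal[
    "data_unavailable",
    "site_inaccessible",
    "diagnosis_unavailable",
    "description_unclear",
    "other",
]

MISSING_REASONS: tuple[str, ...] = (
    "data_unavailable",
    "site_inaccessible",
    "diagnosis_unavailable",
    "description_unclear",
    "other",
)

Color = Literal["green", "yellow", "orange", "red"]

PenaltyMode = Literal["single_mean", "mean_per_blank"]

#: Fields that would identify a person or an address; assessments are
#: anonymous by design and documents carrying these are rejected outright.
PII_FIELDS: frozenset[str] = frozenset(
    {
        "name",
        "first_name",
        "last_name",
        "surname",
        "occupant_name",
        "address",
        "street",
        "postal_code",
        "zip",
        "zipcode",
        "city_address",
        "phone",
        "telephone",
        "email",
        "national_id",
    }
)


class UnscorableError(ValueError):
    """Every thematic category is blank: the dwelling has no Domiscore."""


class VersionMismatchError(ValueError):
    """Assessment and grid (or matrix) declare different grid versions."""


class DwellingMeta(BaseModel):
    """Anonymous dwelling metadata recorded at the visit."""

    model_config = ConfigDict(extra="forbid")

    housing_type: Literal["collective", "individual"] = "collective"
    setting: Literal["urban", "rural"] = "urban"
    overseas: bool = False
    tenure: Literal["owner_occupant", "private_rental", "social_housing"] = "private_rental"
    typology: str = ""


class VisitMeta(BaseModel):
    """Optional visit timings, in minutes."""

    model_config = ConfigDict(extra="forbid")

    minutes_before: Optional[float] = None
    minutes_during: Optional[float] = None
    minutes_after: Optional[float] = None


class Assessment(BaseModel):
    """One dwelling visit: per-variable score (0-3) or missing-with-reason.

    ``entries`` maps each variable id either to an integer score or to a
    missing-reason code.  The schema forbids extra fields, which is also
    how personally identifying information is kept out structurally.
    """

    model_config = ConfigDict(extra="forbid")

    grid_version: str
    entries: dict[str, int | str] = Field(default_factory=dict)
    dwelling_meta: DwellingMeta = Field(default_factory=DwellingMeta)
    vulnerabilities: set[Vulnerability] = Field(default_factory=set)
    visit_meta: Optional[VisitMeta] = None

    @field_validator("entries")
    @classmethod
    def _entry_domain(cls, v: dict[str, int | str]) -> dict[str, int | str]:
        for vid, val in v.items():
            if isinstance(val, bool):
                raise ValueError(f"entry {vid!r}: boolean is not a score")
            if isinstance(val, int):
                if val not in SCORE_LEVELS:
                    raise ValueError(
                        f"entry {vid!r}: score {val} outside 0-3 (pre-penalty scores "
                        f"must lie in 0-3)"
                    )
            elif isinstance(val, str):
                if val not in MISSING_REASONS:
                    raise ValueError(
                        f"entry {vid!r}: unknown missing reason {val!r}; "
                        f"expected one of {MISSING_REASONS}"
                    )
            else:
                raise ValueError(f"entry {vid!r}: unsupported value {val!r}")
        return v

    def scored_entries(self) -> dict[str, int]:
        """The subset of entries that carry an actual score."""
        return {k: v for k, v in self.entries.items() if isinstance(v, int)}


def validate_assessment(assessment: Assessment, grid: GridDefinition) -> list[str]:
    """Cross-check an assessment against a grid; returns violations."""
    report: list[str] = []
    if assessment.grid_version != grid.version:
        report.append(
            f"assessment declares grid version {assessment.grid_version!r}, "
            f"grid is {grid.version!r}"
        )
    known = {v.id for v in grid.variables}
    for vid in assessment.entries:
        if vid not in known:
            report.append(f"entry references unknown variable {vid!r}")
    return report


# -- result types --------------------------------------------------------------


@dataclass(frozen=True)
class ThematicResult:
    """One category's aggregated score, color and provenance."""

    category_id: str
    score: Optional[int]
    color: Optional[str]
    blank: bool
    contributing_variable: Optional[str]


@dataclass(frozen=True)
class ClassBoundaries:
    """Lower bounds of the yellow, orange and red classes for ``n_themes``."""

    n_themes: int
    lower_bounds: tuple[int, int, int]

    def ranges(self) -> list[tuple[str, int, Optional[int]]]:
        """(class, low, high) rows; the red class has no upper bound."""
        y, o, r = self.lower_bounds
        return [
            ("green", 0, y - 1),
            ("yellow", y, o - 1),
            ("orange", o, r - 1),
            ("red", r, None),
        ]


@dataclass(frozen=True)
class DomiscoreResult:
    """The full outcome of scoring one assessment."""

    grid_version: str
    thematic: tuple[ThematicResult, ...]
    n_completed: int
    raw_sum: int
    penalty: Fraction
    global_score: int
    equivalence_class: str
    alerts: tuple[tuple[str, int], ...]
    completion_rate: float
    penalty_mode: str = "single_mean"


# -- elementary operations -----------------------------------------------------


def score_color(score: int) -> str:
    """Traffic-light color of an (adjusted) score: >= 3 is red."""
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    return ("green", "yellow", "orange")[score] if score < 3 else "red"


def apply_vulnerability_penalties(
    assessment: Assessment,
    matrix: Optional[VulnerabilityMatrix],
    grid: GridDefinition,
) -> dict[str, int]:
    """Adjusted per-variable scores after vulnerability penalties.

    For each scored variable and each present vulnerability whose rule's
    trigger threshold is reached by the *pre-penalty* score, one point is
    added.  Distinct vulnerabilities stack; rules never re-trigger on the
    adjusted score.  Missing entries stay missing (absent from the result).
    """
    problems = [p for p in validate_assessment(assessment, grid) if "unknown variable" in p]
    if problems:
        raise KeyError("; ".join(problems))
    base = assessment.scored_entries()
    adjusted = dict(base)
    if matrix is None or not assessment.vulnerabilities:
        return adjusted
    for rule in matrix.rules:
        if rule.vulnerability not in assessment.vulnerabilities:
            continue
        pre = base.get(rule.variable_id)
        if pre is not None and pre >= rule.trigger_threshold:
            adjusted[rule.variable_id] += rule.penalty_points
    return adjusted


def compute_thematic_scores(
    adjusted: dict[str, int], grid: GridDefinition
) -> list[ThematicResult]:
    """Per-category maximum over scored variables, in grid order.

    A category with no scored variable is blank; ties for the maximum go
    to the first variable in grid order.
    """
    results = []
    for cat in grid.categories:
        best_vid: Optional[str] = None
        best: Optional[int] = None
        for vid in cat.variable_ids:
            if vid in adjusted and (best is None or adjusted[vid] > best):
                best = adjusted[vid]
                best_vid = vid
        if best is None:
            results.append(ThematicResult(cat.id, None, None, True, None))
        else:
            results.append(ThematicResult(cat.id, best, score_color(best), False, best_vid))
    return results


def compute_missing_penalty(
    thematic: list[ThematicResult], penalty_mode: PenaltyMode = "single_mean"
) -> Fraction:
    """Exact missing-data penalty for a thematic profile.

    Zero when no category is blank; otherwise the mean of the completed
    thematic scores (``single_mean``), or that mean once per blank category
    (``mean_per_blank``, i.e. mean-imputation of the blanks).
    """
    completed = [t for t in thematic if not t.blank]
    n_blank = len(thematic) - len(completed)
    if not completed:
        raise UnscorableError("all thematic categories are blank; no Domiscore can be computed")
    if n_blank == 0:
        return Fraction(0)
    mean = Fraction(sum(t.score for t in completed), len(completed))
    if penalty_mode == "mean_per_blank":
        return mean * n_blank
    if penalty_mode != "single_mean":
        raise ValueError(f"unknown penalty_mode {penalty_mode!r}")
    return mean


def round_half_away(x: Fraction) -> int:
    """Round to the closest whole number, ties away from zero."""
    if x >= 0:
        return int((2 * x + 1) // 2)
    return -int((2 * (-x) + 1) // 2)


def compute_global_score(
    thematic: list[ThematicResult], penalty_mode: PenaltyMode = "single_mean"
) -> tuple[int, Fraction, int]:
    """``(raw_sum, penalty, global_score)`` for a thematic profile."""
    penalty = compute_missing_penalty(thematic, penalty_mode)
    raw_sum = sum(t.score for t in thematic if not t.blank)
    return raw_sum, penalty, round_half_away(raw_sum + penalty)


def class_boundaries(n_themes: int) -> ClassBoundaries:
    """Lower bounds of the yellow/orange/red classes: (floor(n/2)+1) * (1,2,3).

    With 15 themes this gives (8, 16, 24): half plus one of the themes
    scored red marks the entry of the red class.
    """
    if n_themes < 1:
        raise ValueError(f"n_themes must be >= 1, got {n_themes}")
    step = n_themes // 2 + 1
    return ClassBoundaries(n_themes, (step, 2 * step, 3 * step))


def classify(global_score: int, n_themes: int) -> str:
    """Equivalence class of a global score; red is unbounded above."""
    if global_score < 0:
        raise ValueError(f"global_score must be >= 0, got {global_score}")
    y, o, r = class_boundaries(n_themes).lower_bounds
    if global_score >= r:
        return "red"
    if global_score >= o:
        return "orange"
    if global_score >= y:
        return "yellow"
    return "green"


def detect_alerts(adjusted: dict[str, int], grid: GridDefinition) -> list[tuple[str, int]]:
    """Scored variables at or above their alert threshold, in grid order."""
    alerts = []
    for vid in grid.variable_ids:
        v = grid.variable(vid)
        if v.alert_threshold is None:
            continue
        score = adjusted.get(vid)
        if score is not None and score >= v.alert_threshold:
            alerts.append((vid, score))
    return alerts


def score_assessment(
    assessment: Assessment,
    grid: GridDefinition,
    matrix: Optional[VulnerabilityMatrix] = None,
    penalty_mode: PenaltyMode = "single_mean",
) -> DomiscoreResult:
    """Score one assessment end to end.

    Order of operations: vulnerability penalties, thematic maxima,
    missing-data penalty, global score, classification against the grid's
    own theme count, alert detection, completion rate.  Deterministic for
    fixed inputs.

    Raises :class:`VersionMismatchError` when the assessment does not
    declare the grid's version, and :class:`UnscorableError` when every
    category is blank.
    """
    if assessment.grid_version != grid.version:
        raise VersionMismatchError(
            f"assessment declares grid version {assessment.grid_version!r}, "
            f"grid is {grid.version!r}"
        )
    adjusted = apply_vulnerability_penalties(assessment, matrix, grid)
    thematic = compute_thematic_scores(adjusted, grid)
    raw_sum, penalty, global_score = compute_global_score(thematic, penalty_mode)
    return DomiscoreResult(
        grid_version=grid.version,
        thematic=tuple(thematic),
        n_completed=sum(1 for t in thematic if not t.blank),
        raw_sum=raw_sum,
        penalty=penalty,
        global_score=global_score,
        equivalence_class=classify(global_score, grid.n_themes),
        alerts=tuple(detect_alerts(adjusted, grid)),
        completion_rate=len(adjusted) / grid.n_variables,
        penalty_mode=penalty_mode,
    )
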