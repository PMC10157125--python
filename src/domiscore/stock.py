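"""Territory-level aggregation of scored assessments.

Aggregating many dwellings' global scores gives a picture of housing
quality at the scale of a territory: counts per traffic-light class,
moments of the global-score and completion-rate distributions, and the
per-theme color frequency table (the territory "profile").  Summaries are
per assessment (visit); deduplication by dwelling is the caller's concern
since assessments are anonymous by design.

Standard deviations use the sample (n-1) convention and are ``None`` for
a single assessment; this is recorded in the summary metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import GridDefinition, VulnerabilityMatrix
from .scoring import (
    Assessment,
    DomiscoreResult,
    VersionMismatchError,
    score_assessment,
)

COLOR_BINS = ("green", "yellow", "orange", "red", "blank")


def completion_rate(assessment: Assessment, grid: GridDefinition) -> float:
    """Fraction of grid variables actually scored, in [0, 1]."""
    return len(assessment.scored_entries()) / grid.n_variables


def percentage(numerator: int, denominator: int) -> int:
    """Share as a whole percent, rounded half away from zero.

    This is the convention used for printed descriptives such as
    participation or completion rates (e.g. 151/1266 -> 12).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    share = 100 * numerator / denominator
    return int(np.floor(share + 0.5)) if share >= 0 else -int(np.floor(-share + 0.5))


@dataclass(frozen=True)
class StockSummary:
    """Territory-level aggregate of a batch of scored assessments."""

    n_dwellings: int
    class_counts: dict[str, int]
    global_score_stats: dict[str, Optional[float]]
    completion_stats: dict[str, Optional[float]]
    theme_color_frequencies: dict[str, dict[str, int]]
    alert_count: int
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AgreementReport:
    """Reproducibility comparison of two assessments of the same dwelling."""

    n_compared_variables: int
    exact_agreement: Optional[float]
    per_category_score_delta: dict[str, Optional[int]]
    global_score_delta: int


def _mean_sd(values: Sequence[float]) -> tuple[float, Optional[float]]:
    # sorting makes the fold exactly permutation-invariant (float summation
    # is order-sensitive in the last bit)
    arr = np.sort(np.asarray(values, dtype=float))
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd


def summarize_stock(
    results: Sequence[DomiscoreResult],
    assessments: Sequence[Assessment],
    grid: GridDefinition,
) -> StockSummary:
    """Aggregate per-dwelling results into a :class:`StockSummary`.

    ``results`` and ``assessments`` must be parallel, non-empty and all on
    ``grid``'s version.  The aggregation is a pure fold: permuting the
    inputs (jointly) leaves the summary unchanged.
    """
    if not results:
        raise ValueError("cannot summarize an empty stock")
    if len(results) != len(assessments):
        raise ValueError("results and assessments must be parallel lists")
    for r in results:
        if r.grid_version != grid.version:
            raise VersionMismatchError(
                f"result on grid {r.grid_version!r} mixed into a "
                f"{grid.version!r} summary"
            )

    n = len(results)
    class_counts = {c: 0 for c in ("green", "yellow", "orange", "red")}
    for r in results:
        class_counts[r.equivalence_class] += 1

    g_mean, g_sd = _mean_sd([r.global_score for r in results])
    scores = [r.global_score for r in results]
    c_mean, c_sd = _mean_sd([completion_rate(a, grid) for a in assessments])

    theme_freq = {
        cat.id: {c: 0 for c in COLOR_BINS} for cat in grid.categories
    }
    for r in results:
        for t in r.thematic:
            theme_freq[t.category_id]["blank" if t.blank else t.color] += 1

    return StockSummary(
        n_dwellings=n,
        class_counts=class_counts,
        global_score_stats={
            "mean": g_mean,
            "sd": g_sd,
            "min": float(min(scores)),
            "max": float(max(scores)),
        },
        completion_stats={"mean": c_mean, "sd": c_sd},
        theme_color_frequencies=theme_freq,
        alert_count=sum(len(r.alerts) for r in results),
        metadata={
            "grid_version": grid.version,
            "sd_convention": "sample (n-1); None for n=1",
            "penalty_mode": results[0].penalty_mode,
        },
    )


def compare_assessments(
    a: Assessment,
    b: Assessment,
    grid: GridDefinition,
    matrix: Optional[VulnerabilityMatrix] = None,
) -> AgreementReport:
    """Agreement between two visits of the same dwelling.

    Exact agreement is computed over the variables scored in *both*
    assessments (``None`` when that set is empty); thematic and global
    deltas are signed ``a - b`` differences of the two full Domiscore
    results, so ``compare(b, a)`` flips only the signs.
    """
    if a.grid_version != b.grid_version or a.grid_version != grid.version:
        raise VersionMismatchError(
            "both assessments must declare the grid's version "
            f"({a.grid_version!r}, {b.grid_version!r} vs {grid.version!r})"
        )
    sa, sb = a.scored_entries(), b.scored_entries()
    common = sorted(set(sa) & set(sb), key=grid.variable_ids.index)
    agreement = (
        sum(1 for vid in common if sa[vid] == sb[vid]) / len(common) if common else None
    )

    ra = score_assessment(a, grid, matrix)
    rb = score_assessment(b, grid, matrix)
    deltas: dict[str, Optional[int]] = {}
    for ta, tb in zip(ra.thematic, rb.thematic):
        if ta.blank or tb.blank:
            deltas[ta.category_id] = None
        else:
            deltas[ta.category_id] = ta.score - tb.score
    return AgreementReport(
        n_compared_variables=len(common),
        exact_agreement=agreement,
        per_category_score_delta=deltas,
        global_score_delta=ra.global_score - rb.global_score,
    )
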