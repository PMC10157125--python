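"""Reproducible synthetic dwellings, assessments and housing stocks.

No real visit data exists for this instrument, so every downstream module
is exercised on synthetic assessments.  A :class:`QualityProfile` drives
one dwelling: per-variable ordinal scores are drawn from a categorical
distribution over the levels 0-3, each variable is independently left
unscored with probability ``missingness`` (with a missing-reason drawn
from configurable weights), occupant vulnerabilities are drawn per-kind,
and dwelling metadata follows a configurable mixture.

Default metadata mixtures echo the instrument's 28-visit test phase
(71% urban, 68% collective housing, tenure 46/32/22% private rental /
social housing / owner-occupant, 9/28 overseas) and the default 9%
missingness matches the observed 91% mean completion rate.  Scores are
independent across variables by default; an optional within-category
correlation knob shares a latent draw per category, since real housing
deficiencies cluster by theme.

All randomness flows through ``numpy.random.Generator`` seeded from
integers only, so identical seeds give identical stocks on any platform.
Per-dwelling generators are derived with ``SeedSequence(seed).spawn``,
so extending a stock never reshuffles earlier dwellings.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .grid import VULNERABILITIES, GridDefinition
from .scoring import MISSING_REASONS, Assessment, DwellingMeta

#: Missing-reason weights echoing the reported reasons for the unscored 9%
#: of variables: data unavailability dominant, then on-site complexity,
#: unclear descriptions, and a residual.
DEFAULT_REASON_WEIGHTS: dict[str, float] = {
    "data_unavailable": 4 / 9,
    "diagnosis_unavailable": 1 / 9,
    "site_inaccessible": 2 / 9,
    "description_unclear": 1 / 9,
    "other": 1 / 9,
}

DEFAULT_META_MIX: dict[str, dict[str, float]] = {
    "housing_type": {"collective": 19 / 28, "individual": 9 / 28},
    "setting": {"urban": 20 / 28, "rural": 8 / 28},
    "tenure": {
        "private_rental": 13 / 28,
        "social_housing": 9 / 28,
        "owner_occupant": 6 / 28,
    },
}

#: Probability the dwelling lies overseas (9 of the 28 test visits).
DEFAULT_OVERSEAS_P = 9 / 28


class QualityProfile(BaseModel):
    """Distributional description of one kind of dwelling."""

    model_config = ConfigDict(extra="forbid")

    name: str
    level_weights: tuple[float, float, float, float]
    missingness: float = Field(default=0.09, ge=0.0, le=1.0)
    vulnerability_prevalence: dict[str, float] = Field(default_factory=dict)
    reason_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_REASON_WEIGHTS)
    )
    meta_mix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_META_MIX.items()}
    )
    overseas_p: float = Field(default=DEFAULT_OVERSEAS_P, ge=0.0, le=1.0)
    category_correlation: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("level_weights")
    @classmethod
    def _weights_simplex(cls, v):
        if any(w < 0 for w in v):
            raise ValueError("level_weights must be non-negative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"level_weights must sum to 1, got {sum(v)}")
        return v

    @field_validator("vulnerability_prevalence")
    @classmethod
    def _prevalence_domain(cls, v):
        for k, p in v.items():
            if k not in VULNERABILITIES:
                raise ValueError(f"unknown vulnerability {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {k!r} outside [0, 1]: {p}")
        return v

    @field_validator("reason_weights")
    @classmethod
    def _reasons_simplex(cls, v):
        for k in v:
            if k not in MISSING_REASONS:
                raise ValueError(f"unknown missing reason {k!r}")
        total = sum(v.values())
        if any(w < 0 for w in v.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("reason_weights must be a probability vector")
        return v


def favorable_profile(**overrides) -> QualityProfile:
    """Mostly level-0/1 dwellings (sound housing stock)."""
    return QualityProfile(
        name="favorable", level_weights=(0.70, 0.22, 0.06, 0.02), **overrides
    )


def mixed_profile(**overrides) -> QualityProfile:
    """Mid-range dwellings with occasional severe deficiencies."""
    return QualityProfile(
        name="mixed", level_weights=(0.35, 0.35, 0.20, 0.10), **overrides
    )


def degraded_profile(**overrides) -> QualityProfile:
    """Substandard dwellings: mass shifted toward levels 2-3."""
    return QualityProfile(
        name="degraded", level_weights=(0.10, 0.20, 0.35, 0.35), **overrides
    )


BUILTIN_PROFILES = {
    "favorable": favorable_profile,
    "mixed": mixed_profile,
    "degraded": degraded_profile,
}


class StockSpec(BaseModel):
    """A housing stock to simulate: size, profile mixture and seed."""

    model_config = ConfigDict(extra="forbid")

    n_dwellings: int = Field(ge=1)
    profile_mixture: list[tuple[float, QualityProfile]]
    seed: int = 0

    @model_validator(mode="after")
    def _mixture_simplex(self) -> "StockSpec":
        if not self.profile_mixture:
            raise ValueError("profile_mixture must be non-empty")
        weights = [w for w, _ in self.profile_mixture]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        return self


def _choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    p = np.asarray([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def generate_assessment(
    grid: GridDefinition,
    profile: QualityProfile,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Assessment:
    """Draw one synthetic assessment of ``grid`` from ``profile``.

    Identical ``(grid, profile, seed)`` always yields an identical
    assessment.  Pass ``rng`` instead of ``seed`` to draw from an existing
    generator stream.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    levels = np.asarray(profile.level_weights, dtype=float)
    levels = levels / levels.sum()

    entries: dict[str, int | str] = {}
    for cat in grid.categories:
        # optional shared latent severity: with prob rho a variable copies
        # the category's common draw instead of its own
        common = int(rng.choice(4, p=levels))
        for vid in cat.variable_ids:
            if profile.missingness > 0 and rng.random() < profile.missingness:
                entries[vid] = _choice(rng, profile.reason_weights)
                continue
            own = int(rng.choice(4, p=levels))
            if profile.category_correlation > 0 and rng.random() < profile.category_correlation:
                entries[vid] = common
            else:
                entries[vid] = own

    vulnerabilities = {
        v
        for v in VULNERABILITIES
        if rng.random() < profile.vulnerability_prevalence.get(v, 0.0)
    }
    meta = DwellingMeta(
        housing_type=_choice(rng, profile.meta_mix["housing_type"]),
        setting=_choice(rng, profile.meta_mix["setting"]),
        overseas=bool(rng.random() < profile.overseas_p),
        tenure=_choice(rng, profile.meta_mix["tenure"]),
    )
    return Assessment(
        grid_version=grid.version,
        entries=entries,
        dwelling_meta=meta,
        vulnerabilities=vulnerabilities,
    )


def generate_stock(grid: GridDefinition, spec: StockSpec) -> list[Assessment]:
    """Simulate ``spec.n_dwellings`` assessments of ``grid``.

    Dwelling ``i`` uses the ``i``-th child of ``SeedSequence(spec.seed)``,
    so the first ``k`` dwellings of a larger stock equal the stock of size
    ``k`` drawn from the same seed.
    """
    profiles: Sequence[QualityProfile] = [p for _, p in spec.profile_mixture]
    weights = np.asarray([w for w, _ in spec.profile_mixture], dtype=float)
    weights = weights / weights.sum()

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_dwellings)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        profile = profiles[rng.choice(len(profiles), p=weights)]
        out.append(generate_assessment(grid, profile, rng=rng))
    return out
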