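"""Definition, validation and serialization of the Domiscore instrument.

The Domiscore grid is a versioned multi-criteria instrument: a set of
ordinal variables (each scored 0 = most favorable to 3 = most unfavorable)
grouped into thematic categories (indoor air, noise, lighting, ...).  Some
variables additionally carry an *alert threshold*: the level at or above
which the situation must be reported to the competent authorities.  A
companion *vulnerability matrix* lists the (occupant vulnerability,
variable) pairs for which one penalty point is added to the variable's
score once it reaches a trigger level.

Two grid versions are packaged as documented reconstructions:

* ``"2020-01"`` — the pre-testing grid: 47 variables in 15 categories;
* ``"2020-11"`` — the post-testing grid: 46 variables in 16 categories,
  with nine alert variables.

Grids and matrices are plain JSON (or YAML) documents; see
``domiscore/data/schemas`` for the published JSON Schemas.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

SourceTag = Literal["in_situ", "mandatory_diagnostic", "open_data", "occupant_report"]

Vulnerability = Literal[
    "young_children_u4",
    "elderly_o70",
    "physical_disability",
    "visual_disability",
    "hearing_disability",
]

VULNERABILITIES: tuple[str, ...] = (
    "young_children_u4",
    "elderly_o70",
    "physical_disability",
    "visual_disability",
    "hearing_disability",
)

#: Score levels a variable may take before penalties are applied.
SCORE_LEVELS: tuple[int, ...] = (0, 1, 2, 3)


class GridError(ValueError):
    """A grid or matrix document failed validation."""


class VariableDefinition(BaseModel):
    """One scorable housing characteristic.

    ``level_descriptions`` must describe exactly the four ordinal levels
    0-3; ``alert_threshold``, when set, is the level (1, 2 or 3) at which
    reporting to authorities is required.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    category_id: str
    position: int = Field(ge=1)
    sources: list[SourceTag] = Field(min_length=1)
    level_descriptions: dict[int, str]
    alert_threshold: Optional[int] = None
    notes: str = ""

    @field_validator("level_descriptions")
    @classmethod
    def _levels_cover_0_to_3(cls, v: dict[int, str], info) -> dict[int, str]:
        if set(v) != set(SCORE_LEVELS):
            raise ValueError(
                f"level_descriptions must cover exactly levels 0-3, got {sorted(v)}"
            )
        return v

    @field_validator("alert_threshold")
    @classmethod
    def _threshold_domain(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v not in (1, 2, 3):
            raise ValueError(f"alert_threshold must be in {{1, 2, 3}}, got {v}")
        return v


class CategoryDefinition(BaseModel):
    """A thematic category: an ordered, non-empty group of variables."""

    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    variable_ids: list[str] = Field(min_length=1)


class GridDefinition(BaseModel):
    """A versioned Domiscore grid: ordered categories plus their variables."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = "1"
    version: str
    note: str = ""
    categories: list[CategoryDefinition]
    variables: list[VariableDefinition]

    @model_validator(mode="after")
    def _cross_check(self) -> "GridDefinition":
        var_ids = [v.id for v in self.variables]
        dup = _duplicates(var_ids)
        if dup:
            raise ValueError(f"duplicate variable ids: {sorted(dup)}")
        cat_ids = [c.id for c in self.categories]
        dup = _duplicates(cat_ids)
        if dup:
            raise ValueError(f"duplicate category ids: {sorted(dup)}")
        cat_set = set(cat_ids)
        for v in self.variables:
            if v.category_id not in cat_set:
                raise ValueError(
                    f"variable {v.id!r} references unknown category {v.category_id!r}"
                )
        # membership lists must partition the variable set
        listed: list[str] = []
        for c in self.categories:
            for vid in c.variable_ids:
                if vid not in set(var_ids):
                    raise ValueError(
                        f"category {c.id!r} lists unknown variable {vid!r}"
                    )
                listed.append(vid)
        dup = _duplicates(listed)
        if dup:
            raise ValueError(f"variables listed in more than one category: {sorted(dup)}")
        if set(listed) != set(var_ids):
            missing = set(var_ids) - set(listed)
            raise ValueError(f"variables not listed in any category: {sorted(missing)}")
        for c in self.categories:
            for vid in c.variable_ids:
                if self.variable(vid).category_id != c.id:
                    raise ValueError(
                        f"variable {vid!r} listed under {c.id!r} but declares "
                        f"category {self.variable(vid).category_id!r}"
                    )
        return self

    # -- convenience accessors -------------------------------------------------

    def variable(self, variable_id: str) -> VariableDefinition:
        try:
            return self._by_id[variable_id]
        except KeyError:
            raise KeyError(f"unknown variable id {variable_id!r}") from None

    @property
    def _by_id(self) -> dict[str, VariableDefinition]:
        return {v.id: v for v in self.variables}

    @property
    def variable_ids(self) -> list[str]:
        """Variable ids in grid (position) order."""
        return [v.id for v in sorted(self.variables, key=lambda v: v.position)]

    @property
    def n_themes(self) -> int:
        return len(self.categories)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def category_variables(self, category_id: str) -> list[str]:
        for c in self.categories:
            if c.id == category_id:
                return list(c.variable_ids)
        raise KeyError(f"unknown category id {category_id!r}")


class VulnerabilityRule(BaseModel):
    """One penalty rule: +1 point on ``variable_id`` when the named
    vulnerability is present and the pre-penalty score reaches
    ``trigger_threshold``."""

    model_config = ConfigDict(extra="forbid")

    vulnerability: Vulnerability
    variable_id: str
    trigger_threshold: int
    penalty_points: Literal[1] = 1
    note: str = ""

    @field_validator("trigger_threshold")
    @classmethod
    def _threshold_domain(cls, v: int) -> int:
        if v not in (1, 2, 3):
            raise ValueError(f"trigger_threshold must be in {{1, 2, 3}}, got {v}")
        return v


class VulnerabilityMatrix(BaseModel):
    """The full rule table for a given grid version."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = "1"
    grid_version: str
    note: str = ""
    rules: list[VulnerabilityRule] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_pairs(self) -> "VulnerabilityMatrix":
        pairs = [(r.vulnerability, r.variable_id) for r in self.rules]
        dup = _duplicates(pairs)
        if dup:
            raise ValueError(f"duplicate (vulnerability, variable) rules: {sorted(dup)}")
        return self


def _duplicates(items) -> set:
    seen: set = set()
    dups: set = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


# -- loading / serialization ---------------------------------------------------


def _read_document(source) -> dict:
    """Accept a dict, a JSON/YAML string, or a path to a .json/.yaml file."""
    if isinstance(source, dict):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    elif isinstance(source, str):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError:
            doc = yaml.safe_load(source)
    else:
        raise GridError(f"cannot read grid document from {type(source).__name__}")
    if not isinstance(doc, dict):
        raise GridError("grid document must be a mapping at top level")
    return doc


def load_grid(source) -> GridDefinition:
    """Parse and validate a grid document (dict, JSON/YAML text, or path).

    Raises :class:`GridError` naming the offending element on any violation
    (duplicate ids, unknown category references, level descriptions not
    covering 0-3, ...).
    """
    doc = _read_document(source)
    try:
        return GridDefinition.model_validate(doc)
    except ValidationError as exc:
        raise GridError(str(exc)) from exc


def load_matrix(source) -> VulnerabilityMatrix:
    """Parse and validate a vulnerability-matrix document."""
    doc = _read_document(source)
    try:
        return VulnerabilityMatrix.model_validate(doc)
    except ValidationError as exc:
        raise GridError(str(exc)) from exc


def serialize_grid(grid: GridDefinition, path: Optional[Path] = None) -> str:
    """Render a grid back to its canonical JSON document form."""
    text = json.dumps(grid.model_dump(mode="json"), indent=1, ensure_ascii=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def validate_matrix(matrix: VulnerabilityMatrix | dict, grid: GridDefinition) -> list[str]:
    """Cross-check a matrix against a grid; returns a list of violations
    (empty when consistent).  Violations are reported, never raised.

    Accepts either a validated :class:`VulnerabilityMatrix` or a raw
    document, so structurally illegal rules (e.g. a trigger threshold of
    0) are listed rather than raised.
    """
    report: list[str] = []
    known = {v.id for v in grid.variables}
    if isinstance(matrix, dict):
        if matrix.get("grid_version") != grid.version:
            report.append(
                f"matrix targets grid version {matrix.get('grid_version')!r}, "
                f"grid is {grid.version!r}"
            )
        for i, raw in enumerate(matrix.get("rules", [])):
            try:
                rule = VulnerabilityRule.model_validate(raw)
            except ValidationError as exc:
                report.append(f"rule {i}: {exc.errors()[0]['msg']}")
                continue
            if rule.variable_id not in known:
                report.append(
                    f"rule ({rule.vulnerability}, {rule.variable_id}) "
                    "targets unknown variable"
                )
        return report
    if matrix.grid_version != grid.version:
        report.append(
            f"matrix targets grid version {matrix.grid_version!r}, "
            f"grid is {grid.version!r}"
        )
    for r in matrix.rules:
        if r.variable_id not in known:
            report.append(
                f"rule ({r.vulnerability}, {r.variable_id}) targets unknown variable"
            )
    return report


def alert_variables(grid: GridDefinition) -> list[tuple[str, int]]:
    """Variables that trigger a report to authorities, in grid order,
    as ``(variable_id, alert_threshold)`` pairs."""
    out = []
    for vid in grid.variable_ids:
        v = grid.variable(vid)
        if v.alert_threshold is not None:
            out.append((v.id, v.alert_threshold))
    return out


# -- packaged fixtures ---------------------------------------------------------

GRID_VERSIONS = ("2020-01", "2020-11")


def load_packaged_grid(version: str = "2020-11") -> GridDefinition:
    """Load one of the packaged grid reconstructions ("2020-01" or "2020-11")."""
    if version not in GRID_VERSIONS:
        raise GridError(f"no packaged grid for version {version!r}; have {GRID_VERSIONS}")
    text = resources.files("domiscore.data").joinpath(f"grid_{version}.json").read_text(
        encoding="utf-8"
    )
    return load_grid(json.loads(text))


def load_packaged_matrix() -> VulnerabilityMatrix:
    """Load the packaged exemplar vulnerability matrix (grid 2020-11)."""
    text = (
        resources.files("domiscore.data")
        .joinpath("vulnerability_matrix_2020-11.json")
        .read_text(encoding="utf-8")
    )
    return load_matrix(json.loads(text))
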