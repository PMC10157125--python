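"""File formats: assessment JSON, batch CSV, result documents, YAML specs.

Batch CSV layout (UTF-8, comma-separated, header mandatory): one row per
dwelling with metadata columns (``assessment_id``, ``housing_type``,
``setting``, ``overseas``, ``tenure``, ``typology``), one 0/1 column per
vulnerability kind (``vuln_<kind>``), and one column per grid variable id
holding either a score 0-3 or a missing-reason code — never an empty cell,
so "unscored" stays distinct from "column absent".

Result documents carry the missing-data penalty both as an exact fraction
string (``"18/12"``) and as a decimal.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .grid import VULNERABILITIES, GridDefinition
from .scoring import PII_FIELDS, Assessment, DomiscoreResult, DwellingMeta
from .synthetic import BUILTIN_PROFILES, QualityProfile, StockSpec

META_COLUMNS = ("assessment_id", "housing_type", "setting", "overseas", "tenure", "typology")


class PIIViolation(ValueError):
    """The document carries a field that could identify a person or address."""


def check_pii(doc: dict) -> list[str]:
    """Names of forbidden personally-identifying fields found in ``doc``."""
    found = [k for k in doc if k.lower() in PII_FIELDS]
    meta = doc.get("dwelling_meta")
    if isinstance(meta, dict):
        found += [f"dwelling_meta.{k}" for k in meta if k.lower() in PII_FIELDS]
    return found


def assessment_to_dict(assessment: Assessment) -> dict:
    doc = assessment.model_dump(mode="json", exclude_none=True)
    doc["vulnerabilities"] = sorted(assessment.vulnerabilities)
    return doc


def load_assessment(source: str | Path | dict) -> Assessment:
    """Read one assessment from a JSON document, rejecting PII fields."""
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = source
    pii = check_pii(doc)
    if pii:
        raise PIIViolation(
            f"assessment carries identifying field(s) {pii}; "
            "assessments are anonymous by design"
        )
    return Assessment.model_validate(doc)


def save_assessment(assessment: Assessment, path: Path) -> None:
    Path(path).write_text(
        json.dumps(assessment_to_dict(assessment), indent=1, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


# -- batch CSV -----------------------------------------------------------------


def assessments_to_frame(assessments: Sequence[Assessment], grid: GridDefinition) -> pd.DataFrame:
    """Batch table: one row per assessment, one column per variable id."""
    rows = []
    for i, a in enumerate(assessments):
        row: dict = {
            "assessment_id": f"A{i:05d}",
            "housing_type": a.dwelling_meta.housing_type,
            "setting": a.dwelling_meta.setting,
            "overseas": int(a.dwelling_meta.overseas),
            "tenure": a.dwelling_meta.tenure,
            "typology": a.dwelling_meta.typology,
        }
        for v in VULNERABILITIES:
            row[f"vuln_{v}"] = int(v in a.vulnerabilities)
        for vid in grid.variable_ids:
            row[vid] = a.entries.get(vid, "data_unavailable")
        rows.append(row)
    return pd.DataFrame(rows)


def write_batch_csv(assessments: Sequence[Assessment], grid: GridDefinition, path: Path) -> None:
    assessments_to_frame(assessments, grid).to_csv(path, index=False)


def read_batch_csv(path: Path, grid: GridDefinition) -> list[Assessment]:
    """Parse a batch CSV back into assessments (PII columns rejected)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    pii = [c for c in df.columns if c.lower() in PII_FIELDS]
    if pii:
        raise PIIViolation(f"batch CSV carries identifying column(s) {pii}")
    known = set(grid.variable_ids)
    var_cols = [c for c in df.columns if c in known]
    out = []
    for _, row in df.iterrows():
        entries: dict[str, int | str] = {}
        for vid in var_cols:
            raw = str(row[vid]).strip()
            if raw == "":
                continue
            try:
                entries[vid] = int(float(raw))
            except ValueError:
                entries[vid] = raw
        vulnerabilities = {
            v for v in VULNERABILITIES if str(row.get(f"vuln_{v}", "0")).strip() in ("1", "True", "true")
        }
        meta = DwellingMeta(
            housing_type=str(row.get("housing_type", "collective")) or "collective",
            setting=str(row.get("setting", "urban")) or "urban",
            overseas=str(row.get("overseas", "0")).strip() in ("1", "True", "true"),
            tenure=str(row.get("tenure", "private_rental")) or "private_rental",
            typology=str(row.get("typology", "")),
        )
        out.append(
            Assessment(
                grid_version=grid.version,
                entries=entries,
                dwelling_meta=meta,
                vulnerabilities=vulnerabilities,
            )
        )
    return out


# -- results -------------------------------------------------------------------


def fraction_str(f: Fraction) -> str:
    return f"{f.numerator}/{f.denominator}" if f.denominator != 1 else str(f.numerator)


def result_to_dict(result: DomiscoreResult) -> dict:
    return {
        "grid_version": result.grid_version,
        "penalty_mode": result.penalty_mode,
        "thematic": [
            {
                "category_id": t.category_id,
                "score": t.score,
                "color": t.color,
                "blank": t.blank,
                "contributing_variable": t.contributing_variable,
            }
            for t in result.thematic
        ],
        "n_completed": result.n_completed,
        "raw_sum": result.raw_sum,
        "penalty": fraction_str(result.penalty),
        "penalty_decimal": float(result.penalty),
        "global_score": result.global_score,
        "equivalence_class": result.equivalence_class,
        "alerts": [list(a) for a in result.alerts],
        "completion_rate": result.completion_rate,
    }


def save_result(result: DomiscoreResult, path: Path) -> None:
    Path(path).write_text(
        json.dumps(result_to_dict(result), indent=1, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def results_to_frame(
    results: Sequence[Optional[DomiscoreResult]],
    errors: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    """Batch result table; rows whose result is None carry the error text."""
    errors = errors or {}
    rows = []
    for i, r in enumerate(results):
        if r is None:
            rows.append(
                {"assessment_id": f"A{i:05d}", "error": errors.get(i, "unscorable")}
            )
            continue
        rows.append(
            {
                "assessment_id": f"A{i:05d}",
                "global_score": r.global_score,
                "equivalence_class": r.equivalence_class,
                "raw_sum": r.raw_sum,
                "penalty": fraction_str(r.penalty),
                "penalty_decimal": float(r.penalty),
                "n_completed": r.n_completed,
                "completion_rate": r.completion_rate,
                "n_alerts": len(r.alerts),
                "error": "",
            }
        )
    return pd.DataFrame(rows)


# -- YAML specs ----------------------------------------------------------------


def load_profile(source: str | Path | dict) -> QualityProfile:
    """A profile from YAML/JSON, or a builtin name (favorable/mixed/degraded)."""
    if isinstance(source, str) and source in BUILTIN_PROFILES:
        return BUILTIN_PROFILES[source]()
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        doc = source
    return QualityProfile.model_validate(doc)


def load_stock_spec(source: str | Path | dict) -> StockSpec:
    """A stock spec from YAML/JSON; profiles may be builtin names."""
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        doc = dict(source)
    mixture = []
    for item in doc.get("profile_mixture", []):
        if isinstance(item, dict):
            weight = item["weight"]
            prof = item["profile"]
        else:
            weight, prof = item
        if isinstance(prof, str):
            prof = BUILTIN_PROFILES[prof]()
        else:
            prof = QualityProfile.model_validate(prof)
        mixture.append((float(weight), prof))
    return StockSpec(
        n_dwellings=int(doc["n_dwellings"]),
        profile_mixture=mixture,
        seed=int(doc.get("seed", 0)),
    )
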