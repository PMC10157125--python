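# domiscore

A scoring engine for the **Domiscore**, a multi-criteria instrument that
rates a dwelling's impact on the health and well-being of its occupants.
It is aimed at housing and public-health professionals (hygiene services,
housing inspectors, social workers, territory planners) who need a
standardized, anonymous, traffic-light summary of a home visit — and at
anyone who wants to aggregate many visits into a picture of a housing
stock.

## The instrument

A dwelling is described by 46 ordinal variables (47 in the initial grid
version) — ventilation, mold, noise at night, natural light, electrical
safety, access to basic services, … — each scored

> 0 (most favorable) · 1 · 2 · 3 (most unfavorable)

and grouped into 16 thematic categories (15 initially). Scoring proceeds
in two steps:

1. **Thematic scores** (aspiration-level aggregation). Each category takes
   the *highest (poorest)* score of its scored variables, color-coded
   0 = green, 1 = yellow, 2 = orange, ≥3 = red; a category with no scored
   variable stays blank (white).
2. **Global score.** The arithmetic sum of the thematic scores, adjusted by
   two penalties:
   * **Vulnerability penalty** — one point is added to a variable when a
     vulnerable occupant (young child < 4, elderly > 70, physical, visual
     or hearing disability) is present and the variable reaches a
     rule-specific trigger level (e.g. ventilation rated 3 with young
     children becomes 4). Adjusted scores are not capped at 3.
   * **Missing-data penalty** — if any category is blank, the mean of the
     completed thematic scores is added, on the assumption that missing
     information more likely hides a poor situation. The sum is rounded to
     the closest whole number (ties away from zero).

The global score runs from 0 to 45 (15 themes) or 48 (16 themes), more if
penalties apply, and is sorted into one of four equivalence classes. For
`n` themes the yellow/orange/red lower bounds are `(⌊n/2⌋+1)·(1, 2, 3)`;
with 15 themes: **0–7 green, 8–15 yellow, 16–23 orange, ≥24 red**.

Some variables carry an **alert threshold**: a score at or above it flags a
situation that must be reported to the authorities (nine variables in the
final grid). Scoring always continues past alerts.

Assessments are **anonymous by design**: documents carrying a name,
address or similar field are rejected at validation.

## Worked example

```python
from domiscore import (Assessment, load_packaged_grid, load_packaged_matrix,
                       score_assessment)

grid = load_packaged_grid("2020-11")      # 46 variables, 16 categories
matrix = load_packaged_matrix()           # vulnerability-penalty rules

entries = {v: 0 for v in grid.variable_ids}
entries.update({"ventilation": 3, "mold": 2, "noise_night": 2, "heating": 1})
for v in grid.category_variables("outdoor_pollution"):   # open data unreachable
    entries[v] = "data_unavailable"

visit = Assessment(grid_version="2020-11", entries=entries,
                   vulnerabilities={"young_children_u4"})
r = score_assessment(visit, grid, matrix)
print(r.raw_sum, r.penalty, r.global_score, r.equivalence_class)
```

prints

```
7 7/15 7 green
```

Ventilation rated 3 with young children present is downgraded to 4, so the
indoor-air theme is red with a thematic score of 4; noise is orange and
temperature yellow; the blank outdoor-pollution category adds the mean of
the 15 completed thematic scores, 7/15 ≈ 0.47, and 7.47 rounds to a global
score of 7 — the last score still in the green class. The completion rate
is 42/46 ≈ 0.913.

The same engine is available from the shell:

```bash
domiscore boundaries 15                      # class ranges for 15 themes
domiscore validate --matrix packaged         # check the packaged documents
domiscore simulate --n 28 --seed 1 --out stock.csv
domiscore summarize --matrix packaged --format text --out report.txt stock.csv
```

`simulate` draws synthetic dwellings from quality profiles (favorable /
mixed / degraded) with configurable missingness, vulnerability prevalence
and metadata mixtures; `summarize` aggregates a scored batch into a
territory report (class counts, score and completion statistics, per-theme
color frequencies).

## Notes

The packaged grids are *documented reconstructions* of the instrument's
two published versions (the legally authoritative French wording is not
reproduced); the vulnerability matrix ships the two documented rules plus
clearly flagged synthetic placeholders. See `docs/methods.md` for the
scoring conventions, generator calibration and known limitations.
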