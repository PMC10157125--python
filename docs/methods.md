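# Methods

## The scoring model

The Domiscore is a multi-criteria sorting instrument. Each of the grid's
variables is an ordinal judgment on a four-level scale, 0 (most favorable
to health) to 3 (most unfavorable), gathered from four kinds of sources:
in-situ observation, mandatory diagnostics, open-access data, and the
occupants' reported experience. The model makes three deliberate
simplifications:

* **No weights.** Categories and variables are unweighted: no robust
  evidence ranks one housing hazard's health importance above another's at
  this granularity.
* **Aspiration-level (max) aggregation within themes.** A theme is only as
  good as its worst scored variable. This makes thematic scores sensitive
  to single severe deficiencies and insensitive to the number of mild
  ones — intended behavior for a screening tool.
* **Additive aggregation across themes.** The global score is the plain
  sum of thematic scores, so it is monotone in every variable.

### Penalties

**Vulnerability penalties** encode interactions between housing defects
and occupant frailty. A rule is a triple (vulnerability, variable, trigger
level in {1,2,3}); when the occupant vulnerability is present and the
variable's *pre-penalty* score reaches the trigger, one point is added.
Conventions chosen where the published description is silent:

* rules are evaluated against pre-penalty scores only — no cascading
  re-triggering (the rule table is a lookup, not an iterative process);
* distinct vulnerabilities can each add a point to the same variable;
* adjusted scores are **not capped** at 3: a variable rated 3 can become
  4, a thematic score can exceed 3 (still colored red), and the red class
  is open-ended. This is the only reading consistent with the published
  score range "45 … or more if penalties are applied".

**Missing-data penalty.** A category is *blank* iff none of its variables
is scored; a category with at least one scored variable is completed and
its maximum is taken over scored variables only. When at least one
category is blank, the mean of the completed thematic scores
(`raw_sum / n_completed`) is added to the sum — the pessimistic assumption
that missing information hides poor conditions. The default
`penalty_mode="single_mean"` adds the mean once regardless of how many
categories are blank, implementing the published formula literally;
`penalty_mode="mean_per_blank"` (mean × number of blank categories,
equivalent to mean-imputing each blank theme) is provided for users who
read the rule as per-category. An assessment in which *every* category is
blank raises `UnscorableError` rather than scoring 0: an unvisitable
dwelling has no Domiscore.

The penalty is kept as an exact `fractions.Fraction` until the final
rounding, and exported both as a fraction string (`"18/12"`) and a
decimal. **Rounding** of `raw_sum + penalty` is to the closest whole
number with ties away from zero (19.5 → 20): since the penalty encodes
suspicion of worse conditions, ties resolve pessimistically. Implemented
in integer arithmetic, so no float tie-breaking is involved.

### Equivalence classes

For `n` themes the yellow, orange and red lower bounds are
`(⌊n/2⌋+1)·k`, `k = 1, 2, 3` — "half plus one of the themes at level k".
For the 15-theme grid this reproduces the published table
(0–7 / 8–15 / 16–23 / ≥24); the 16-theme bounds (9, 18, 27) are an
extrapolation of the same rule, as no published table exists for that
version. Penalized, rounded global scores are classified against the same
boundaries with no adjustment for missingness. Order of operations —
vulnerability adjustment before thematic aggregation, hence before the
missing-data penalty — follows from the thematic score being defined over
adjusted variables; the interaction is not otherwise specified.

### Alerts

A variable may carry an alert threshold in {1,2,3}; any scored variable at
or above it is returned as an alert `(variable_id, score)`. Alerts are
computed on adjusted scores, never interrupt scoring (dropping alerted
dwellings would bias territory summaries upward), and the engine only
flags them — transmitting reports to authorities is out of scope.

## Packaged grids and matrix

The engine is grid-agnostic; grids are versioned JSON/YAML documents
(JSON Schemas in `domiscore/data/schemas/`). Two reconstructions are
packaged to satisfy the instrument's structural facts:

* `2020-01`: 47 variables in the 15 published themes (1–7 variables
  each), five alert variables;
* `2020-11`: 46 variables in 16 themes and nine alert variables, encoding
  every published amendment: "ease of cleaning" and "adequate kitchen
  space" removed, pesticides separated from outdoor air pollution,
  "public transportation" renamed "access to basic services" (variable
  number 39), safe-roads wording on the bicycle-path variable, an on-site
  radon measurement option, and the most urgent themes moved to the front
  of the grid.

Which theme was split to produce the 16th category is not published; here
the "close environment" theme was split into *close environment* (green
spaces, neighborhood safety) and *access to services and mobility*
(basic services, bicycle path), which keeps variable 39 in the documented
position. Variable labels and the four level descriptions are generic
reconstructions — the fixtures exist to satisfy structural invariants,
not to claim regulatory fidelity, and say so in their headers.

The vulnerability matrix ships the two documented rules —
(young children, ventilation, trigger 3) and (visual disability, surface
area, trigger 1) — plus placeholder rules marked
`"note": "placeholder (synthetic)"`, covering 14 distinct housing
characteristics across the five vulnerability kinds.

## Synthetic dwellings and stocks

`QualityProfile` describes a kind of dwelling: a categorical distribution
over the levels 0–3 per variable, an independent per-variable missingness
probability with missing reasons drawn from configurable weights, a
per-vulnerability prevalence, and metadata mixtures. Defaults are
calibrated once to the instrument's 28-visit test phase and not used as
tuning dials:

| parameter | default | basis |
|---|---|---|
| missingness | 0.09 | observed 91% mean completion |
| reason weights | 4/9, 1/9, 2/9, 1/9, 1/9 | reported 5/2/1/1 breakdown of unscored variables (data unavailability split 4:1 between open data and diagnoses) |
| setting | urban 20/28 | test-phase visit mix |
| housing type | collective 19/28 | idem |
| tenure | 13/28, 9/28, 6/28 | private rental / social / owner |
| overseas | 9/28 | idem |

The three built-in quality profiles place level-weight mass
(0.70, 0.22, 0.06, 0.02) for *favorable*, (0.35, 0.35, 0.20, 0.10) for
*mixed* and (0.10, 0.20, 0.35, 0.35) for *degraded* — chosen once so that
the profiles are stochastically ordered and span all four classes under
max-aggregation. Because a theme takes the worst of several draws,
even the mixed profile concentrates stocks in orange/red; this is a
property of the instrument, not a generator artifact.

Scores are independent across variables by default. Real deficiencies
cluster by theme (damp housing is moldy *and* poorly ventilated), so an
optional `category_correlation` knob lets each variable copy a shared
per-category draw with that probability. This is a modeling convenience,
not an empirical claim; the synthetic stocks do not emulate the French
housing stock, spatial structure, assessor disagreement, or informative
missingness (missingness is independent of true condition, unlike the
pessimistic assumption behind the penalty). Passing tests therefore
demonstrate the engine's arithmetic and invariances, not field validity.

Randomness: all draws flow through `numpy.random.Generator`. Dwelling `i`
of a stock uses child `i` of `numpy.random.SeedSequence(seed)`, so stocks
are reproducible across platforms and extendable without reshuffling
earlier dwellings.

## Territory summaries and agreement

`summarize_stock` aggregates per-visit results: class counts, global-score
and completion-rate moments, per-theme color frequencies (the territory
"profile") and the total alert count. Standard deviations use the sample
(n−1) convention, recorded in the summary metadata, and are `None` for a
single visit. Values are sorted before the moments are taken so the
aggregation is exactly permutation-invariant despite float summation.
Summaries are per visit; deduplicating repeat visits of one dwelling is
the caller's responsibility, as assessments are anonymous.

`compare_assessments` supports repeat-visit reproducibility checks with
the simplest defensible statistic: the exact-agreement fraction over
variables scored in both visits (`None` when none are), plus signed
thematic and global deltas. No chance-corrected coefficient (e.g. a
weighted kappa) is computed, to avoid inventing disagreement weights;
users can build one from the per-variable data.

A `percentage` helper implements the whole-percent convention used for
printed descriptives (round half away from zero).

## Numerical and interface choices

* Pre-penalty scores are validated to 0–3; adjusted scores may exceed 3.
* Batch CSV encodes unscored variables as missing-reason codes, never
  empty cells, so "unscored" is distinct from "column absent".
* PII rejection is structural (schemas forbid extra fields) plus an
  explicit deny-list check on raw documents and CSV headers.
* CLI exit codes: 0 ok, 1 validation failure, 2 I/O failure, 3 batch with
  no scorable row; unscorable rows inside a batch are reported per-row
  without aborting the batch.
* Tests exercise the property suites at moderate sizes (1000 random
  small-grid oracle comparisons, 500-dwelling stocks), chosen as the
  smallest sizes at which the stochastic checks are stable.

## Known limitations

* The 16-theme class boundaries are an extrapolation (see above).
* The reconstructed grids match the published structure (counts, themes,
  amendments, alert count) but not the authoritative per-variable wording;
  no claim of legal equivalence ("insalubrious" determinations) is made.
* The exact-agreement statistic ignores chance agreement; with only four
  levels, expected chance agreement is substantial.
* Timing metadata (`visit_meta`) is carried but never analyzed; the
  published timing figures are internally inconsistent and are not a
  reproduction target.
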