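"""Scoring engine: penalties, thematic maxima, global score, classes, alerts."""

from fractions import Fraction

import pytest

from domiscore import (
    Assessment,
    UnscorableError,
    VersionMismatchError,
    apply_vulnerability_penalties,
    class_boundaries,
    classify,
    compute_global_score,
    compute_missing_penalty,
    compute_thematic_scores,
    detect_alerts,
    score_assessment,
)
from domiscore.grid import VulnerabilityMatrix
from domiscore.scoring import round_half_away, score_color

from .conftest import complete_assessment, make_grid


# -- vulnerability penalties ---------------------------------------------------


class TestVulnerabilityPenalties:
    def test_documented_examples(self, grid11, matrix11):
        """Ventilation 3 -> 4 with young children; surface area 1 -> 2 with
        a visually disabled occupant."""
        a = Assessment(
            grid_version="2020-11",
            entries={"ventilation": 3, "surface_area": 1},
            vulnerabilities={"young_children_u4", "visual_disability"},
        )
        adj = apply_vulnerability_penalties(a, matrix11, grid11)
        assert adj["ventilation"] == 4
        assert adj["surface_area"] == 2

    def test_below_trigger_rule_cannot_fire(self, grid11, matrix11):
        a = Assessment(
            grid_version="2020-11",
            entries={"surface_area": 0, "ventilation": 2},
            vulnerabilities={"visual_disability", "young_children_u4"},
        )
        adj = apply_vulnerability_penalties(a, matrix11, grid11)
        assert adj == {"surface_area": 0, "ventilation": 2}

    def test_identity_without_vulnerabilities(self, grid11, matrix11):
        a = complete_assessment(grid11, level=2)
        adj = apply_vulnerability_penalties(a, matrix11, grid11)
        assert adj == a.scored_entries()

    def test_distinct_vulnerabilities_stack(self):
        grid = make_grid([1])
        matrix = VulnerabilityMatrix(
            grid_version="test",
            rules=[
                {"vulnerability": "elderly_o70", "variable_id": "c0v0", "trigger_threshold": 2},
                {"vulnerability": "physical_disability", "variable_id": "c0v0", "trigger_threshold": 2},
            ],
        )
        a = Assessment(
            grid_version="test",
            entries={"c0v0": 2},
            vulnerabilities={"elderly_o70", "physical_disability"},
        )
        assert apply_vulnerability_penalties(a, matrix, grid)["c0v0"] == 4

    def test_trigger_uses_pre_penalty_score(self):
        # a rule at threshold 3 must not fire on a score that only reaches
        # 3 through another rule's penalty
        grid = make_grid([1])
        matrix = VulnerabilityMatrix(
            grid_version="test",
            rules=[
                {"vulnerability": "elderly_o70", "variable_id": "c0v0", "trigger_threshold": 2},
                {"vulnerability": "physical_disability", "variable_id": "c0v0", "trigger_threshold": 3},
            ],
        )
        a = Assessment(
            grid_version="test",
            entries={"c0v0": 2},
            vulnerabilities={"elderly_o70", "physical_disability"},
        )
        assert apply_vulnerability_penalties(a, matrix, grid)["c0v0"] == 3

    def test_missing_entries_untouched(self, grid11, matrix11):
        a = Assessment(
            grid_version="2020-11",
            entries={"ventilation": "data_unavailable"},
            vulnerabilities={"young_children_u4"},
        )
        assert apply_vulnerability_penalties(a, matrix11, grid11) == {}

    def test_unknown_variable_rejected(self, grid11, matrix11):
        a = Assessment(grid_version="2020-11", entries={"flux_capacitor": 1})
        with pytest.raises(KeyError, match="flux_capacitor"):
            apply_vulnerability_penalties(a, matrix11, grid11)


# -- thematic scores -----------------------------------------------------------


class TestThematicScores:
    def test_maximum_rule(self):
        grid = make_grid([3])
        t = compute_thematic_scores({"c0v0": 0, "c0v1": 1, "c0v2": 3}, grid)
        assert t[0].score == 3 and t[0].color == "red" and not t[0].blank

    def test_blank_when_nothing_scored(self):
        grid = make_grid([2, 1])
        t = compute_thematic_scores({"c1v0": 1}, grid)
        assert t[0].blank and t[0].score is None and t[0].color is None

    def test_max_over_scored_entries_only(self):
        grid = make_grid([3])
        t = compute_thematic_scores({"c0v0": 2, "c0v2": 1}, grid)
        assert t[0].score == 2 and t[0].contributing_variable == "c0v0"

    def test_tie_goes_to_first_in_grid_order(self):
        grid = make_grid([3])
        t = compute_thematic_scores({"c0v0": 1, "c0v1": 2, "c0v2": 2}, grid)
        assert t[0].contributing_variable == "c0v1"

    def test_adjusted_scores_above_three_are_red(self):
        grid = make_grid([1])
        t = compute_thematic_scores({"c0v0": 4}, grid)
        assert t[0].score == 4 and t[0].color == "red"

    @pytest.mark.parametrize("score,color", [(0, "green"), (1, "yellow"), (2, "orange"), (3, "red"), (5, "red")])
    def test_color_mapping(self, score, color):
        assert score_color(score) == color


# -- missing-data penalty and global score ------------------------------------


class TestPenaltyAndGlobalScore:
    def _profile(self, scores, n_blank):
        grid = make_grid([1] * (len(scores) + n_blank))
        adjusted = {f"c{i}v0": s for i, s in enumerate(scores)}
        return compute_thematic_scores(adjusted, grid)

    def test_penalty_is_mean_of_completed(self):
        """12 completed categories summing 18 with 3 blanks -> 18/12 = 1.5."""
        scores = [3, 3, 3, 3, 3, 3, 0, 0, 0, 0, 0, 0]  # sum 18 over 12
        t = self._profile(scores, 3)
        assert compute_missing_penalty(t) == Fraction(18, 12)
        raw, pen, glob = compute_global_score(t)
        assert (raw, pen, glob) == (18, Fraction(3, 2), 20)

    def test_no_blank_means_no_penalty(self):
        t = self._profile([1, 2, 3], 0)
        assert compute_missing_penalty(t) == 0
        assert compute_global_score(t) == (6, 0, 6)

    def test_zero_numerator_gives_zero_penalty(self):
        t = self._profile([0, 0], 1)
        assert compute_missing_penalty(t) == 0

    def test_all_blank_is_unscorable(self):
        grid = make_grid([2, 2])
        t = compute_thematic_scores({}, grid)
        with pytest.raises(UnscorableError):
            compute_missing_penalty(t)

    def test_mean_per_blank_mode(self):
        scores = [3, 3, 3, 3, 3, 3, 0, 0, 0, 0, 0, 0]
        t = self._profile(scores, 3)
        assert compute_missing_penalty(t, "mean_per_blank") == Fraction(18, 12) * 3
        _, _, glob = compute_global_score(t, "mean_per_blank")
        assert glob == 23  # 18 + 4.5 = 22.5, ties away from zero

    @pytest.mark.parametrize(
        "x,expected",
        [(Fraction(39, 2), 20), (Fraction(1, 2), 1), (Fraction(3, 2), 2),
         (Fraction(7, 3), 2), (Fraction(0), 0), (Fraction(-1, 2), -1)],
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


# -- class boundaries and classification --------------------------------------


class TestClassification:
    def test_printed_15_theme_boundaries(self):
        assert class_boundaries(15).lower_bounds == (8, 16, 24)

    def test_generalized_rule(self):
        assert class_boundaries(16).lower_bounds == (9, 18, 27)
        assert class_boundaries(1).lower_bounds == (1, 2, 3)

    def test_bad_theme_count(self):
        with pytest.raises(ValueError):
            class_boundaries(0)

    def test_printed_class_table_15_themes(self):
        """classify reproduces 0-7 green / 8-15 yellow / 16-23 orange / 24+ red."""
        for x in range(0, 61):
            expected = (
                "green" if x <= 7 else "yellow" if x <= 15 else "orange" if x <= 23 else "red"
            )
            assert classify(x, 15) == expected

    def test_red_unbounded_above(self):
        assert classify(50, 15) == "red"

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            classify(-1, 15)

    def test_ranges_rendering(self):
        assert class_boundaries(15).ranges() == [
            ("green", 0, 7), ("yellow", 8, 15), ("orange", 16, 23), ("red", 24, None),
        ]


# -- alerts --------------------------------------------------------------------


class TestAlerts:
    def test_threshold_rule(self):
        grid = make_grid([2], alerts={"c0v0": 2})
        assert detect_alerts({"c0v0": 2, "c0v1": 3}, grid) == [("c0v0", 2)]
        assert detect_alerts({"c0v0": 1}, grid) == []

    def test_no_thresholds_no_alerts(self):
        assert detect_alerts({"c0v0": 3}, make_grid([1])) == []

    def test_scoring_continues_past_alerts(self, grid11, matrix11):
        """An assessment full of reportable situations still gets a score."""
        a = complete_assessment(grid11, level=3)
        r = score_assessment(a, grid11, matrix11)
        assert len(r.alerts) == 9
        assert r.global_score == 48


# -- end-to-end ----------------------------------------------------------------


class TestScoreAssessment:
    def test_floor_case(self, grid11, matrix11):
        r = score_assessment(complete_assessment(grid11, level=0), grid11, matrix11)
        assert r.global_score == 0
        assert r.equivalence_class == "green"
        assert r.alerts == ()
        assert r.completion_rate == 1.0
        assert r.penalty == 0

    def test_ceiling_15_categories(self, grid01):
        r = score_assessment(complete_assessment(grid01, level=3), grid01)
        assert r.global_score == 45 and r.equivalence_class == "red"

    def test_ceiling_16_categories(self, grid11):
        r = score_assessment(complete_assessment(grid11, level=3), grid11)
        assert r.global_score == 48 and r.equivalence_class == "red"

    def test_blank_categories_compose(self):
        """3 blank categories over a 15-theme grid: 18 + 18/12 -> 20."""
        grid = make_grid([1] * 15)
        entries = {f"c{i}v0": 3 for i in range(6)}
        entries.update({f"c{i}v0": 0 for i in range(6, 12)})
        a = Assessment(grid_version="test", entries=entries)
        r = score_assessment(a, grid)
        assert r.n_completed == 12
        assert r.raw_sum == 18
        assert r.penalty == Fraction(3, 2)
        assert r.global_score == 20
        assert r.equivalence_class == "orange"
        assert r.completion_rate == 12 / 15

    def test_all_blank_unscorable(self, grid11):
        a = Assessment(
            grid_version="2020-11",
            entries={vid: "data_unavailable" for vid in grid11.variable_ids},
        )
        with pytest.raises(UnscorableError):
            score_assessment(a, grid11)

    def test_version_mismatch(self, grid11):
        with pytest.raises(VersionMismatchError):
            score_assessment(Assessment(grid_version="2020-01", entries={}), grid11)

    def test_deterministic(self, grid11, matrix11):
        a = complete_assessment(grid11, level=1, vulnerabilities={"elderly_o70"})
        assert score_assessment(a, grid11, matrix11) == score_assessment(a, grid11, matrix11)


# -- assessment schema ---------------------------------------------------------


class TestAssessmentSchema:
    def test_scores_outside_0_3_rejected(self):
        with pytest.raises(ValueError, match="outside 0-3"):
            Assessment(grid_version="x", entries={"a": 5})

    def test_unknown_missing_reason_rejected(self):
        with pytest.raises(ValueError, match="missing reason"):
            Assessment(grid_version="x", entries={"a": "on_holiday"})

    def test_extra_identifying_fields_forbidden(self):
        with pytest.raises(ValueError):
            Assessment(grid_version="x", entries={}, address="12 rue X")
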