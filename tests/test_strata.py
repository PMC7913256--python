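"""Cross-window stratification and the per-stratum rule engine."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from crossvis import (
    ExposureStatus,
    RuleDecision,
    Stratum,
    SubjectClassification,
    Verdict,
    assign_stratum,
    boundary_distance,
    evaluate_rule,
    stratify,
    summarize,
)
from crossvis.design import WindowSpec

S, V = ExposureStatus, Verdict


class TestAssignStratum:
    @pytest.mark.parametrize("pair,expected", [
        ((S.RECENT_STOPPER, S.NON_USER), Stratum.A),
        ((S.NON_USER, S.RECENT_STOPPER), Stratum.B),
        ((S.RECENT_STOPPER, S.RECENT_STOPPER), Stratum.C),
        ((S.INTERMITTENT, S.CONTINUOUS), Stratum.D),
        ((S.CONTINUOUS, S.INTERMITTENT), Stratum.E),
        ((S.INTERMITTENT, S.INTERMITTENT), Stratum.F),
        ((S.CONTINUOUS, S.CONTINUOUS), Stratum.G),
        ((S.NON_USER, S.NON_USER), Stratum.H),
    ])
    def test_total_injective_mapping_over_admissible_pairs(self, pair, expected):
        assert assign_stratum(SubjectClassification("x", *pair)) is expected

    def test_unassessed_strata_flagged(self):
        assert not Stratum.G.assessed and not Stratum.H.assessed
        assert all(s.assessed for s in (Stratum.A, Stratum.B, Stratum.C,
                                        Stratum.D, Stratum.E, Stratum.F))

    def test_inadmissible_pair_rejected_at_construction(self):
        # case-window exposure cannot differ between control-window statuses
        with pytest.raises(ValueError):
            SubjectClassification("x", S.INTERMITTENT, S.NON_USER)


class TestBoundaryDistance:
    def test_rhs_is_near_event_boundary(self):
        cw1 = WindowSpec(101, 150)
        assert boundary_distance(105, cw1, "RHS") == 4
        assert boundary_distance(105, cw1, "LHS") == 45
        assert boundary_distance(101, cw1, "RHS") == 0

    def test_non_integer_offset_rejected(self):
        with pytest.raises(TypeError):
            boundary_distance(125.5, WindowSpec(101, 150), "RHS")


class TestRuleEngine:
    def test_rule_a_majority_closer_to_event_side(self, history, design):
        # latest offsets 103, 110, 148: distances to RHS(101) = 2, 9, 47;
        # to LHS(150) = 47, 40, 2 -> 2 of 3 closer to RHS -> condition met
        members = [history({off}, f"s{off}") for off in (103, 110, 148)]
        d = evaluate_rule(Stratum.A, members, design)
        assert (d.n_meeting_condition, d.condition_met) == (2, True)
        assert (d.verdict_cw1, d.verdict_cw2) == (V.CORRECT, V.MISCLASSIFIED)

    def test_rule_a_complement_branch(self, history, design):
        members = [history({off}, f"s{off}") for off in (130, 140, 148)]
        d = evaluate_rule(Stratum.A, members, design)
        assert not d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.MISCLASSIFIED, V.CORRECT)

    def test_rule_b_washout_dispensing_flips_verdict(self, history, design):
        # stratum B: exposed in CW2 only; washout (51-100) dispensings decide
        with_washout = [history({75, 160}, "w1"), history({60, 170}, "w2"),
                        history({180}, "clean")]
        d = evaluate_rule(Stratum.B, with_washout, design)
        assert d.condition_met and d.n_meeting_condition == 2
        assert (d.verdict_cw1, d.verdict_cw2) == (V.MISCLASSIFIED, V.CORRECT)
        d2 = evaluate_rule(Stratum.B, [history({180}, "c1"), history({190}, "c2")], design)
        assert not d2.condition_met
        assert (d2.verdict_cw1, d2.verdict_cw2) == (V.CORRECT, V.MISCLASSIFIED)

    def test_rule_c_compares_across_windows(self, history, design):
        # latest 105: |105-101|=4 vs |105-200|=95 -> closer to RHS of CW1
        members = [history({105, 160}, "a"), history({110, 190}, "b")]
        d = evaluate_rule(Stratum.C, members, design)
        assert d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.CORRECT, V.CORRECT)

    def test_rule_c_complement_warns_both_misclassified(self, history, caplog):
        import logging

        from crossvis.design import StudyDesign

        # under the default geometry every reachable latest dispensing is
        # nearer CW1's event-side edge than CW2's far edge, so the complement
        # needs a short second control window to be exercised
        design = StudyDesign(WindowSpec(1, 50), WindowSpec(101, 150), WindowSpec(151, 160), 160)
        members = [history({140, 155}, "a"), history({145, 158}, "b")]
        with caplog.at_level(logging.WARNING, logger="crossvis.strata"):
            d = evaluate_rule(Stratum.C, members, design)
        assert not d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.MISCLASSIFIED, V.MISCLASSIFIED)
        assert any("BOTH control windows" in r.message for r in caplog.records)

    def test_rule_d_distance_arithmetic_on_bare_offsets(self, history, design):
        # earliest offsets 102 and 150: distances to RHS(151) of CW2 = 49, 1;
        # to LHS(200) = 98, 50 -> both closer to RHS -> met
        members = [history({102}, "a"), history({150}, "b")]
        d = evaluate_rule(Stratum.D, members, design, validate=False)
        assert (d.n_meeting_condition, d.condition_met) == (2, True)
        assert (d.verdict_cw1, d.verdict_cw2) == (V.MISCLASSIFIED, V.CORRECT)

    def test_rule_d_on_genuine_members(self, history, design):
        # exposed in case + CW2 only; earliest (max offset) in first half of CW2
        members = [history({30, 160}, "a"), history({40, 170}, "b"), history({20, 199}, "c")]
        d = evaluate_rule(Stratum.D, members, design)
        assert d.n_meeting_condition == 2 and d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.MISCLASSIFIED, V.CORRECT)

    def test_rule_e_persistent_user_bias(self, history, design):
        # earliest offset 149: distance 1 to LHS(150), 48 to RHS(101) -> met
        members = [history({10, 120, 149}, f"s{i}") for i in range(3)]
        d = evaluate_rule(Stratum.E, members, design)
        assert d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.CORRECT, V.MISCLASSIFIED)

    def test_rule_f_earliest_in_case_window(self, history, design):
        members = [history({10, 40}, "a"), history({45}, "b"), history({20, 75}, "c")]
        d = evaluate_rule(Stratum.F, members, design)
        # earliest offsets 40, 45 in case window; 75 in washout -> 2 of 3
        assert d.n_meeting_condition == 2 and d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.CORRECT, V.CORRECT)

    def test_membership_validated(self, history, design):
        with pytest.raises(ValueError, match="belongs to stratum"):
            evaluate_rule(Stratum.A, [history({30}, "intermittent")], design)

    def test_empty_stratum_indeterminate(self, design):
        d = evaluate_rule(Stratum.C, [], design)
        assert d.n_members == 0 and not d.condition_met
        assert (d.verdict_cw1, d.verdict_cw2) == (V.INDETERMINATE, V.INDETERMINATE)

    def test_exact_half_tie_is_not_a_majority(self, history, design):
        members = [history({103}, "near"), history({148}, "far")]
        d = evaluate_rule(Stratum.A, members, design)
        assert d.n_meeting_condition == 1 and not d.condition_met

    def test_equidistant_offset_counts_as_not_closer(self, history):
        # a tie needs a window whose boundaries share parity: CW1 20-30 has
        # integer midpoint 25, equidistant from both edges
        from crossvis.design import StudyDesign, WindowSpec

        design = StudyDesign(WindowSpec(1, 10), WindowSpec(20, 30), WindowSpec(31, 41), 41)
        member = history({25})  # equidistant: |25-20| == |25-30|
        d = evaluate_rule(Stratum.A, [member], design)
        assert d.n_meeting_condition == 0 and not d.condition_met
        assert d.per_subject_metric[0][1] == 0.0

    def test_per_dispensing_counting_mode(self, history, design):
        # one member, three dispensings in CW1: 103, 110, 148 -> 2 of 3 meet
        member = history({103, 110, 148})
        d = evaluate_rule(Stratum.A, [member], design, count_mode="dispensing")
        assert d.n_units == 3 and d.n_meeting_condition == 2 and d.condition_met

    @given(offsets=st.lists(st.integers(min_value=101, max_value=150), min_size=1,
                            max_size=15).filter(lambda xs: len(xs) % 2 == 1))
    @settings(max_examples=60, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_mirror_flip_inverts_majority(self, offsets, history, design):
        """Mirroring offsets within CW1 flips rule A's outcome (odd n, no ties).

        CW1 = 101-150 has no integer midpoint, so ties are impossible and
        the mirrored cohort's majority is the exact complement.
        """
        members = [history({off}, f"s{i}") for i, off in enumerate(offsets)]
        mirrored = [history({101 + 150 - off}, f"s{i}") for i, off in enumerate(offsets)]
        d1 = evaluate_rule(Stratum.A, members, design)
        d2 = evaluate_rule(Stratum.A, mirrored, design)
        assert d1.condition_met != d2.condition_met


class TestSummarize:
    @staticmethod
    def published_style_decisions():
        """Verdict sets as in the published worked example: CW1 correct for
        A, B, C, E, F; CW2 correct for C, D, F."""
        mk = lambda s, v1, v2: RuleDecision(s, 10, 6, True, v1, v2)
        return {
            Stratum.A: mk(Stratum.A, V.CORRECT, V.MISCLASSIFIED),
            Stratum.B: mk(Stratum.B, V.CORRECT, V.MISCLASSIFIED),
            Stratum.C: mk(Stratum.C, V.CORRECT, V.CORRECT),
            Stratum.D: mk(Stratum.D, V.MISCLASSIFIED, V.CORRECT),
            Stratum.E: mk(Stratum.E, V.CORRECT, V.MISCLASSIFIED),
            Stratum.F: mk(Stratum.F, V.CORRECT, V.CORRECT),
        }

    def test_percentages_from_equal_strata(self):
        s = summarize(self.published_style_decisions())
        assert s.denominator == 60
        assert s.percent_correct_cw1 == pytest.approx(83.3333, abs=1e-3)
        assert s.percent_misclassified_cw1 == pytest.approx(16.6667, abs=1e-3)
        assert s.percent_correct_cw2 == pytest.approx(50.0)
        assert s.percent_misclassified_cw2 == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        s = summarize(self.published_style_decisions())
        for window in ("cw1", "cw2"):
            total = (getattr(s, f"percent_correct_{window}")
                     + getattr(s, f"percent_misclassified_{window}")
                     + getattr(s, f"percent_indeterminate_{window}"))
            assert total == pytest.approx(100.0)

    def test_single_nonempty_stratum(self):
        decisions = {Stratum.C: RuleDecision(Stratum.C, 5, 4, True, V.CORRECT, V.CORRECT)}
        s = summarize(decisions)
        assert s.percent_correct_cw1 == 100.0 and s.percent_correct_cw2 == 100.0

    def test_all_strata_empty_errors(self, design):
        decisions = {s: evaluate_rule(s, [], design) for s in
                     (Stratum.A, Stratum.B, Stratum.C, Stratum.D, Stratum.E, Stratum.F)}
        with pytest.raises(ValueError, match="denominator"):
            summarize(decisions)

    def test_explicit_sizes_and_denominator_override(self):
        s = summarize(self.published_style_decisions(),
                      stratum_sizes={st_: 20 for st_ in Stratum}, denominator=120)
        assert s.percent_correct_cw2 == pytest.approx(50.0)


class TestStratify:
    def test_groups_cover_every_subject_once(self):
        cls = [
            SubjectClassification("a", S.RECENT_STOPPER, S.NON_USER),
            SubjectClassification("b", S.NON_USER, S.NON_USER),
            SubjectClassification("c", S.CONTINUOUS, S.INTERMITTENT),
        ]
        groups = stratify(cls)
        assert sorted(sid for ids in groups.values() for sid in ids) == ["a", "b", "c"]
        assert groups[Stratum.A] == ["a"]
        assert groups[Stratum.H] == ["b"]
        assert groups[Stratum.E] == ["c"]
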