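from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from msc_oracle import brute_force_msc

from mailedfit.analyses import CHANGE_PRINTED_PATHWAYS, YEAR1_PRINTED_PATHWAYS
from mailedfit.ccm import (
    CoincidenceAnalysis,
    Configuration,
    SearchParams,
    assemble_models,
    configuration_matches,
    detect_contradictions,
    enumerate_msc,
    model_metrics,
    relaxed_msc_search,
    score_configuration,
)
from mailedfit.errors import SchemaError


class TestConfigurationMatches:
    def test_literal_equality(self, year1_table):
        table, _ = year1_table
        case = table.frame.loc["S6"].to_dict()  # 1 clinic, phone reminders
        assert configuration_matches(
            Configuration.from_mapping({"PHONE": 1, "multi_clinic": 0}), case
        )
        s9 = table.frame.loc["S9"].to_dict()  # M, Ph only
        assert not configuration_matches(Configuration.from_mapping({"SCRUB": 1}), s9)

    def test_empty_conjunction_matches_everything(self, year1_table):
        table, _ = year1_table
        empty = Configuration(())
        assert all(
            configuration_matches(empty, row.to_dict())
            for _, row in table.frame.iterrows()
        )

    def test_unknown_factor_is_schema_error(self):
        with pytest.raises(SchemaError):
            configuration_matches(Configuration.from_mapping({"ghost": 1}), {"A": 1})

    def test_repeated_factor_rejected(self):
        with pytest.raises(ValueError):
            Configuration((("A", 0), ("A", 1)))


class TestScoreConfiguration:
    def test_forced_half_and_half(self):
        table = make_table(
            [
                {"A": 1, "outcome": 1},
                {"A": 1, "outcome": 0},
                {"A": 0, "outcome": 1},
                {"A": 0, "outcome": 0},
            ]
        )
        score = score_configuration(Configuration.from_mapping({"A": 1}), table)
        assert score.consistency == Fraction(1, 2)
        assert score.coverage == Fraction(1, 2)

    def test_year1_incentive_pathway_matches_four_positives(self, year1_table):
        table, _ = year1_table
        score = score_configuration(
            Configuration.from_mapping({"multi_clinic": 1, "INCENTIVE": 1}), table
        )
        assert score.n_matched == 4
        assert score.consistency == 1

    def test_planted_single_literal(self, planted_factorial):
        table, _ = planted_factorial
        score = score_configuration(Configuration.from_mapping({"C": 1}), table)
        assert score.consistency == 1
        assert score.coverage == Fraction(8, 10)

    def test_no_match_has_undefined_consistency(self):
        table = make_table([{"A": 0, "outcome": 1}])
        score = score_configuration(Configuration.from_mapping({"A": 1}), table)
        assert score.n_matched == 0 and score.consistency is None


class TestEnumerateMSC:
    def test_single_sufficient_literal_prunes_supersets(self):
        rows = [
            {"A": 1, "B": b, "outcome": 1} for b in (0, 1, 0, 1)
        ] + [{"A": 0, "B": b, "outcome": 0} for b in (0, 1)]
        table = make_table(rows)
        found = enumerate_msc(table, 1, Fraction(3, 20), 2)
        assert [s.configuration.literals for s in found] == [(("A", 1),)]

    def test_planted_dnf_recovered_exactly(self, planted_factorial):
        table, _ = planted_factorial
        found = enumerate_msc(table, 1, Fraction(3, 20), 4)
        assert {s.configuration.literals for s in found} == {
            (("C", 1),),
            (("A", 1), ("B", 1)),
        }

    def test_matches_brute_force_on_planted_table(self, planted_factorial):
        table, _ = planted_factorial
        found = enumerate_msc(table, 1, Fraction(3, 20), 4)
        assert {
            frozenset(s.configuration.literals) for s in found
        } == brute_force_msc(table, 1, Fraction(3, 20), 4)

    def test_all_negative_table_yields_empty_list(self):
        table = make_table([{"A": 1, "outcome": 0}, {"A": 0, "outcome": 0}])
        assert enumerate_msc(table, 1, Fraction(3, 20), 2) == []

    def test_output_ordering_is_total(self, year1_table):
        table, _ = year1_table
        found = enumerate_msc(table, 1, Fraction(3, 20), 3)
        keys = [
            (s.configuration.order, -s.score.coverage, s.configuration.sort_key())
            for s in found
        ]
        assert keys == sorted(keys)


class TestRelaxedSearch:
    def test_stops_at_first_nonempty_threshold(self):
        # best single literal reaches 9/10 consistency; nothing is perfect
        rows = [{"A": 1, "outcome": 1} for _ in range(9)]
        rows += [{"A": 1, "outcome": 0}, {"A": 0, "outcome": 0}, {"A": 0, "outcome": 0}]
        table = make_table(rows)
        result = relaxed_msc_search(table, SearchParams(max_order=1))
        assert result.final_threshold == Fraction(9, 10)
        assert [s.configuration.literals for s in result.mscs] == [(("A", 1),)]
        assert result.thresholds_tried == (Fraction(1), Fraction(19, 20), Fraction(9, 10))

    def test_year1_table_succeeds_at_full_consistency(self, year1_table):
        table, _ = year1_table
        result = relaxed_msc_search(table)
        assert result.final_threshold == 1

    def test_all_negative_table_signals_no_solution(self):
        table = make_table([{"A": 1, "outcome": 0}])
        result = relaxed_msc_search(table)
        assert result.no_solution and result.final_threshold is None


class TestContradictions:
    def test_year1_default_coding_has_two_contradictory_pairs(self, year1_table):
        """Two profile-identical pairs with mixed outcomes exist in year 1.

        S4/S9 (4 clinics, mailed return + phone, OC FIT, no prior study)
        and S13/S17 (1 clinic, mailed return only, other FIT, no prior
        study) — verified by brute-force profile grouping.
        """
        table, _ = year1_table
        groups = detect_contradictions(table)
        assert [sorted(g) for g in groups] == [["S13", "S17"], ["S4", "S9"]]

    def test_single_case_table(self):
        assert detect_contradictions(make_table([{"A": 1, "outcome": 1}])) == []

    def test_identical_profiles_with_same_outcome_are_consistent(self):
        table = make_table([{"A": 1, "outcome": 1}, {"A": 1, "outcome": 1}])
        assert detect_contradictions(table) == []

    def test_no_perfect_model_covers_a_contradictory_case(self, change_table):
        table, _ = change_table
        contradictory = {c for g in detect_contradictions(table) for c in g}
        results = CoincidenceAnalysis(
            table, SearchParams(coverage_floor=Fraction(1, 10))
        ).fit()
        for model in results.models:
            if model.consistency == 1:
                assert not (set(model.covered_positive_ids) & contradictory)


class TestAssembleModels:
    def test_planted_dnf_is_top_model(self, planted_factorial):
        table, truth = planted_factorial
        mscs = enumerate_msc(table, 1, Fraction(3, 20), 4)
        models = assemble_models(mscs, table)
        top = models[0]
        assert {p.literals for p in top.pathways} == {
            c.literals for c in truth.as_pathways()
        }
        assert top.consistency == 1 and top.coverage == 1

    def test_change_table_model_metrics(self, change_table):
        table, _ = change_table
        params = SearchParams(coverage_floor=Fraction(1, 10))
        mscs = enumerate_msc(table, 1, params.coverage_floor, params.max_order)
        models = assemble_models(mscs, table, params)
        top = models[0]
        assert (top.n_matched_positive, top.n_matched) == (5, 5)
        assert top.coverage == Fraction(5, 7)
        assert {p.literals for p in top.pathways} == {
            p.literals for p in CHANGE_PRINTED_PATHWAYS
        }

    def test_single_covering_pathway(self):
        rows = [{"A": 1, "outcome": 1} for _ in range(3)] + [{"A": 0, "outcome": 0}]
        table = make_table(rows)
        mscs = enumerate_msc(table, 1, Fraction(3, 20), 1)
        models = assemble_models(mscs, table)
        assert models[0].pathways == (Configuration.from_mapping({"A": 1}),)
        assert models[0].coverage == 1

    def test_no_qualifying_disjunction_returns_empty(self):
        rows = [
            {"A": 1, "B": 0, "outcome": 1},
            {"A": 0, "B": 1, "outcome": 1},
            {"A": 0, "B": 0, "outcome": 0},
            {"A": 1, "B": 1, "outcome": 0},
        ]
        table = make_table(rows)
        mscs = enumerate_msc(table, 1, Fraction(1, 10), 2)
        assert mscs
        # a single perfect pathway covers only 1 of 2 positives: below a
        # full-coverage floor no one-pathway disjunction qualifies
        assert (
            assemble_models(mscs[:1], table, SearchParams(model_coverage_floor=1)) == []
        )


class TestModelMetrics:
    def test_year1_printed_pathways_cover_9_of_11(self, year1_table):
        table, _ = year1_table
        consistency, coverage, covered, uncovered = model_metrics(
            YEAR1_PRINTED_PATHWAYS, table
        )
        assert coverage == Fraction(9, 11)
        assert sorted(uncovered) == ["S14", "S9"]

    def test_change_printed_pathways(self, change_table):
        table, _ = change_table
        consistency, coverage, _, _ = model_metrics(CHANGE_PRINTED_PATHWAYS, table)
        assert consistency == 1 and coverage == Fraction(5, 7)

    def test_always_true_pathway(self):
        rows = [{"A": 1, "outcome": o} for o in (1, 0, 0, 1, 1)]
        table = make_table(rows)
        consistency, coverage, _, _ = model_metrics(
            [Configuration.from_mapping({"A": 1})], table
        )
        assert coverage == 1 and consistency == Fraction(3, 5)

    def test_idempotent_with_stored_model_values(self, change_table):
        table, _ = change_table
        results = CoincidenceAnalysis(
            table, SearchParams(coverage_floor=Fraction(1, 10))
        ).fit()
        top = results.top_model
        consistency, coverage, _, uncovered = model_metrics(top, table)
        assert (consistency, coverage) == (top.consistency, top.coverage)
        assert tuple(sorted(uncovered)) == top.uncovered_positive_ids

    def test_schema_mismatch(self, change_table):
        table, _ = change_table
        with pytest.raises(SchemaError):
            model_metrics([Configuration.from_mapping({"ghost": 1})], table)


# ---------------------------------------------------------------------------
# Property tests


@st.composite
def condition_tables(draw, max_factors=5, max_cases=16):
    n_factors = draw(st.integers(1, max_factors))
    names = [f"F{i}" for i in range(n_factors)]
    n_cases = draw(st.integers(2, max_cases))
    rows = [
        {
            **{name: draw(st.integers(0, 1)) for name in names},
            "outcome": draw(st.integers(0, 1)),
        }
        for _ in range(n_cases)
    ]
    return make_table(rows)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    table=condition_tables(),
    threshold=st.sampled_from([1, Fraction(9, 10), Fraction(3, 4)]),
    floor=st.sampled_from([Fraction(1, 10), Fraction(3, 10)]),
)
def test_enumeration_equals_brute_force_oracle(table, threshold, floor):
    found = {
        frozenset(s.configuration.literals)
        for s in enumerate_msc(table, threshold, floor, 4)
    }
    assert found == brute_force_msc(table, threshold, floor, 4)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(table=condition_tables(), threshold=st.sampled_from([1, Fraction(4, 5)]))
def test_returned_mscs_are_soundly_minimal(table, threshold):
    floor = Fraction(1, 10)
    for scored in enumerate_msc(table, threshold, floor, 4):
        for sub in scored.configuration.proper_subconjunctions():
            score = score_configuration(sub, table)
            ok_cons = score.consistency is not None and score.consistency >= threshold
            ok_cov = score.coverage is not None and score.coverage >= floor
            assert not (ok_cons and ok_cov)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(table=condition_tables(max_factors=4))
def test_coverage_is_anti_monotone_in_order(table):
    """Adding a literal to a conjunction never increases its coverage."""
    if table.n_positive == 0:
        return
    names = list(table.factor_names)
    base = Configuration.from_mapping({names[0]: 1})
    base_cov = score_configuration(base, table).coverage
    for name in names[1:]:
        for level in (0, 1):
            extended = Configuration(base.literals + ((name, level),))
            assert score_configuration(extended, table).coverage <= base_cov


@settings(max_examples=40, derandomize=True, deadline=None)
@given(table=condition_tables(max_factors=4))
def test_model_coverage_is_monotone_in_pathways(table):
    """Adding a pathway to a disjunction never decreases model coverage."""
    if table.n_positive == 0:
        return
    mscs = enumerate_msc(table, Fraction(1, 2), Fraction(1, 100), 2)
    if len(mscs) < 2:
        return
    growing = []
    last = Fraction(0)
    for scored in mscs[:4]:
        growing.append(scored.configuration)
        coverage = model_metrics(growing, table)[1]
        assert coverage >= last
        last = coverage


@settings(max_examples=25, derandomize=True, deadline=None)
@given(table=condition_tables(max_factors=4, max_cases=12))
def test_fit_is_deterministic(table):
    if table.n_positive == 0:
        return
    a = CoincidenceAnalysis(table).fit()
    b = CoincidenceAnalysis(table).fit()
    assert a.to_report() == b.to_report()
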