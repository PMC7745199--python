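import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evidencedrift import (
    ChangeCriteria,
    ConclusionAssessment,
    Metric,
    ReportedResult,
    classify_conclusion,
    classify_result_change,
    compare_sources,
    conclusion_changed,
    detect_methods_changes,
    p_crossing,
    pair_results,
    relative_change,
)
from evidencedrift.change_detection import (
    AmbiguousResultsError,
    UndefinedChangeError,
    changes_to_frame,
    frame_to_changes,
)
from evidencedrift.corpus_model import Direction, MethodsProfile, Uncertainty

from conftest import make_study


def rr(label, metric, estimate=None, p=None):
    return ReportedResult(outcome_label=label, metric=metric, estimate=estimate, p_value=p)


class TestRelativeChange:
    def test_event_rate_24_to_35(self):
        # 44-participant interim vs 86-participant final report: 24% -> 35%
        assert relative_change(24.0, 35.0) == pytest.approx(11 / 24)

    def test_identity(self):
        assert relative_change(3.7, 3.7) == 0.0

    def test_boundary_ten_percent(self):
        assert relative_change(2.0, 1.8) == pytest.approx(0.10)

    def test_zero_initial_undefined(self):
        with pytest.raises(UndefinedChangeError):
            relative_change(0.0, 1.0)

    @given(
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=0.01, max_value=1e3),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_asymmetric_in_general(self, a, b):
        # detection is symmetric, magnitude is not: denominator is the initial
        assert relative_change(a, b) * a == pytest.approx(relative_change(b, a) * b)


class TestPCrossing:
    @pytest.mark.parametrize(
        "p_old,p_new,expected",
        [
            (0.06, 0.04, True),
            (0.2, 0.08, False),
            (0.05, 0.04, True),  # 0.05 itself is not significant (strict <)
            (0.04, 0.05, True),
            (None, 0.01, False),
            (0.2, None, False),
        ],
    )
    def test_examples(self, p_old, p_new, expected):
        assert p_crossing(p_old, p_new, 0.05) is expected


class TestPairResults:
    def test_identical_lists_all_matched(self):
        a = [rr("mortality", Metric.hazard_ratio, 0.8, 0.04)]
        matched, added, removed = pair_results(a, list(a))
        assert len(matched) == 1 and added == removed == 0

    def test_extra_outcome_counts_added(self):
        a = [rr("mortality", Metric.hazard_ratio, 0.8)]
        b = a + [rr("icu admission", Metric.odds_ratio, 1.2)]
        _, added, removed = pair_results(a, b)
        assert (added, removed) == (1, 0)

    def test_metric_is_part_of_the_key(self):
        a = [rr("mortality", Metric.hazard_ratio, 0.8)]
        b = [rr("mortality", Metric.odds_ratio, 0.8)]
        matched, added, removed = pair_results(a, b)
        assert matched == [] and added == 1 and removed == 1

    def test_label_normalization(self):
        a = [rr("  ICU   Admission ", Metric.odds_ratio, 1.0)]
        b = [rr("icu admission", Metric.odds_ratio, 1.0)]
        matched, _, _ = pair_results(a, b)
        assert len(matched) == 1

    def test_duplicate_key_is_ambiguous(self):
        a = [rr("x", Metric.odds_ratio, 1.0), rr("x", Metric.odds_ratio, 2.0)]
        with pytest.raises(AmbiguousResultsError):
            pair_results(a, [])


class TestClassifyResultChange:
    def test_identical_versions_all_false(self):
        a = [rr("adverse events", Metric.event_rate, 24.0, 0.2)]
        out = classify_result_change(a, list(a), 44, 44)
        assert not out["result_changed"] and not out["important_change"]
        assert out["max_relative_change"] == 0.0 and not out["p_crossed"]

    def test_event_rate_jump_is_important(self):
        a = [rr("adverse events", Metric.event_rate, 24.0, 0.2)]
        b = [rr("adverse events", Metric.event_rate, 35.0, 0.2)]
        out = classify_result_change(a, b, 44, 86)
        assert out["result_changed"] and out["important_change"]
        assert out["max_relative_change"] == pytest.approx(11 / 24)
        assert out["sample_size_changed"] and not out["p_crossed"]

    def test_exact_ten_percent_is_important(self):
        a = [rr("mortality", Metric.hazard_ratio, 2.0)]
        b = [rr("mortality", Metric.hazard_ratio, 1.8)]
        assert classify_result_change(a, b, 10, 10)["important_change"]

    def test_p_shift_without_crossing_not_important(self):
        a = [rr("mortality", Metric.hazard_ratio, 0.8, 0.3)]
        b = [rr("mortality", Metric.hazard_ratio, 0.8, 0.2)]
        out = classify_result_change(a, b, 10, 10)
        assert out["result_changed"] and not out["important_change"]

    def test_zero_initial_changes_but_never_important(self):
        a = [rr("case growth rate", Metric.regression_coefficient, 0.0)]
        b = [rr("case growth rate", Metric.regression_coefficient, 0.05)]
        out = classify_result_change(a, b, 10, 10)
        assert out["result_changed"]
        assert not out["important_change"]
        assert out["max_relative_change"] is None

    def test_detection_is_symmetric(self):
        a = [rr("mortality", Metric.hazard_ratio, 1.0, 0.2)]
        b = [rr("mortality", Metric.hazard_ratio, 1.4, 0.01)]
        assert (
            classify_result_change(a, b, 5, 5)["result_changed"]
            == classify_result_change(b, a, 5, 5)["result_changed"]
        )

    @given(st.floats(min_value=0.11, max_value=5.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_threshold_monotonicity(self, rel):
        a = [rr("m", Metric.odds_ratio, 1.0)]
        b = [rr("m", Metric.odds_ratio, 1.0 + rel)]
        loose = classify_result_change(a, b, 1, 1, ChangeCriteria(relative_change_threshold=0.10))
        strict = classify_result_change(a, b, 1, 1, ChangeCriteria(relative_change_threshold=10.0))
        assert loose["important_change"] >= strict["important_change"]


class TestConclusionCoding:
    @pytest.mark.parametrize(
        "text,direction,uncertainty",
        [
            ("The drug might be effective in this population.", "positive", "reported"),
            ("These results prove the efficacy of the intervention.", "positive", "not_reported"),
            ("No difference was observed between arms.", "neutral", "not_reported"),
            (
                "Treatment was associated with increased mortality and harm.",
                "negative",
                "not_reported",
            ),
            (
                "Findings suggest benefit but should be confirmed in further studies.",
                "positive",
                "reported",
            ),
        ],
    )
    def test_lexicon_examples(self, text, direction, uncertainty):
        coded = classify_conclusion(text)
        assert coded.direction.value == direction
        assert coded.uncertainty.value == uncertainty

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            classify_conclusion("   ")

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("positive", "not_reported"), ("positive", "reported"), True),
            (("neutral", "reported"), ("positive", "reported"), True),
            (("negative", "reported"), ("negative", "reported"), False),
        ],
    )
    def test_conclusion_changed(self, a, b, expected):
        ca = ConclusionAssessment(direction=a[0], uncertainty=a[1])
        cb = ConclusionAssessment(direction=b[0], uncertainty=b[1])
        assert conclusion_changed(ca, cb) is expected


class TestMethodsChanges:
    def test_identical_profiles(self):
        p = MethodsProfile(blinding="double blind")
        assert detect_methods_changes(p, p.model_copy()) == []

    def test_information_added_counts(self):
        a = MethodsProfile()
        b = MethodsProfile(confounder_adjustment="time-dependent propensity score")
        assert detect_methods_changes(a, b) == ["confounder_adjustment"]

    def test_two_fields_stable_order(self):
        a = MethodsProfile(blinding="open label", missing_data="complete case")
        b = MethodsProfile(blinding="double blind", missing_data="imputed")
        assert detect_methods_changes(a, b) == ["blinding", "missing_data"]

    def test_whitespace_normalized(self):
        a = MethodsProfile(blinding="double  blind ")
        b = MethodsProfile(blinding="double blind")
        assert detect_methods_changes(a, b) == []


class TestCompareSources:
    def test_two_versions_no_article_one_record(self):
        recs = compare_sources(make_study(n_versions=2))
        assert [r.pair_type.value for r in recs] == ["first_vs_latest_preprint"]

    def test_three_versions_plus_article_three_records(self):
        recs = compare_sources(make_study(n_versions=3, with_article=True))
        assert {r.pair_type.value for r in recs} == {
            "first_vs_latest_preprint",
            "first_preprint_vs_article",
            "latest_preprint_vs_article",
        }

    def test_single_source_single_version_not_comparable(self):
        assert compare_sources(make_study(n_versions=1)) == []

    def test_invariant_chain_on_synthetic_corpus(self, small_corpus):
        studies, _ = small_corpus
        for study in studies:
            for rec in compare_sources(study):
                if rec.important_change:
                    assert rec.result_changed
                if rec.p_crossed:
                    assert rec.important_change

    def test_csv_round_trip(self, small_corpus):
        studies, _ = small_corpus
        records = [r for s in studies for r in compare_sources(s)]
        assert frame_to_changes(changes_to_frame(records)) == records
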