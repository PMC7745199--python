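import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evidencedrift import (
    ConclusionAssessment,
    UsageMetrics,
    citation_share,
    compare_sources,
    km_unpublished,
    median_iqr,
    normalize_usage,
    percent,
    summarize_corpus,
    transition_counts,
)
from evidencedrift.change_detection import ChangeRecord, PairType
from evidencedrift.descriptive_synthesis import conclusion_endpoints, publication_delays


def ca(direction, uncertainty):
    return ConclusionAssessment(direction=direction, uncertainty=uncertainty)


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([76]) == (76.0, 76.0, 76.0)

    def test_linear_interpolation_example(self):
        assert median_iqr([1, 2, 3, 4]) == (2.5, 1.75, 3.25)

    def test_permutation_invariance(self):
        assert median_iqr([4, 1, 3, 2]) == median_iqr([1, 2, 3, 4])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_against_interpolation_oracle(self, values):
        # independent "type 7" oracle: index h = (n-1)q, interpolate neighbours
        def quantile(sorted_v, q):
            h = (len(sorted_v) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

        s = sorted(values)
        med, q1, q3 = median_iqr(values)
        assert med == pytest.approx(quantile(s, 0.5))
        assert q1 == pytest.approx(quantile(s, 0.25))
        assert q3 == pytest.approx(quantile(s, 0.75))


class TestKaplanMeier:
    def test_all_censored_constant_one(self):
        curve = km_unpublished([(30.0, False), (60.0, False)])
        assert curve.times == []
        assert curve.probability_at(100.0) == 1.0

    def test_two_events_no_censoring(self):
        curve = km_unpublished([(10.0, True), (20.0, True)])
        assert curve.times == [10.0, 20.0]
        assert curve.survival == pytest.approx([0.5, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # events at 5 and 9, censored at 7: S(5) = 2/3, S(9) = 2/3 * (1 - 1/1) = 0
        curve = km_unpublished([(5.0, True), (7.0, False), (9.0, True)])
        assert curve.times == [5.0, 9.0]
        assert curve.survival == pytest.approx([2 / 3, 0.0])
        assert curve.at_risk == [3, 1]

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            km_unpublished([(-1.0, True)])

    @given(
        st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=40),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_no_censoring_equals_empirical_survivor(self, days):
        curve = km_unpublished([(float(d), True) for d in days])
        n = len(days)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(sum(1 for d in days if d > t) / n)

    def test_nonincreasing_probabilities(self):
        rng = np.random.default_rng(0)
        delays = [(float(d), bool(e)) for d, e in zip(rng.integers(0, 300, 50), rng.random(50) < 0.4)]
        curve = km_unpublished(delays)
        assert all(a >= b for a, b in zip(curve.survival, curve.survival[1:]))
        assert all(0.0 <= s <= 1.0 for s in curve.survival)


class TestUsage:
    def test_thirty_citations_thirty_days(self):
        m = UsageMetrics(
            citations=30, attention_score=0.0, pubpeer_comments=0,
            retrieval_date=dt.date(2020, 3, 31),
        )
        rates = normalize_usage(m, dt.date(2020, 3, 1))
        assert rates["citations_per_day"] == 1.0

    def test_same_day_clamps_to_one(self):
        m = UsageMetrics(
            citations=4, attention_score=2.0, pubpeer_comments=0,
            retrieval_date=dt.date(2020, 3, 1),
        )
        assert normalize_usage(m, dt.date(2020, 3, 1))["citations_per_day"] == 4.0

    def test_retrieval_before_online_rejected(self):
        m = UsageMetrics(
            citations=1, attention_score=0.0, pubpeer_comments=0,
            retrieval_date=dt.date(2020, 2, 1),
        )
        with pytest.raises(ValueError):
            normalize_usage(m, dt.date(2020, 3, 1))

    def test_scale_equivariance(self):
        online = dt.date(2020, 3, 1)
        m1 = UsageMetrics(citations=7, attention_score=3.0, pubpeer_comments=1,
                          retrieval_date=dt.date(2020, 6, 1))
        m2 = UsageMetrics(citations=14, attention_score=6.0, pubpeer_comments=2,
                          retrieval_date=dt.date(2020, 6, 1))
        r1, r2 = normalize_usage(m1, online), normalize_usage(m2, online)
        for key in r1:
            assert r2[key] == pytest.approx(2 * r1[key])

    @pytest.mark.parametrize("p,a,expected", [(29, 71, 0.29), (0, 5, 0.0), (0, 0, None)])
    def test_citation_share(self, p, a, expected):
        assert citation_share(p, a) == expected


class TestTransitions:
    def test_identical_pairs_diagonal(self):
        states = [ca("positive", "reported")] * 5 + [ca("neutral", "not_reported")] * 3
        m = transition_counts(states, states)
        assert m.total == 8 and m.off_diagonal_total == 0

    def test_dominant_flow_cell(self):
        first = [ca("positive", "not_reported")] * 12
        last = [ca("positive", "reported")] * 12
        m = transition_counts(first, last)
        assert m.count(first[0], last[0]) == 12
        assert m.off_diagonal_total == 12

    def test_direction_aggregation(self):
        first = [ca("neutral", "reported")] * 6
        last = [ca("positive", "reported")] * 6
        m = transition_counts(first, last).direction_counts()
        assert m[1, 0] == 6  # neutral -> positive in (positive, neutral, negative) order

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transition_counts([ca("neutral", "reported")], [])

    def test_off_diagonal_equals_changed_count(self, small_corpus):
        studies, _ = small_corpus
        endpoints = [ep for s in studies if (ep := conclusion_endpoints(s)) is not None]
        matrix = transition_counts([a for a, _ in endpoints], [b for _, b in endpoints])
        n_changed = sum(1 for a, b in endpoints if a != b)
        assert matrix.total == len(endpoints)
        assert matrix.off_diagonal_total == n_changed


class TestSummarizeCorpus:
    def test_empty_corpus(self):
        summary = summarize_corpus([], None, [])
        assert summary.n_studies == 0
        assert summary.pct_preprint_reported is None
        assert summary.changes is None
        assert summary.median_delay_days is None

    def test_all_single_source(self):
        from conftest import make_study

        studies = [make_study(study_id=f"s{i}") for i in range(4)]
        summary = summarize_corpus(studies, None, [])
        assert summary.n_multisource == 0 and summary.changes is None

    def test_unknown_study_reference_rejected(self):
        rec = ChangeRecord(study_id="ghost", pair_type=PairType.first_vs_latest_preprint)
        with pytest.raises(ValueError):
            summarize_corpus([], None, [rec])

    def test_consistency_on_synthetic_corpus(self, small_corpus):
        studies, _ = small_corpus
        records = [r for s in studies for r in compare_sources(s)]
        summary = summarize_corpus(studies, None, records)
        summary.consistency_check()  # every percentage re-derivable from counts
        assert summary.n_preprint_reported + summary.n_article_only == summary.n_studies

    def test_publication_delays_censoring(self, small_corpus):
        studies, _ = small_corpus
        cutoff = dt.date(2020, 9, 2)
        delays = publication_delays(studies, cutoff)
        n_published = sum(1 for s in studies if s.preprint and s.article)
        assert sum(1 for _, event in delays if event) == n_published
        assert all(d >= 0 for d, _ in delays)

    @pytest.mark.parametrize("num,den,expected", [(338, 556, 61), (66, 338, 20), (1, 0, None), (5, 1000, 1)])
    def test_percent_rounding(self, num, den, expected):
        assert percent(num, den) == expected
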