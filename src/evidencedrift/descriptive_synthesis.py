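"""Descriptive outputs: corpus summary tables, time-to-publication survival,
conclusion-transition matrix, and exposure-normalized usage metrics.

Percentages are rounded half away from zero to integers, matching the
style of printed summary tables. Quantiles use linear interpolation
between order statistics (the common "type 7" rule). Publication-delay
survival treats journal publication as the event and censors preprints
still unpublished at the data cutoff.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .change_detection import ChangeRecord, PairType
from .corpus_model import ConclusionAssessment, Direction, Study, Uncertainty, UsageMetrics

__all__ = [
    "percent",
    "median_iqr",
    "ChangeSection",
    "CorpusSummary",
    "summarize_corpus",
    "SurvivalCurve",
    "km_unpublished",
    "normalize_usage",
    "citation_share",
    "STATE_ORDER",
    "TransitionMatrix",
    "transition_counts",
    "conclusion_endpoints",
    "publication_delays",
]


def percent(numerator: int, denominator: int) -> Optional[int]:
    """Integer percentage, rounded half away from zero; None if denominator 0."""
    if denominator == 0:
        return None
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between order statistics."""
    if len(values) == 0:
        raise ValueError("median_iqr requires a non-empty input")
    arr = np.asarray(values, dtype=float)
    med, q1, q3 = np.percentile(arr, [50.0, 25.0, 75.0])
    return float(med), float(q1), float(q3)


_COMPONENTS = ("any", "results", "important", "conclusion", "methods")


@dataclass
class ChangeSection:
    """Counts and percentages of changed studies over one denominator."""

    denominator: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, Optional[int]] = field(default_factory=dict)


@dataclass
class CorpusSummary:
    n_studies: int
    n_preprint_reported: int
    n_article_only: int
    n_preprints_published: int
    n_multiversion: int
    n_multisource: int
    pct_preprint_reported: Optional[int]
    pct_preprints_published: Optional[int]
    pct_multiversion: Optional[int]
    pct_multisource: Optional[int]
    changes: Optional[ChangeSection]
    changes_by_pair_type: dict[str, ChangeSection]
    median_delay_days: Optional[float]
    delay_iqr: Optional[tuple[float, float]]
    median_versions: Optional[float]
    versions_iqr: Optional[tuple[float, float]]
    versions_range: Optional[tuple[int, int]]

    def consistency_check(self) -> None:
        """Every percentage must be re-derivable from its own counts."""
        assert self.n_preprint_reported + self.n_article_only == self.n_studies
        assert self.pct_preprint_reported == percent(self.n_preprint_reported, self.n_studies)
        assert self.pct_preprints_published == percent(
            self.n_preprints_published, self.n_preprint_reported
        )
        assert self.pct_multiversion == percent(self.n_multiversion, self.n_preprint_reported)
        assert self.pct_multisource == percent(self.n_multisource, self.n_studies)
        sections = list(self.changes_by_pair_type.values())
        if self.changes is not None:
            sections.append(self.changes)
        for sec in sections:
            for comp, count in sec.counts.items():
                assert sec.percentages[comp] == percent(count, sec.denominator)


def _change_flags(records: Sequence[ChangeRecord]) -> dict[str, bool]:
    flags = {
        "results": any(r.result_changed for r in records),
        "important": any(r.important_change for r in records),
        "conclusion": any(r.conclusion_changed for r in records),
        "methods": any(r.methods_fields_changed for r in records),
    }
    flags["any"] = flags["results"] or flags["conclusion"] or flags["methods"]
    return flags


def _section(per_study_flags: Sequence[dict[str, bool]], denominator: int) -> ChangeSection:
    counts = {c: sum(f[c] for f in per_study_flags) for c in _COMPONENTS}
    return ChangeSection(
        denominator=denominator,
        counts=counts,
        percentages={c: percent(n, denominator) for c, n in counts.items()},
    )


def summarize_corpus(
    studies: Sequence[Study],
    links=None,
    change_records: Sequence[ChangeRecord] = (),
) -> CorpusSummary:
    """Aggregate studies and change records into the corpus summary.

    Denominators follow the reporting conventions of the source tables:
    preprint share over all studies; published and multi-version shares
    over preprint-reported studies; change shares over multi-source
    studies; per-pair-type shares over studies having that pair.
    ``links`` is accepted for interface completeness; publication status
    is derived from the studies themselves.
    """
    known = {s.study_id for s in studies}
    for rec in change_records:
        if rec.study_id not in known:
            raise ValueError(f"change record references unknown study {rec.study_id!r}")

    n = len(studies)
    with_pp = [s for s in studies if s.preprint is not None]
    published = [s for s in with_pp if s.article is not None]
    multiversion = [s for s in with_pp if len(s.preprint.versions) > 1]
    multisource = [s for s in studies if s.is_multisource]

    by_study: dict[str, list[ChangeRecord]] = {}
    for rec in change_records:
        by_study.setdefault(rec.study_id, []).append(rec)

    changes: Optional[ChangeSection] = None
    by_pair: dict[str, ChangeSection] = {}
    if multisource:
        flags = [_change_flags(by_study.get(s.study_id, [])) for s in multisource]
        changes = _section(flags, len(multisource))
        for pair_type in PairType:
            sub = [
                [r for r in by_study.get(s.study_id, []) if r.pair_type is pair_type]
                for s in multisource
            ]
            sub = [recs for recs in sub if recs]
            if sub:
                by_pair[pair_type.value] = _section([_change_flags(r) for r in sub], len(sub))

    delays = [
        (s.article.record.online_date - s.preprint.record.online_date).days for s in published
    ]
    med_delay = iqr_delay = None
    if delays:
        m, q1, q3 = median_iqr(delays)
        med_delay, iqr_delay = m, (q1, q3)

    versions = [len(s.preprint.versions) for s in with_pp]
    med_v = iqr_v = rng_v = None
    if versions:
        m, q1, q3 = median_iqr(versions)
        med_v, iqr_v = m, (q1, q3)
        rng_v = (min(versions), max(versions))

    summary = CorpusSummary(
        n_studies=n,
        n_preprint_reported=len(with_pp),
        n_article_only=n - len(with_pp),
        n_preprints_published=len(published),
        n_multiversion=len(multiversion),
        n_multisource=len(multisource),
        pct_preprint_reported=percent(len(with_pp), n),
        pct_preprints_published=percent(len(published), len(with_pp)),
        pct_multiversion=percent(len(multiversion), len(with_pp)),
        pct_multisource=percent(len(multisource), n),
        changes=changes,
        changes_by_pair_type=by_pair,
        median_delay_days=med_delay,
        delay_iqr=iqr_delay,
        median_versions=med_v,
        versions_iqr=iqr_v,
        versions_range=rng_v,
    )
    summary.consistency_check()
    return summary


@dataclass
class SurvivalCurve:
    """Product-limit estimate of remaining unpublished as a journal article."""

    times: list[float]  # event (publication) times, ascending
    survival: list[float]  # S(t) just after each event time
    at_risk: list[int]  # risk-set size at each event time
    censoring_times: list[float]

    def probability_at(self, t: float) -> float:
        prob = 1.0
        for time, s in zip(self.times, self.survival):
            if time <= t:
                prob = s
            else:
                break
        return prob


def km_unpublished(delays: Sequence[tuple[float, bool]]) -> SurvivalCurve:
    """Kaplan–Meier estimate of the probability a preprint remains unpublished.

    ``delays`` holds (days since first preprint online, event flag): the
    event is journal publication; False means censored at the data cutoff.
    With no censoring this equals the empirical survivor function.
    """
    if any(d < 0 for d, _ in delays):
        raise ValueError("delays must be non-negative")
    durations = [d for d, _ in delays]
    events = [bool(e) for _, e in delays]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = [float(t) for t in event_rows.index]
    sf = kmf.survival_function_[kmf.survival_function_.columns[0]]
    survival = [float(sf.loc[t]) for t in event_rows.index]
    at_risk = [int(v) for v in event_rows["at_risk"]]
    censoring = sorted(float(d) for d, e in delays if not e)
    return SurvivalCurve(times=times, survival=survival, at_risk=at_risk, censoring_times=censoring)


def normalize_usage(metrics: UsageMetrics, online_date: dt.date) -> dict[str, float]:
    """Per-day usage rates: each metric over days online (clamped to >= 1)."""
    if metrics.retrieval_date < online_date:
        raise ValueError("retrieval_date precedes online_date")
    days = max(1, (metrics.retrieval_date - online_date).days)
    return {
        "citations_per_day": metrics.citations / days,
        "attention_per_day": metrics.attention_score / days,
        "pubpeer_comments_per_day": metrics.pubpeer_comments / days,
    }


def citation_share(preprint_citations: int, article_citations: int) -> Optional[float]:
    """Fraction of a pair's citations attributed to the preprint; None if both 0."""
    if preprint_citations < 0 or article_citations < 0:
        raise ValueError("citation counts must be non-negative")
    total = preprint_citations + article_citations
    if total == 0:
        return None
    return preprint_citations / total


# State order for the transition matrix: direction-major, uncertainty-minor.
STATE_ORDER: tuple[tuple[Direction, Uncertainty], ...] = tuple(
    (d, u)
    for d in (Direction.positive, Direction.neutral, Direction.negative)
    for u in (Uncertainty.not_reported, Uncertainty.reported)
)
_STATE_INDEX = {state: i for i, state in enumerate(STATE_ORDER)}


@dataclass
class TransitionMatrix:
    """6x6 conclusion-state transition counts, first version -> latest source."""

    counts: np.ndarray
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def off_diagonal_total(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def count(self, first: ConclusionAssessment, last: ConclusionAssessment) -> int:
        i = _STATE_INDEX[(first.direction, first.uncertainty)]
        j = _STATE_INDEX[(last.direction, last.uncertainty)]
        return int(self.counts[i, j])

    def direction_counts(self) -> np.ndarray:
        """3x3 aggregation over directions (uncertainty marginalized out)."""
        return self.counts.reshape(3, 2, 3, 2).sum(axis=(1, 3))


def conclusion_endpoints(
    study: Study,
) -> Optional[tuple[ConclusionAssessment, ConclusionAssessment]]:
    """(first preprint version, latest available source) assessment pair.

    The endpoint is the article when present, else the latest preprint
    version. Returns None for single-source single-version studies or when
    either endpoint lacks a pre-coded assessment.
    """
    if not study.is_multisource or study.preprint is None:
        return None
    first = study.preprint.versions[0].conclusion
    last_version = study.article.version if study.article is not None else study.preprint.versions[-1]
    last = last_version.conclusion
    if first is None or last is None:
        return None
    return first, last


def publication_delays(
    studies: Sequence[Study], cutoff: dt.date
) -> list[tuple[float, bool]]:
    """(days, published?) per preprint-reported study, for the survival fit.

    Published preprints contribute their preprint-to-article delay as an
    event; unpublished ones are censored at the cutoff date. Preprints
    appearing after the cutoff are excluded.
    """
    delays: list[tuple[float, bool]] = []
    for s in studies:
        if s.preprint is None:
            continue
        online = s.preprint.record.online_date
        if s.article is not None:
            delays.append((max(0, (s.article.record.online_date - online).days), True))
        elif online <= cutoff:
            delays.append(((cutoff - online).days, False))
    return delays


def transition_counts(
    first: Sequence[ConclusionAssessment], last: Sequence[ConclusionAssessment]
) -> TransitionMatrix:
    """Count conclusion-state transitions over paired assessments."""
    if len(first) != len(last):
        raise ValueError("first and last assessment lists must have equal length")
    counts = np.zeros((6, 6), dtype=int)
    for a, b in zip(first, last):
        counts[_STATE_INDEX[(a.direction, a.uncertainty)], _STATE_INDEX[(b.direction, b.uncertainty)]] += 1
    labels = tuple(f"{d.value}/{u.value}" for d, u in STATE_ORDER)
    return TransitionMatrix(counts=counts, labels=labels)
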