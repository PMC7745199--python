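import datetime as dt

import pytest

from evidencedrift import (
    Author,
    BibliographicRecord,
    ConclusionAssessment,
    GeneratorParams,
    Metric,
    ReportedResult,
    SourceType,
    SourceVersion,
    Study,
    StudyDesign,
    generate_corpus,
)
from evidencedrift.corpus_model import ArticleSource, PreprintSource


def make_record(
    record_id="pp-1",
    source_type=SourceType.preprint,
    title="Efficacy of remdesivir on mortality in hospitalized adults",
    authors=None,
    online_date=dt.date(2020, 3, 1),
    **kwargs,
):
    authors = authors or [
        Author(family="Müller", given="Émile", orcid="0000-0001-0000-0001"),
        Author(family="García", given="Lucía"),
        Author(family="Chen", given="Wei", orcid="0000-0002-0000-0002"),
    ]
    return BibliographicRecord(
        record_id=record_id,
        source_type=source_type,
        title=title,
        authors=authors,
        online_date=online_date,
        **kwargs,
    )


def make_version(version_number=1, date=dt.date(2020, 3, 1), results=None, sample_size=44, conclusion=None):
    results = results if results is not None else [
        ReportedResult(
            outcome_label="adverse events", metric=Metric.event_rate, estimate=24.0, p_value=0.2
        )
    ]
    return SourceVersion(
        version_number=version_number,
        date=date,
        results=results,
        sample_size=sample_size,
        conclusion=conclusion,
        conclusion_text="No difference was observed between groups."
        if conclusion is None
        else None,
    )


def make_study(study_id="study-1", n_versions=1, with_article=False, **version_kwargs):
    versions = [
        make_version(version_number=v, date=dt.date(2020, 3, 1) + dt.timedelta(days=20 * (v - 1)))
        for v in range(1, n_versions + 1)
    ]
    article = None
    if with_article:
        article = ArticleSource(
            record=make_record(
                record_id=f"{study_id}-art",
                source_type=SourceType.journal_article,
                online_date=dt.date(2020, 6, 1),
            ),
            version=make_version(date=dt.date(2020, 6, 1)),
        )
    return Study(
        study_id=study_id,
        design=StudyDesign.rct,
        intervention_category="antimalarials",
        preprint=PreprintSource(record=make_record(record_id=f"{study_id}-pp"), versions=versions),
        article=article,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 150-study synthetic corpus with ground truth (fixed seed)."""
    return generate_corpus(GeneratorParams(n_studies=150, seed=11))
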