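"""Domain types and corpus I/O for the evidence-instability pipeline.

A *study* is the unit of analysis. Each study may be reported in up to two
evidence sources — a preprint (possibly with several dated versions) and a
journal article — and each source version carries structured results, a
sample size and an abstract-conclusion assessment. The corpus is serialized
as JSON Lines (one study per line, UTF-8); bibliographic input follows the
CSL-JSON work-record convention used by Crossref.
"""

from __future__ import annotations

import datetime as dt
import json
from enum import Enum
from pathlib import Path
from typing import ClassVar, Iterable, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Author",
    "SourceType",
    "BibliographicRecord",
    "Metric",
    "ReportedResult",
    "Direction",
    "Uncertainty",
    "ConclusionAssessment",
    "MethodsProfile",
    "SourceVersion",
    "UsageMetrics",
    "StudyDesign",
    "PreprintSource",
    "ArticleSource",
    "Study",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "read_bibliographic_records",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or invariant violations."""


class SourceType(str, Enum):
    preprint = "preprint"
    journal_article = "journal_article"


class Author(BaseModel):
    """One byline entry; ``given`` may be a full name or initials."""

    family: str = Field(min_length=1)
    given: str = ""
    orcid: Optional[str] = None


class BibliographicRecord(BaseModel):
    """A work record for one preprint or journal article."""

    record_id: str
    source_type: SourceType
    title: str
    authors: list[Author] = Field(min_length=1)
    online_date: dt.date
    venue: str = ""
    doi: Optional[str] = None
    registration_id: Optional[str] = None
    version_count: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _article_single_version(self) -> "BibliographicRecord":
        if self.source_type is SourceType.journal_article and self.version_count != 1:
            raise ValueError("journal articles carry exactly one version")
        return self


class Metric(str, Enum):
    hazard_ratio = "hazard_ratio"
    odds_ratio = "odds_ratio"
    relative_risk = "relative_risk"
    event_rate = "event_rate"
    correlation = "correlation"
    regression_coefficient = "regression_coefficient"


class ReportedResult(BaseModel):
    """An effect estimate for one outcome.

    ``event_rate`` estimates live on the percent scale (0–100).
    """

    outcome_label: str
    metric: Metric
    estimate: Optional[float] = None
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ReportedResult":
        if self.estimate is None and self.p_value is None:
            raise ValueError("at least one of estimate/p_value must be present")
        if self.metric is Metric.event_rate and self.estimate is not None:
            if not 0.0 <= self.estimate <= 100.0:
                raise ValueError("event_rate estimates are percentages in [0, 100]")
        return self


class Direction(str, Enum):
    positive = "positive"
    neutral = "neutral"
    negative = "negative"


class Uncertainty(str, Enum):
    reported = "reported"
    not_reported = "not_reported"


class ConclusionAssessment(BaseModel):
    """Coded stance of an abstract conclusion toward the intervention."""

    direction: Direction
    uncertainty: Uncertainty

    model_config = {"frozen": True}


class MethodsProfile(BaseModel):
    """Methodologic fields whose changes could affect a risk-of-bias appraisal."""

    blinding: Optional[str] = None
    missing_data: Optional[str] = None
    randomization_allocation: Optional[str] = None
    participant_inclusion: Optional[str] = None
    confounder_adjustment: Optional[str] = None

    FIELD_ORDER: ClassVar[tuple[str, ...]] = (
        "blinding",
        "missing_data",
        "randomization_allocation",
        "participant_inclusion",
        "confounder_adjustment",
    )


class SourceVersion(BaseModel):
    """One dated version of an evidence source.

    ``sample_size`` is the number of individuals enrolled, or the number of
    countries/regions analyzed for population-level policy studies.
    """

    version_number: int = Field(ge=1)
    date: dt.date
    results: list[ReportedResult] = Field(default_factory=list)
    sample_size: int = Field(default=0, ge=0)
    conclusion_text: Optional[str] = None
    conclusion: Optional[ConclusionAssessment] = None
    methods_profile: Optional[MethodsProfile] = None

    @model_validator(mode="after")
    def _conclusion_present(self) -> "SourceVersion":
        if self.conclusion is None and self.conclusion_text is None:
            raise ValueError("either conclusion or conclusion_text must be present")
        return self


class UsageMetrics(BaseModel):
    citations: int = Field(ge=0)
    attention_score: float = Field(ge=0.0)
    pubpeer_comments: int = Field(ge=0)
    retrieval_date: dt.date


class StudyDesign(str, Enum):
    rct = "rct"
    observational = "observational"


class PreprintSource(BaseModel):
    record: BibliographicRecord
    versions: list[SourceVersion] = Field(min_length=1)

    @model_validator(mode="after")
    def _ordered(self) -> "PreprintSource":
        if self.record.source_type is not SourceType.preprint:
            raise ValueError("preprint source must carry a preprint record")
        nums = [v.version_number for v in self.versions]
        if nums != sorted(set(nums)):
            raise ValueError("versions must be strictly ordered by version_number")
        dates = [v.date for v in self.versions]
        if dates != sorted(dates):
            raise ValueError("preprint versions must be sorted by date")
        return self


class ArticleSource(BaseModel):
    record: BibliographicRecord
    version: SourceVersion

    @model_validator(mode="after")
    def _is_article(self) -> "ArticleSource":
        if self.record.source_type is not SourceType.journal_article:
            raise ValueError("article source must carry a journal_article record")
        return self


class Study(BaseModel):
    study_id: str
    design: StudyDesign
    intervention_category: str = ""
    preprint: Optional[PreprintSource] = None
    article: Optional[ArticleSource] = None
    preprint_usage: Optional[UsageMetrics] = None
    article_usage: Optional[UsageMetrics] = None

    @model_validator(mode="after")
    def _at_least_one_source(self) -> "Study":
        if self.preprint is None and self.article is None:
            raise ValueError("study must carry at least one evidence source")
        return self

    @property
    def is_multisource(self) -> bool:
        """True when more than one source or more than one preprint version exists."""
        multi_version = self.preprint is not None and len(self.preprint.versions) > 1
        both = self.preprint is not None and self.article is not None
        return multi_version or both


# ---------------------------------------------------------------------------
# corpus I/O


def write_corpus(studies: Iterable[Study], path: str | Path) -> None:
    """Write studies as JSON Lines, one study per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for study in studies:
            fh.write(study.model_dump_json(exclude_none=True))
            fh.write("\n")


def read_corpus(path: str | Path) -> list[Study]:
    """Read a JSON Lines corpus, preserving study order.

    Lines starting with ``#`` (provenance headers) and blank lines are
    skipped. Raises :class:`CorpusError` naming the offending line on parse
    failure, or the study and field on an invariant violation.
    """
    path = Path(path)
    studies: list[Study] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            try:
                studies.append(Study.model_validate(payload))
            except ValidationError as exc:
                sid = payload.get("study_id", "<unknown>") if isinstance(payload, dict) else "<unknown>"
                fields = ", ".join(
                    ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
                )
                raise CorpusError(
                    f"line {lineno}: study {sid!r} failed validation on: {fields}"
                ) from exc
    return studies


# CSL-JSON date precedence: Crossref preprints carry "posted", articles "issued".
_CSL_DATE_KEYS = ("posted", "issued", "created")


def _csl_date(record: dict) -> Optional[dt.date]:
    for key in _CSL_DATE_KEYS:
        block = record.get(key)
        if not isinstance(block, dict):
            continue
        parts = block.get("date-parts")
        if not parts or not parts[0] or parts[0][0] is None:
            continue
        ymd = list(parts[0]) + [1, 1]  # missing month/day default to the 1st
        return dt.date(int(ymd[0]), int(ymd[1]), int(ymd[2]))
    return None


def read_bibliographic_records(
    path: str | Path, source_type: SourceType | str = SourceType.preprint
) -> list[BibliographicRecord]:
    """Read a CSL-JSON array of work records.

    Maps title, author given/family/ORCID and the first available date
    (posted > issued > created) into :class:`BibliographicRecord`; unknown
    fields are ignored. ``source_type`` labels all records in the file.
    """
    path = Path(path)
    source_type = SourceType(source_type)
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise CorpusError("CSL-JSON input must be an array of work records")
    records: list[BibliographicRecord] = []
    for idx, item in enumerate(raw):
        authors = [
            Author(
                family=a.get("family", ""),
                given=a.get("given", ""),
                orcid=a.get("ORCID"),
            )
            for a in item.get("author", [])
            if a.get("family")
        ]
        date = _csl_date(item)
        if not authors or date is None:
            raise CorpusError(f"record {idx}: missing authors or date")
        title = item.get("title", "")
        if isinstance(title, list):  # some CSL emitters wrap title in a list
            title = title[0] if title else ""
        records.append(
            BibliographicRecord(
                record_id=item.get("id") or item.get("DOI") or f"record-{idx}",
                source_type=source_type,
                title=title,
                authors=authors,
                online_date=date,
                venue=item.get("container-title", "") or "",
                doi=item.get("DOI"),
                registration_id=item.get("registration-id"),
                version_count=int(item.get("version-count", 1)),
            )
        )
    return records
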