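"""Synthetic corpora with known ground truth for the full pipeline.

Emulates a corpus of COVID-19 intervention studies in which each study may
be reported as a preprint (with one or more dated versions) and/or a
journal article. Defaults reproduce the published corpus shape: 556
studies, 61% preprint-reported, 19.5% of preprints later published
(log-normal delay, median 76 days), 27% of preprints multi-version, and —
among multi-source studies — change rates of 45% (any component), 30%
(results), 21% (important) and 24% (conclusion).

Planted changes are constructed to satisfy exactly the classification
rules of :mod:`evidencedrift.change_detection` at default criteria, so
detector output can be checked against ground truth on every seed.
Bibliographic metadata of article records is perturbed (initials,
diacritics, token swaps, dropped middle authors, date shifts) to stress
the record-linkage stage.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus_model import (
    ArticleSource,
    Author,
    BibliographicRecord,
    ConclusionAssessment,
    Direction,
    MethodsProfile,
    Metric,
    PreprintSource,
    ReportedResult,
    SourceType,
    SourceVersion,
    Study,
    StudyDesign,
    Uncertainty,
    UsageMetrics,
)

__all__ = [
    "GeneratorParams",
    "PlantedFlags",
    "GroundTruth",
    "generate_corpus",
    "perturb_record",
    "plant_changes",
    "generate_fixture_corpus",
    "generate_linkage_validation",
]


class GeneratorParams(BaseModel):
    """Corpus-level parameters; defaults state the emulated corpus."""

    n_studies: int = Field(default=556, ge=0)
    p_preprint: float = Field(default=0.61, ge=0.0, le=1.0)
    p_article_given_preprint: float = Field(default=0.195, ge=0.0, le=1.0)
    p_multiversion_given_preprint: float = Field(default=0.27, ge=0.0, le=1.0)
    delay_log_median_days: float = Field(default=76.0, gt=0.0)
    delay_log_sigma: float = Field(default=0.49, gt=0.0)
    p_any_change: float = Field(default=0.45, ge=0.0, le=1.0)
    p_result_change: float = Field(default=0.30, ge=0.0, le=1.0)
    p_important_change: float = Field(default=0.21, ge=0.0, le=1.0)
    p_conclusion_change: float = Field(default=0.24, ge=0.0, le=1.0)
    perturbation_level: float = Field(default=0.3, ge=0.0, le=1.0)
    independent_changes: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "GeneratorParams":
        if not (self.p_important_change <= self.p_result_change <= self.p_any_change):
            raise ValueError("require p_important_change <= p_result_change <= p_any_change")
        if not self.independent_changes:
            # coupled planting needs a feasible result/conclusion overlap
            overlap = self.p_result_change + self.p_conclusion_change - self.p_any_change
            if overlap < -1e-12 or overlap > min(self.p_result_change, self.p_conclusion_change) + 1e-12:
                raise ValueError(
                    "p_any_change incompatible with result/conclusion marginals; "
                    "set independent_changes=True or adjust probabilities"
                )
        return self


class PlantedFlags(BaseModel):
    """Ground-truth change flags planted into one multi-source study."""

    result_changed: bool = False
    important: bool = False
    p_crossed: bool = False
    conclusion_changed: bool = False
    sample_size_changed: bool = False

    @model_validator(mode="after")
    def _chain(self) -> "PlantedFlags":
        if self.important and not self.result_changed:
            raise ValueError("important change requires result_changed")
        if self.p_crossed and not self.important:
            raise ValueError("a p-value crossing is by definition an important change")
        return self


class GroundTruth(BaseModel):
    true_links: set[tuple[str, str]] = Field(default_factory=set)
    planted_changes: dict[str, PlantedFlags] = Field(default_factory=dict)


# ---------------------------------------------------------------------------
# deterministic substreams: outcomes keyed by (seed, record id), so the
# insertion order of studies never changes any study's realization


def _substream(seed: int, *keys: object) -> np.random.Generator:
    payload = f"{seed}::" + "|".join(str(k) for k in keys)
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


# ---------------------------------------------------------------------------
# name / title / conclusion material

_FAMILIES = [
    "Müller", "García", "Sørensen", "Nguyen", "Dubois", "Rossi", "Novák",
    "Kowalski", "Silva", "Johansson", "Papadopoulos", "Yamamoto", "Chen",
    "Kim", "Okafor", "Haddad", "Petrov", "Fernández", "Schneider", "Moreau",
    "Costa", "Olsen", "Horváth", "Díaz", "Laurent", "Ricci", "Weber",
    "Jansen", "O'Brien", "Almeida", "Keller", "Braun", "Sato", "Leroy",
    "Vargas", "Nilsen", "Takahashi", "Björk", "Castillo", "Nakamura",
]
_GIVENS = [
    "Émile", "Théodora", "Isabelle", "Olivier", "Guillaume", "Philippe",
    "Anna", "José", "Søren", "Lucía", "Marta", "Pavel", "Ingrid", "Hiroshi",
    "Wei", "Min", "Amara", "Rania", "Nikolai", "Clara", "Stefan", "Élodie",
    "Tomás", "Greta", "Jonas", "Mária", "Pierre", "Aiko", "Dmitri", "Sofia",
]
_DRUGS = [
    "remdesivir", "hydroxychloroquine", "lopinavir ritonavir", "tocilizumab",
    "convalescent plasma", "dexamethasone", "favipiravir", "interferon beta",
    "azithromycin", "ivermectin", "baricitinib", "colchicine",
]
_POLICIES = [
    "lockdown measures", "school closures", "travel restrictions",
    "mask mandates", "contact tracing", "social distancing policies",
]
_OUTCOME_WORDS = [
    "mortality", "clinical improvement", "viral clearance", "hospitalization",
    "oxygen requirement", "symptom duration", "icu admission", "case growth",
]
_POPULATIONS = [
    "hospitalized adults", "outpatients", "critically ill patients",
    "elderly patients", "healthcare workers", "the general population",
]
_JOURNALS = [
    "Journal of Infection", "Clinical Trials Review", "Respiratory Medicine Reports",
    "International Epidemiology Letters", "Critical Care Insights", "Global Health Advances",
]
_INTERVENTION_CATEGORIES = [
    ("social distancing or lockdown", 0.17),
    ("antimalarials", 0.14),
    ("monoclonal antibodies", 0.10),
    ("corticosteroids", 0.07),
    ("other", 0.52),
]

_OUTCOME_LABELS = [
    ("28-day mortality", Metric.hazard_ratio),
    ("clinical improvement", Metric.odds_ratio),
    ("viral clearance at day 7", Metric.relative_risk),
    ("adverse events", Metric.event_rate),
    ("icu admission", Metric.odds_ratio),
    ("case growth rate", Metric.regression_coefficient),
]

# Templates are chosen so the cue lexicon recovers the coded state exactly.
_CONCLUSION_TEMPLATES: dict[tuple[Direction, Uncertainty], str] = {
    (Direction.positive, Uncertainty.not_reported):
        "These results prove the efficacy of {drug} in {population}.",
    (Direction.positive, Uncertainty.reported):
        "{drug} might be effective in {population}; further studies are needed to confirm these findings.",
    (Direction.neutral, Uncertainty.not_reported):
        "No difference was observed between the {drug} group and the control group in {population}.",
    (Direction.neutral, Uncertainty.reported):
        "No difference was observed between groups; these findings should be confirmed in larger cohorts of {population}.",
    (Direction.negative, Uncertainty.not_reported):
        "Treatment with {drug} was associated with increased mortality and a higher adverse effect rate in {population}.",
    (Direction.negative, Uncertainty.reported):
        "{drug} may be harmful in {population}; caution is warranted pending additional studies.",
}


def _conclusion_text(state: ConclusionAssessment, drug: str, population: str) -> str:
    template = _CONCLUSION_TEMPLATES[(state.direction, state.uncertainty)]
    return template.format(drug=drug.capitalize(), population=population)


def _orcid(rng: np.random.Generator) -> str:
    return "0000-000{}-{}-{}".format(
        rng.integers(1, 4), f"{rng.integers(0, 10**4):04d}", f"{rng.integers(0, 10**4):04d}"
    )


def _authors(rng: np.random.Generator) -> list[Author]:
    n = int(rng.integers(3, 13))
    fams = rng.choice(len(_FAMILIES), size=n, replace=False)
    authors = []
    for k in fams:
        given = _GIVENS[int(rng.integers(0, len(_GIVENS)))]
        orcid = _orcid(rng) if rng.random() < 0.5 else None
        authors.append(Author(family=_FAMILIES[int(k)], given=given, orcid=orcid))
    return authors


def _title(rng: np.random.Generator, drug: str) -> str:
    head = ["Efficacy", "Effect", "Impact", "Association"][int(rng.integers(0, 4))]
    outcome = _OUTCOME_WORDS[int(rng.integers(0, len(_OUTCOME_WORDS)))]
    outcome2 = _OUTCOME_WORDS[int(rng.integers(0, len(_OUTCOME_WORDS)))]
    population = _POPULATIONS[int(rng.integers(0, len(_POPULATIONS)))]
    tail = [
        "a randomized controlled trial",
        "a retrospective cohort analysis",
        "an interrupted time series analysis",
        "a multicenter observational study",
    ][int(rng.integers(0, 4))]
    return f"{head} of {drug} on {outcome} and {outcome2} in {population}: {tail}"


# ---------------------------------------------------------------------------
# record perturbation


def _strip_marks(text: str) -> str:
    import unicodedata

    return "".join(
        c for c in unicodedata.normalize("NFKD", text) if not unicodedata.combining(c)
    )


def perturb_record(record: BibliographicRecord, level: float, seed: int) -> BibliographicRecord:
    """Metadata noise mimicking preprint-to-journal record divergence.

    With probability scaled by ``level`` each: given names collapse to
    initials, diacritics are stripped, two adjacent title tokens swap, one
    middle author is dropped, and the online date shifts by up to 5 days.
    ``level=0`` returns the record unchanged; the first author's family
    name is never altered.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    if level == 0.0:
        return record.model_copy(deep=True)
    rng = _substream(seed, "perturb", record.record_id)
    authors = [a.model_copy() for a in record.authors]
    for idx, author in enumerate(authors):
        if rng.random() < level and author.given:
            author.given = author.given[0] + "."
        if rng.random() < level:
            if idx > 0:
                author.family = _strip_marks(author.family)
            author.given = _strip_marks(author.given)
    if len(authors) > 2 and rng.random() < level:
        drop = int(rng.integers(1, len(authors) - 1))  # never first or last author
        authors.pop(drop)
    title = record.title
    tokens = title.split()
    if len(tokens) >= 2 and rng.random() < level:
        pos = int(rng.integers(0, len(tokens) - 1))
        tokens[pos], tokens[pos + 1] = tokens[pos + 1], tokens[pos]
        title = " ".join(tokens)
    date = record.online_date
    if rng.random() < level:
        date = date + dt.timedelta(days=int(rng.integers(-5, 6)))
    return record.model_copy(
        update={"authors": authors, "title": title, "online_date": date}, deep=True
    )


# ---------------------------------------------------------------------------
# version content and planted changes


def _base_results(rng: np.random.Generator) -> list[ReportedResult]:
    n = int(rng.integers(1, 4))
    picks = rng.choice(len(_OUTCOME_LABELS), size=n, replace=False)
    results = []
    for k in picks:
        label, metric = _OUTCOME_LABELS[int(k)]
        if metric is Metric.event_rate:
            estimate = float(np.round(rng.uniform(5.0, 60.0), 1))
        elif metric is Metric.regression_coefficient:
            estimate = float(np.round(rng.uniform(0.2, 2.0) * (1 if rng.random() < 0.5 else -1), 3))
        else:
            estimate = float(np.round(np.exp(rng.normal(0.0, 0.5)), 2)) or 1.0
        p = float(np.round(rng.uniform(0.001, 0.6), 3))
        if abs(p - 0.05) < 1e-6:
            p = 0.06
        results.append(ReportedResult(outcome_label=label, metric=metric, estimate=estimate, p_value=p))
    return results


def _shift_estimate(result: ReportedResult, rel: float, rng: np.random.Generator) -> ReportedResult:
    est = result.estimate
    assert est is not None and est != 0
    sign = 1.0 if rng.random() < 0.5 else -1.0
    new = est * (1.0 + sign * rel)
    if result.metric is Metric.event_rate and not (0.0 <= new <= 100.0):
        new = est * (1.0 - rel)
    return result.model_copy(update={"estimate": new})


def plant_changes(study: Study, flags: PlantedFlags, seed: int) -> Study:
    """Rewrite the later sources of ``study`` so that change detection at
    default criteria recovers exactly ``flags``.

    The first preprint version is the baseline; every later preprint
    version and the article receive the same final content, so the OR of
    per-pair verdicts equals the planted study-level flags. Requires a
    multi-source study.
    """
    if not study.is_multisource:
        raise ValueError("plant_changes requires a multi-source study")
    rng = _substream(seed, "plant", study.study_id)
    base = study.preprint.versions[0] if study.preprint else study.article.version
    results = [r.model_copy() for r in base.results]
    sample_size = base.sample_size
    if flags.result_changed:
        if flags.p_crossed:
            with_p = [k for k, r in enumerate(results) if r.p_value is not None]
            if not with_p:
                raise ValueError("cannot plant a p-value crossing: no result carries a p value")
            target = with_p[int(rng.integers(0, len(with_p)))]
            old_p = results[target].p_value
            if old_p < 0.05:
                new_p = float(rng.uniform(0.06, 0.4))
            else:
                new_p = float(rng.uniform(0.005, 0.045))
            results[target] = results[target].model_copy(update={"p_value": new_p})
        elif flags.important:
            target = int(rng.integers(0, len(results)))
            rel = float(rng.uniform(0.10, 0.60))
            results[target] = _shift_estimate(results[target], rel, rng)
        else:
            target = int(rng.integers(0, len(results)))
            rel = float(rng.uniform(0.02, 0.08))
            results[target] = _shift_estimate(results[target], rel, rng)
    if flags.sample_size_changed:
        sample_size = sample_size + max(1, int(round(sample_size * float(rng.uniform(0.1, 0.6)))))
    conclusion = base.conclusion
    if flags.conclusion_changed:
        assert conclusion is not None
        if (conclusion.direction, conclusion.uncertainty) == (
            Direction.positive,
            Uncertainty.not_reported,
        ):
            # dominant observed flow: positive without uncertainty -> with
            conclusion = ConclusionAssessment(
                direction=Direction.positive, uncertainty=Uncertainty.reported
            )
        elif conclusion.direction is Direction.neutral:
            conclusion = ConclusionAssessment(
                direction=Direction.positive, uncertainty=conclusion.uncertainty
            )
        else:
            flipped = (
                Uncertainty.reported
                if conclusion.uncertainty is Uncertainty.not_reported
                else Uncertainty.not_reported
            )
            conclusion = ConclusionAssessment(direction=conclusion.direction, uncertainty=flipped)
    drug = study.intervention_category
    population = "the study population"

    def final_version(template: SourceVersion) -> SourceVersion:
        return template.model_copy(
            update={
                "results": [r.model_copy() for r in results],
                "sample_size": sample_size,
                "conclusion": conclusion,
                "conclusion_text": _conclusion_text(conclusion, drug, population)
                if conclusion is not None
                else template.conclusion_text,
                "methods_profile": base.methods_profile.model_copy()
                if base.methods_profile
                else None,
            }
        )

    new_study = study.model_copy(deep=True)
    if new_study.preprint is not None:
        versions = new_study.preprint.versions
        new_study.preprint = PreprintSource(
            record=new_study.preprint.record,
            versions=[versions[0]] + [final_version(v) for v in versions[1:]],
        )
    if new_study.article is not None:
        new_study.article = ArticleSource(
            record=new_study.article.record, version=final_version(new_study.article.version)
        )
    return new_study


# ---------------------------------------------------------------------------
# study assembly


def _make_version(
    rng: np.random.Generator,
    version_number: int,
    date: dt.date,
    results: list[ReportedResult],
    sample_size: int,
    state: ConclusionAssessment,
    drug: str,
    population: str,
    methods: Optional[MethodsProfile],
) -> SourceVersion:
    return SourceVersion(
        version_number=version_number,
        date=date,
        results=[r.model_copy() for r in results],
        sample_size=sample_size,
        conclusion=state,
        conclusion_text=_conclusion_text(state, drug, population),
        methods_profile=methods.model_copy() if methods else None,
    )


def _methods_profile(rng: np.random.Generator, design: StudyDesign) -> MethodsProfile:
    if design is StudyDesign.rct:
        return MethodsProfile(
            blinding=["open label", "double blind", "assessor blinded"][int(rng.integers(0, 3))],
            missing_data="complete case analysis",
            randomization_allocation="central randomization, sealed envelopes",
            participant_inclusion="all randomized participants analyzed",
        )
    return MethodsProfile(
        missing_data="multiple imputation",
        participant_inclusion="consecutive admissions",
        confounder_adjustment=["age and sex adjusted", "propensity score"][int(rng.integers(0, 2))],
    )


def _build_study(
    index: int,
    seed: int,
    *,
    has_preprint: bool,
    has_article: bool,
    n_versions: int,
    flags: Optional[PlantedFlags],
    perturbation_level: float,
    delay_log_median: float,
    delay_log_sigma: float,
    base_conclusion: Optional[ConclusionAssessment] = None,
) -> tuple[Study, Optional[tuple[str, str]]]:
    study_id = f"study-{index:04d}"
    rng = _substream(seed, "study", study_id)
    design = StudyDesign.rct if rng.random() < 0.3 else StudyDesign.observational
    cat_probs = np.array([w for _, w in _INTERVENTION_CATEGORIES])
    category = _INTERVENTION_CATEGORIES[
        int(rng.choice(len(_INTERVENTION_CATEGORIES), p=cat_probs / cat_probs.sum()))
    ][0]
    drug = _DRUGS[int(rng.integers(0, len(_DRUGS)))] if design is StudyDesign.rct else (
        _DRUGS[int(rng.integers(0, len(_DRUGS)))]
        if rng.random() < 0.6
        else _POLICIES[int(rng.integers(0, len(_POLICIES)))]
    )
    population = _POPULATIONS[int(rng.integers(0, len(_POPULATIONS)))]
    authors = _authors(rng)
    title = _title(rng, drug)
    registration = (
        f"NCT{rng.integers(10**7, 10**8)}" if design is StudyDesign.rct and rng.random() < 0.8 else None
    )
    first_date = dt.date(2020, 1, 15) + dt.timedelta(days=int(rng.integers(0, 213)))

    results = _base_results(rng)
    sample_size = (
        int(rng.integers(40, 800)) if design is StudyDesign.rct else int(rng.integers(60, 5000))
    )
    if base_conclusion is not None:
        state = base_conclusion
    else:
        directions = (Direction.positive, Direction.neutral, Direction.negative)
        state = ConclusionAssessment(
            direction=directions[int(rng.choice(3, p=[0.5, 0.35, 0.15]))],
            uncertainty=Uncertainty.reported if rng.random() < 0.5 else Uncertainty.not_reported,
        )
    methods = _methods_profile(rng, design)

    preprint = None
    article = None
    link: Optional[tuple[str, str]] = None
    if has_preprint:
        pp_record = BibliographicRecord(
            record_id=f"pp-{index:04d}",
            source_type=SourceType.preprint,
            title=title,
            authors=authors,
            online_date=first_date,
            venue="medRxiv",
            doi=f"10.1101/2020.{index:04d}",
            registration_id=registration,
            version_count=n_versions,
        )
        versions = []
        date = first_date
        for v in range(1, n_versions + 1):
            if v > 1:
                date = date + dt.timedelta(days=int(rng.integers(7, 46)))
            versions.append(
                _make_version(rng, v, date, results, sample_size, state, drug, population, methods)
            )
        preprint = PreprintSource(record=pp_record, versions=versions)
    if has_article:
        if has_preprint:
            delay = max(
                1, int(round(rng.lognormal(math.log(delay_log_median), delay_log_sigma)))
            )
            art_date = first_date + dt.timedelta(days=delay)
        else:
            art_date = first_date
        art_record = BibliographicRecord(
            record_id=f"art-{index:04d}",
            source_type=SourceType.journal_article,
            title=title,
            authors=authors,
            online_date=art_date,
            venue=_JOURNALS[int(rng.integers(0, len(_JOURNALS)))],
            doi=f"10.5555/j.{index:04d}",
            registration_id=registration,
        )
        if has_preprint:
            art_record = perturb_record(art_record, perturbation_level, seed)
            link = (f"pp-{index:04d}", f"art-{index:04d}")
        article = ArticleSource(
            record=art_record,
            version=_make_version(
                rng, 1, art_date, results, sample_size, state, drug, population, methods
            ),
        )

    usage_pp = usage_art = None
    if has_preprint and has_article:
        retrieval = max(dt.date(2020, 10, 21), art_date + dt.timedelta(days=30))
        usage_pp = UsageMetrics(
            citations=int(rng.poisson(8)),
            attention_score=float(np.round(rng.gamma(2.0, 10.0), 1)),
            pubpeer_comments=int(rng.random() < 0.08),
            retrieval_date=retrieval,
        )
        usage_art = UsageMetrics(
            citations=int(rng.poisson(20)),
            attention_score=float(np.round(rng.gamma(2.0, 15.0), 1)),
            pubpeer_comments=int(rng.random() < 0.05),
            retrieval_date=retrieval,
        )

    study = Study(
        study_id=study_id,
        design=design,
        intervention_category=drug,
        preprint=preprint,
        article=article,
        preprint_usage=usage_pp,
        article_usage=usage_art,
    )
    if flags is not None and study.is_multisource:
        study = plant_changes(study, flags, seed)
    return study, link


def _draw_flags(rng: np.random.Generator, params: GeneratorParams) -> PlantedFlags:
    p_r, p_c, p_any = params.p_result_change, params.p_conclusion_change, params.p_any_change
    result = rng.random() < p_r
    important = result and rng.random() < (params.p_important_change / p_r if p_r else 0.0)
    p_crossed = important and rng.random() < 0.5
    if params.independent_changes or p_r in (0.0, 1.0):
        conclusion = rng.random() < p_c
    else:
        overlap = min(max(p_r + p_c - p_any, 0.0), min(p_r, p_c))
        conclusion = rng.random() < (overlap / p_r if result else (p_c - overlap) / (1.0 - p_r))
    sample_changed = result and rng.random() < (1.0 / 3.0)  # 18 of 54 result changes
    return PlantedFlags(
        result_changed=result,
        important=important,
        p_crossed=p_crossed,
        conclusion_changed=conclusion,
        sample_size_changed=sample_changed,
    )


def _n_versions(rng: np.random.Generator, multiversion: bool) -> int:
    if not multiversion:
        return 1
    n = 2
    while n < 6 and rng.random() < 0.35:
        n += 1
    return n


def generate_corpus(params: GeneratorParams | None = None) -> tuple[list[Study], GroundTruth]:
    """Generate a corpus plus its ground truth, deterministic in the seed."""
    params = params or GeneratorParams()
    truth = GroundTruth()
    studies: list[Study] = []
    for i in range(params.n_studies):
        rng = _substream(params.seed, "structure", i)
        has_pp = rng.random() < params.p_preprint
        has_art = (rng.random() < params.p_article_given_preprint) if has_pp else True
        n_versions = _n_versions(rng, has_pp and rng.random() < params.p_multiversion_given_preprint)
        multisource = has_pp and (has_art or n_versions > 1)
        flags = _draw_flags(rng, params) if multisource else None
        base_conclusion = None
        if flags is not None and flags.conclusion_changed:
            # seed the from-state so planted transitions follow the observed
            # mix, dominated by positive/no-uncertainty starts
            u = rng.random()
            if u < 0.45:
                base_conclusion = ConclusionAssessment(
                    direction=Direction.positive, uncertainty=Uncertainty.not_reported
                )
            elif u < 0.75:
                base_conclusion = ConclusionAssessment(
                    direction=Direction.neutral,
                    uncertainty=Uncertainty.reported if u < 0.6 else Uncertainty.not_reported,
                )
            else:
                base_conclusion = ConclusionAssessment(
                    direction=Direction.negative if u < 0.85 else Direction.positive,
                    uncertainty=Uncertainty.reported,
                )
        study, link = _build_study(
            i,
            params.seed,
            has_preprint=has_pp,
            has_article=has_art,
            n_versions=n_versions,
            flags=flags,
            perturbation_level=params.perturbation_level,
            delay_log_median=params.delay_log_median_days,
            delay_log_sigma=params.delay_log_sigma,
            base_conclusion=base_conclusion,
        )
        studies.append(study)
        if link is not None:
            truth.true_links.add(link)
        if flags is not None:
            truth.planted_changes[study.study_id] = flags
    return studies, truth


# ---------------------------------------------------------------------------
# deterministic fixture reproducing the printed corpus marginals


def generate_fixture_corpus(seed: int = 0) -> tuple[list[Study], GroundTruth, set[str]]:
    """A 556-study corpus with exactly the published marginal counts.

    338 preprint-reported studies, 66 published as articles, 91 with > 1
    preprint version (18 with both), hence 139 multi-source; planted
    change counts 63/42/29/33 (any/results/important/conclusion). Returns
    (studies, ground truth, subgroup study ids) where the 25-study
    quantitative-synthesis subgroup contains exactly 15 changed studies.
    """
    studies: list[Study] = []
    truth = GroundTruth()
    subgroup: set[str] = set()
    for i in range(556):
        has_pp = i < 338
        has_art = i < 66 or i >= 338
        multiversion = has_pp and 48 <= i < 139
        rng = _substream(seed, "fixture", i)
        n_versions = _n_versions(rng, multiversion)
        flags = None
        if has_pp and i < 139:  # the multi-source block
            result = i < 42
            important = i < 29
            p_crossed = i < 10
            conclusion = 30 <= i < 63
            flags = PlantedFlags(
                result_changed=result,
                important=important,
                p_crossed=p_crossed,
                conclusion_changed=conclusion,
                sample_size_changed=result and (i % 3 == 0),
            )
        base_conclusion = None
        if flags is not None and flags.conclusion_changed:
            base_conclusion = ConclusionAssessment(
                direction=Direction.positive, uncertainty=Uncertainty.not_reported
            )
        study, link = _build_study(
            i,
            seed,
            has_preprint=has_pp,
            has_article=has_art,
            n_versions=n_versions,
            flags=flags,
            perturbation_level=0.0,
            delay_log_median=76.0,
            delay_log_sigma=0.49,
            base_conclusion=base_conclusion,
        )
        studies.append(study)
        if link is not None:
            truth.true_links.add(link)
        if flags is not None:
            truth.planted_changes[study.study_id] = flags
        if 48 <= i < 63 or 63 <= i < 73:  # 15 changed + 10 unchanged multi-source
            subgroup.add(study.study_id)
    return studies, truth, subgroup


# ---------------------------------------------------------------------------
# linkage validation harness


def generate_linkage_validation(
    n_true: int = 740,
    n_decoys: int = 300,
    level: float = 0.3,
    seed: int = 0,
) -> tuple[list[BibliographicRecord], list[BibliographicRecord], set[tuple[str, str]]]:
    """True preprint–article pairs plus decoy articles for linkage validation.

    Registration IDs are withheld so the metadata scorer — not the
    registration short-circuit — is exercised. Articles of true pairs are
    perturbed copies of their preprints at ``level``; decoys are unrelated
    records. Returns (preprints, articles, true id pairs).
    """
    preprints: list[BibliographicRecord] = []
    articles: list[BibliographicRecord] = []
    true_pairs: set[tuple[str, str]] = set()
    for i in range(n_true):
        rng = _substream(seed, "val-true", i)
        drug = _DRUGS[int(rng.integers(0, len(_DRUGS)))]
        date = dt.date(2020, 1, 15) + dt.timedelta(days=int(rng.integers(0, 213)))
        pp = BibliographicRecord(
            record_id=f"vpp-{i:04d}",
            source_type=SourceType.preprint,
            title=_title(rng, drug),
            authors=_authors(rng),
            online_date=date,
            venue="medRxiv",
        )
        delay = max(1, int(round(rng.lognormal(math.log(76.0), 0.49))))
        art = pp.model_copy(
            update={
                "record_id": f"vart-{i:04d}",
                "source_type": SourceType.journal_article,
                "online_date": date + dt.timedelta(days=delay),
                "venue": _JOURNALS[int(rng.integers(0, len(_JOURNALS)))],
            },
            deep=True,
        )
        art = perturb_record(art, level, seed)
        preprints.append(pp)
        articles.append(art)
        true_pairs.add((pp.record_id, art.record_id))
    for i in range(n_decoys):
        rng = _substream(seed, "val-decoy", i)
        drug = _DRUGS[int(rng.integers(0, len(_DRUGS)))]
        articles.append(
            BibliographicRecord(
                record_id=f"vdec-{i:04d}",
                source_type=SourceType.journal_article,
                title=_title(rng, drug),
                authors=_authors(rng),
                online_date=dt.date(2020, 1, 15) + dt.timedelta(days=int(rng.integers(0, 260))),
                venue=_JOURNALS[int(rng.integers(0, len(_JOURNALS)))],
            )
        )
    return preprints, articles, true_pairs
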