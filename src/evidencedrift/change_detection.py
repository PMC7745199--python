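"""Classify changes in evidence between sources/versions of one study.

Two evidence components are compared: study results (numeric change in any
effect estimate, or the p value crossing the 0.05 significance threshold)
and the abstract conclusion (direction positive/neutral/negative, plus
whether uncertainty is reported). A result change counts as *important*
when any effect estimate moved by >= 10% of its initial value and/or a
p value crossed 0.05. For the quantitative-synthesis subgroup, field-wise
changes in risk-of-bias-relevant methods descriptions are also detected.

Conventions fixed here (see docs/methods.md): p = alpha exactly is "not
significant" (strict <); event-rate changes are relative to the initial
value, not percentage points; outcomes present in only one version are
counted as added/removed but do not by themselves set ``result_changed``.
"""

from __future__ import annotations

import math
import re
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .corpus_model import (
    ConclusionAssessment,
    Direction,
    MethodsProfile,
    ReportedResult,
    SourceVersion,
    Study,
    Uncertainty,
)

__all__ = [
    "ChangeCriteria",
    "PairType",
    "ChangeRecord",
    "relative_change",
    "p_crossing",
    "pair_results",
    "classify_result_change",
    "classify_conclusion",
    "conclusion_changed",
    "detect_methods_changes",
    "compare_sources",
    "AmbiguousResultsError",
    "UndefinedChangeError",
    "DEFAULT_LEXICON",
    "changes_to_frame",
    "frame_to_changes",
]


class UndefinedChangeError(ValueError):
    """Relative change is undefined for an initial value of zero."""


class AmbiguousResultsError(ValueError):
    """Duplicate (outcome label, metric) keys within one result list."""


class ChangeCriteria(BaseModel):
    """Thresholds governing change classification.

    relative_change_threshold
        Minimum relative change of an effect estimate (vs its initial
        value) for a result change to be *important*. Default 0.10.
    alpha
        Significance threshold whose crossing makes a change important.
    numeric_tolerance
        Two values within this tolerance are "unchanged"; guards against
        rounding artifacts in transcribed reports.
    """

    relative_change_threshold: float = Field(default=0.10, gt=0.0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    numeric_tolerance: float = Field(default=1e-9, ge=0.0)


class PairType(str, Enum):
    first_preprint_vs_article = "first_preprint_vs_article"
    latest_preprint_vs_article = "latest_preprint_vs_article"
    first_vs_latest_preprint = "first_vs_latest_preprint"


class ChangeRecord(BaseModel):
    study_id: str
    pair_type: PairType
    result_changed: bool = False
    important_change: bool = False
    max_relative_change: Optional[float] = None
    p_crossed: bool = False
    sample_size_changed: bool = False
    conclusion_changed: bool = False
    conclusion_transition: Optional[tuple[ConclusionAssessment, ConclusionAssessment]] = None
    methods_fields_changed: list[str] = Field(default_factory=list)
    outcomes_added: int = 0
    outcomes_removed: int = 0


def relative_change(initial: float, new: float) -> float:
    """|new - initial| / |initial|; undefined (raises) when initial is zero."""
    if initial == 0:
        raise UndefinedChangeError("relative change undefined for initial value 0")
    return abs(new - initial) / abs(initial)


def p_crossing(p_old: Optional[float], p_new: Optional[float], alpha: float = 0.05) -> bool:
    """True iff both p values are present and exactly one is < alpha.

    The boundary p == alpha counts as not significant (strict <).
    """
    if p_old is None or p_new is None:
        return False
    return (p_old < alpha) != (p_new < alpha)


def _result_key(r: ReportedResult) -> tuple[str, str]:
    label = re.sub(r"\s+", " ", r.outcome_label.strip().lower())
    return label, r.metric.value


def pair_results(
    a: Sequence[ReportedResult], b: Sequence[ReportedResult]
) -> tuple[list[tuple[ReportedResult, ReportedResult]], int, int]:
    """Match results across two versions on (normalized outcome label, metric).

    Returns (matched pairs, n added in b, n removed from a). Duplicate keys
    within one list raise :class:`AmbiguousResultsError`.
    """
    index_a: dict[tuple[str, str], ReportedResult] = {}
    for r in a:
        key = _result_key(r)
        if key in index_a:
            raise AmbiguousResultsError(f"duplicate result key {key} in first list")
        index_a[key] = r
    seen_b: set[tuple[str, str]] = set()
    matched: list[tuple[ReportedResult, ReportedResult]] = []
    added = 0
    for r in b:
        key = _result_key(r)
        if key in seen_b:
            raise AmbiguousResultsError(f"duplicate result key {key} in second list")
        seen_b.add(key)
        if key in index_a:
            matched.append((index_a[key], r))
        else:
            added += 1
    removed = len(index_a) - len(matched)
    return matched, added, removed


def _differs(x: Optional[float], y: Optional[float], tol: float) -> bool:
    if x is None and y is None:
        return False
    if x is None or y is None:
        return True
    return abs(x - y) > tol


def classify_result_change(
    a: Sequence[ReportedResult],
    b: Sequence[ReportedResult],
    n_a: int,
    n_b: int,
    criteria: ChangeCriteria | None = None,
) -> dict:
    """Apply the result-change criteria to one version pair.

    ``result_changed`` fires on any numeric change (beyond tolerance) in a
    matched estimate or p value; ``important_change`` when the largest
    relative estimate change reaches the threshold and/or a p value crosses
    alpha. Estimates whose initial value is zero can set ``result_changed``
    but never contribute a magnitude-based importance call.
    """
    criteria = criteria or ChangeCriteria()
    matched, added, removed = pair_results(a, b)
    result_changed = False
    p_crossed = False
    max_rel: Optional[float] = None
    for old, new in matched:
        if _differs(old.estimate, new.estimate, criteria.numeric_tolerance):
            result_changed = True
        if _differs(old.p_value, new.p_value, criteria.numeric_tolerance):
            result_changed = True
            # a crossing only counts when the p value genuinely changed
            if p_crossing(old.p_value, new.p_value, criteria.alpha):
                p_crossed = True
        if old.estimate is not None and new.estimate is not None and old.estimate != 0:
            rel = relative_change(old.estimate, new.estimate)
            max_rel = rel if max_rel is None else max(max_rel, rel)
    # ">= threshold" with a relative epsilon so a change of exactly 10%
    # (e.g. 2.0 -> 1.8, which floats render as 0.0999...98) is inclusive
    reaches_threshold = max_rel is not None and (
        max_rel >= criteria.relative_change_threshold
        or math.isclose(max_rel, criteria.relative_change_threshold, rel_tol=1e-9)
    )
    important = p_crossed or reaches_threshold
    return {
        "result_changed": result_changed,
        "important_change": important and result_changed,
        "max_relative_change": max_rel,
        "p_crossed": p_crossed,
        "sample_size_changed": n_a != n_b,
        "outcomes_added": added,
        "outcomes_removed": removed,
    }


# Cue lexicon: a reproducible surrogate for the human coding of abstract
# conclusions. Direction by majority of matched direction cues; uncertainty
# is "reported" when any hedge cue matches. Cues are matched as whole words
# / phrases, case-insensitively.
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "positive": (
        "effective",
        "efficacy",
        "efficacious",
        "benefit",
        "beneficial",
        "improved",
        "improvement",
        "reduced mortality",
        "reduced the risk",
        "reduction in harms",
        "protective",
        "shortened",
        "faster recovery",
    ),
    "negative": (
        "harm",
        "harmful",
        "deterioration",
        "worsened",
        "worse outcomes",
        "increased mortality",
        "increased the risk",
        "adverse effect",
        "unsafe",
        "detrimental",
    ),
    "hedge": (
        "might",
        "may",
        "could",
        "appears to",
        "preliminary",
        "further studies",
        "further research",
        "additional studies",
        "should be confirmed",
        "needs confirmation",
        "remains uncertain",
        "caution",
    ),
}


def _count_cues(text: str, cues: tuple[str, ...]) -> int:
    total = 0
    for cue in cues:
        total += len(re.findall(rf"\b{re.escape(cue)}\b", text))
    return total


def classify_conclusion(
    text: str, lexicon: dict[str, tuple[str, ...]] | None = None
) -> ConclusionAssessment:
    """Code a conclusion's direction and uncertainty from cue phrases.

    Direction follows the majority of matched positive vs negative cues
    (ties and no-match -> neutral). Uncertainty is ``reported`` iff any
    hedge cue (mild phrasing, calls for confirmatory studies) matches.
    """
    if not text or not text.strip():
        raise ValueError("conclusion text must be non-empty")
    lexicon = lexicon or DEFAULT_LEXICON
    lowered = text.lower()
    pos = _count_cues(lowered, lexicon["positive"])
    neg = _count_cues(lowered, lexicon["negative"])
    if pos > neg:
        direction = Direction.positive
    elif neg > pos:
        direction = Direction.negative
    else:
        direction = Direction.neutral
    hedged = _count_cues(lowered, lexicon["hedge"]) > 0
    return ConclusionAssessment(
        direction=direction,
        uncertainty=Uncertainty.reported if hedged else Uncertainty.not_reported,
    )


def conclusion_changed(a: ConclusionAssessment, b: ConclusionAssessment) -> bool:
    """Any change in direction or in whether uncertainty is reported."""
    return a.direction != b.direction or a.uncertainty != b.uncertainty


def _normalize_field(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    return re.sub(r"\s+", " ", value.strip())


def detect_methods_changes(a: Optional[MethodsProfile], b: Optional[MethodsProfile]) -> list[str]:
    """Field names whose normalized values differ between two profiles.

    Null vs non-null counts as a change (information added or removed).
    Missing profiles compare as empty. Output order is the fixed field
    order of :class:`MethodsProfile`.
    """
    a = a or MethodsProfile()
    b = b or MethodsProfile()
    changed = []
    for name in MethodsProfile.FIELD_ORDER:
        if _normalize_field(getattr(a, name)) != _normalize_field(getattr(b, name)):
            changed.append(name)
    return changed


def _assessment(version: SourceVersion, lexicon=None) -> Optional[ConclusionAssessment]:
    # Pre-coded assessments (human coding) win over the lexicon surrogate.
    if version.conclusion is not None:
        return version.conclusion
    if version.conclusion_text:
        return classify_conclusion(version.conclusion_text, lexicon)
    return None


def _compare_versions(
    study_id: str,
    pair_type: PairType,
    old: SourceVersion,
    new: SourceVersion,
    criteria: ChangeCriteria,
    lexicon=None,
) -> ChangeRecord:
    fields = classify_result_change(old.results, new.results, old.sample_size, new.sample_size, criteria)
    rec = ChangeRecord(study_id=study_id, pair_type=pair_type, **fields)
    ca, cb = _assessment(old, lexicon), _assessment(new, lexicon)
    if ca is not None and cb is not None:
        rec.conclusion_changed = conclusion_changed(ca, cb)
        rec.conclusion_transition = (ca, cb)
    rec.methods_fields_changed = (
        detect_methods_changes(old.methods_profile, new.methods_profile)
        if (old.methods_profile is not None or new.methods_profile is not None)
        else []
    )
    return rec


def compare_sources(
    study: Study,
    criteria: ChangeCriteria | None = None,
    lexicon: dict[str, tuple[str, ...]] | None = None,
) -> list[ChangeRecord]:
    """Emit one ChangeRecord per applicable evidence-source pair.

    Pairs: first vs latest preprint version (if > 1 versions), first
    preprint version vs article, and latest preprint version vs article
    (the latter only when > 1 versions exist). A study with a single
    source and single version is not comparable and returns [].
    """
    criteria = criteria or ChangeCriteria()
    records: list[ChangeRecord] = []
    pp = study.preprint
    art = study.article
    if pp is not None and len(pp.versions) > 1:
        records.append(
            _compare_versions(
                study.study_id,
                PairType.first_vs_latest_preprint,
                pp.versions[0],
                pp.versions[-1],
                criteria,
                lexicon,
            )
        )
    if pp is not None and art is not None:
        records.append(
            _compare_versions(
                study.study_id,
                PairType.first_preprint_vs_article,
                pp.versions[0],
                art.version,
                criteria,
                lexicon,
            )
        )
        if len(pp.versions) > 1:
            records.append(
                _compare_versions(
                    study.study_id,
                    PairType.latest_preprint_vs_article,
                    pp.versions[-1],
                    art.version,
                    criteria,
                    lexicon,
                )
            )
    return records


# ---------------------------------------------------------------------------
# tabular export: one flattened row per ChangeRecord


def changes_to_frame(records: Sequence[ChangeRecord]):
    """Flatten change records into a DataFrame (one row per source pair)."""
    import pandas as pd

    rows = []
    for r in records:
        first = r.conclusion_transition[0] if r.conclusion_transition else None
        last = r.conclusion_transition[1] if r.conclusion_transition else None
        rows.append(
            {
                "study_id": r.study_id,
                "pair_type": r.pair_type.value,
                "result_changed": r.result_changed,
                "important_change": r.important_change,
                "max_relative_change": r.max_relative_change,
                "p_crossed": r.p_crossed,
                "sample_size_changed": r.sample_size_changed,
                "conclusion_changed": r.conclusion_changed,
                "conclusion_first_direction": first.direction.value if first else None,
                "conclusion_first_uncertainty": first.uncertainty.value if first else None,
                "conclusion_last_direction": last.direction.value if last else None,
                "conclusion_last_uncertainty": last.uncertainty.value if last else None,
                "methods_fields_changed": ";".join(r.methods_fields_changed),
                "outcomes_added": r.outcomes_added,
                "outcomes_removed": r.outcomes_removed,
            }
        )
    columns = [
        "study_id", "pair_type", "result_changed", "important_change",
        "max_relative_change", "p_crossed", "sample_size_changed",
        "conclusion_changed", "conclusion_first_direction",
        "conclusion_first_uncertainty", "conclusion_last_direction",
        "conclusion_last_uncertainty", "methods_fields_changed",
        "outcomes_added", "outcomes_removed",
    ]
    return pd.DataFrame(rows, columns=columns)


def frame_to_changes(frame) -> list[ChangeRecord]:
    """Inverse of :func:`changes_to_frame`."""
    import pandas as pd

    records = []
    for row in frame.to_dict(orient="records"):
        transition = None
        if isinstance(row.get("conclusion_first_direction"), str) and row["conclusion_first_direction"]:
            transition = (
                ConclusionAssessment(
                    direction=row["conclusion_first_direction"],
                    uncertainty=row["conclusion_first_uncertainty"],
                ),
                ConclusionAssessment(
                    direction=row["conclusion_last_direction"],
                    uncertainty=row["conclusion_last_uncertainty"],
                ),
            )
        methods_raw = row.get("methods_fields_changed")
        methods = (
            [f for f in str(methods_raw).split(";") if f]
            if isinstance(methods_raw, str) and methods_raw
            else []
        )
        max_rel = row.get("max_relative_change")
        records.append(
            ChangeRecord(
                study_id=row["study_id"],
                pair_type=PairType(row["pair_type"]),
                result_changed=bool(row["result_changed"]),
                important_change=bool(row["important_change"]),
                max_relative_change=None if pd.isna(max_rel) else float(max_rel),
                p_crossed=bool(row["p_crossed"]),
                sample_size_changed=bool(row["sample_size_changed"]),
                conclusion_changed=bool(row["conclusion_changed"]),
                conclusion_transition=transition,
                methods_fields_changed=methods,
                outcomes_added=int(row["outcomes_added"]),
                outcomes_removed=int(row["outcomes_removed"]),
            )
        )
    return records
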