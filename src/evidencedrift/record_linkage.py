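"""Preprint–journal-article record linkage from bibliographic metadata.

Decides which article records report the same study as a given preprint,
using the metadata signals available from Crossref-style work records:
shared author ORCIDs, normalized author names, the order of coauthors in
the byline, title words, trial-registration IDs, and the plausibility of
the preprint-to-publication timeline. A shared registration ID links a
pair unconditionally; otherwise a weighted feature score is thresholded
and pairs are assigned one-to-one greedily by descending score.
"""

from __future__ import annotations

import datetime as dt
import re
import unicodedata
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .corpus_model import Author, BibliographicRecord, SourceType

__all__ = [
    "LinkFeatures",
    "Link",
    "LinkageConfig",
    "DEFAULT_WEIGHTS",
    "STOP_TOKENS",
    "normalize_author",
    "title_tokens",
    "title_similarity",
    "link_features",
    "link_score",
    "match_corpus",
]


class LinkFeatures(BaseModel):
    orcid_overlap: float = Field(ge=0.0, le=1.0)
    # False when either byline carries no ORCIDs at all: the comparison is
    # then missing, not a disagreement, and is dropped from the score
    orcid_observed: bool = True
    first_author_match: bool
    author_overlap: float = Field(ge=0.0, le=1.0)
    byline_order_similarity: float = Field(ge=0.0, le=1.0)
    title_similarity: float = Field(ge=0.0, le=1.0)
    registration_match: bool
    timeline_ok: bool


class Link(BaseModel):
    preprint_id: str
    article_id: str
    features: LinkFeatures
    score: float = Field(ge=0.0, le=1.0)
    decision: str  # "match" | "no_match"


# Weights over the five scored features; registration_match short-circuits
# and timeline_ok acts as a multiplicative penalty, so neither is weighted.
DEFAULT_WEIGHTS: dict[str, float] = {
    "orcid_overlap": 0.25,
    "first_author_match": 0.15,
    "author_overlap": 0.25,
    "byline_order_similarity": 0.10,
    "title_similarity": 0.25,
}

# Function words plus tokens shared corpus-wide in this literature; they
# carry no discriminating signal between candidate pairs.
STOP_TOKENS: frozenset[str] = frozenset(
    """a an the of in on for and or to with without among between from by at
    as is are was were be been during after before versus vs study trial
    covid 19 sars cov 2""".split()
)


class LinkageConfig(BaseModel):
    """Scoring weights, decision threshold, and timeline handling."""

    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    threshold: float = Field(default=0.70, ge=0.0, le=1.0)
    grace_days: int = Field(default=30, ge=0)
    timeline_penalty: float = Field(default=0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _valid_weights(self) -> "LinkageConfig":
        if set(self.weights) != set(DEFAULT_WEIGHTS):
            raise ValueError(f"weights must cover exactly {sorted(DEFAULT_WEIGHTS)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        return self


# letters with no NFKD decomposition (stroked and ligature forms)
_TRANSLITERATE = str.maketrans(
    {"ø": "o", "Ø": "O", "đ": "d", "Đ": "D", "ł": "l", "Ł": "L", "ð": "d", "Ð": "D"}
) | {ord("ß"): "ss", ord("æ"): "ae", ord("Æ"): "Ae", ord("œ"): "oe", ord("Œ"): "Oe"}


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text.translate(_TRANSLITERATE))
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize_author(author: Author) -> str:
    """Normalized author key: lowercased, diacritic-free ``family|initial``.

    An empty given name yields the bare family name (no separator), so
    "T." and "Theodora" normalize identically while records lacking given
    names still compare on the family name.
    """
    family = _strip_diacritics(author.family).lower().strip()
    given = _strip_diacritics(author.given or "").strip()
    initial = next((c for c in given if c.isalpha()), "")
    return f"{family}|{initial.lower()}" if initial else family


def title_tokens(title: str) -> frozenset[str]:
    tokens = re.split(r"[^\w]+", _strip_diacritics(title).lower())
    return frozenset(t for t in tokens if t and t not in STOP_TOKENS)


def title_similarity(a: str, b: str) -> float:
    """Jaccard index of stop-filtered title token sets; empty vs empty is 1."""
    ta, tb = title_tokens(a), title_tokens(b)
    if not ta and not tb:
        return 1.0
    union = ta | tb
    return len(ta & tb) / len(union)


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    # O(len(a)*len(b)) dynamic programming; bylines are short.
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b):
            cur.append(prev[j] + 1 if x == y else max(prev[j + 1], cur[j]))
        prev = cur
    return prev[-1]


def link_features(p: BibliographicRecord, a: BibliographicRecord, grace_days: int = 30) -> LinkFeatures:
    """Compute the linkage feature vector for a (preprint, article) pair."""
    if p.source_type is not SourceType.preprint or a.source_type is not SourceType.journal_article:
        raise ValueError("link_features expects (preprint, journal_article) in that order")
    orcids_p = {au.orcid for au in p.authors if au.orcid}
    orcids_a = {au.orcid for au in a.authors if au.orcid}
    denom = min(len(orcids_p), len(orcids_a))
    orcid_overlap = len(orcids_p & orcids_a) / denom if denom else 0.0

    keys_p = [normalize_author(au) for au in p.authors]
    keys_a = [normalize_author(au) for au in a.authors]
    union = set(keys_p) | set(keys_a)
    author_overlap = len(set(keys_p) & set(keys_a)) / len(union) if union else 0.0
    shorter = min(len(keys_p), len(keys_a))
    byline = _lcs_length(keys_p, keys_a) / shorter if shorter else 0.0

    timeline_ok = a.online_date >= p.online_date - dt.timedelta(days=grace_days)
    return LinkFeatures(
        orcid_overlap=orcid_overlap,
        orcid_observed=denom > 0,
        first_author_match=keys_p[0] == keys_a[0],
        author_overlap=author_overlap,
        byline_order_similarity=min(byline, 1.0),
        title_similarity=title_similarity(p.title, a.title),
        registration_match=(
            p.registration_id is not None and p.registration_id == a.registration_id
        ),
        timeline_ok=timeline_ok,
    )


def link_score(f: LinkFeatures, config: LinkageConfig | None = None) -> float:
    """Weighted feature sum in [0, 1]; a bad timeline halves the score.

    When the ORCID comparison is unobservable (either record has no
    ORCIDs) its weight is redistributed over the remaining features, so
    absent identifiers are treated as missing data rather than evidence
    against a match.
    """
    config = config or LinkageConfig()
    w = config.weights
    score = (
        w["first_author_match"] * float(f.first_author_match)
        + w["author_overlap"] * f.author_overlap
        + w["byline_order_similarity"] * f.byline_order_similarity
        + w["title_similarity"] * f.title_similarity
    )
    if f.orcid_observed:
        score += w["orcid_overlap"] * f.orcid_overlap
    else:
        denom = 1.0 - w["orcid_overlap"]
        score = score / denom if denom > 0 else 0.0
    if not f.timeline_ok:
        score *= config.timeline_penalty
    return min(score, 1.0)


def _candidate_pairs(
    preprints: Sequence[BibliographicRecord], articles: Sequence[BibliographicRecord]
) -> list[tuple[int, int]]:
    # Prune to pairs sharing >= 1 normalized author key or a registration ID.
    by_key: dict[str, list[int]] = {}
    by_reg: dict[str, list[int]] = {}
    for j, art in enumerate(articles):
        for au in art.authors:
            by_key.setdefault(normalize_author(au), []).append(j)
        if art.registration_id:
            by_reg.setdefault(art.registration_id, []).append(j)
    pairs: set[tuple[int, int]] = set()
    for i, pp in enumerate(preprints):
        for au in pp.authors:
            for j in by_key.get(normalize_author(au), ()):
                pairs.add((i, j))
        if pp.registration_id:
            for j in by_reg.get(pp.registration_id, ()):
                pairs.add((i, j))
    return sorted(pairs)


def match_corpus(
    preprints: Sequence[BibliographicRecord],
    articles: Sequence[BibliographicRecord],
    config: LinkageConfig | None = None,
) -> list[Link]:
    """One-to-one preprint–article matching.

    Registration-ID matches are accepted unconditionally; remaining
    candidates are scored and assigned greedily by descending score above
    the threshold. Ties break on smaller |date gap|, then lexicographic
    (preprint_id, article_id), so output is independent of input order.
    """
    config = config or LinkageConfig()
    scored: list[tuple[float, int, str, str, int, int, LinkFeatures]] = []
    for i, j in _candidate_pairs(preprints, articles):
        p, a = preprints[i], articles[j]
        feats = link_features(p, a, grace_days=config.grace_days)
        score = link_score(feats, config)
        if feats.registration_match or score >= config.threshold:
            gap = abs((a.online_date - p.online_date).days)
            scored.append((score, gap, p.record_id, a.record_id, i, j, feats))
    # registration matches first, then score desc, gap asc, ids lexicographic
    scored.sort(key=lambda t: (not t[6].registration_match, -t[0], t[1], t[2], t[3]))
    used_p: set[int] = set()
    used_a: set[int] = set()
    links: list[Link] = []
    for score, _gap, pid, aid, i, j, feats in scored:
        if i in used_p or j in used_a:
            continue
        used_p.add(i)
        used_a.add(j)
        links.append(
            Link(preprint_id=pid, article_id=aid, features=feats, score=score, decision="match")
        )
    return links
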