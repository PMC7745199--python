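# Methods

## Problem and scope

A single intervention study can be reported in several evidence sources: a
preprint with one or more dated versions, and possibly a journal article.
`evidencedrift` treats the *study* as the unit of analysis and asks three
questions: which bibliographic records belong to the same study (record
linkage); whether the reported evidence changed between source pairs
(change detection); and how the corpus looks in aggregate (descriptive
synthesis). The package consumes structured inputs — work records and
per-version structured study reports — and does no PDF parsing, API
harvesting or review screening.

## Record linkage

For a candidate (preprint, article) pair the feature vector is:

- `orcid_overlap` — shared ORCIDs over the smaller ORCID set;
- `first_author_match` — equality of the normalized first-author keys;
- `author_overlap` — Jaccard similarity of normalized author keys
  (lowercased, diacritic-stripped `family|initial`);
- `byline_order_similarity` — longest common subsequence of the two
  ordered key lists over the shorter byline length;
- `title_similarity` — Jaccard similarity of lowercased title token sets
  after removing ~30 stop tokens (function words plus tokens shared
  corpus-wide in this literature, e.g. *covid*, *sars*);
- `registration_match` — equal non-null trial-registration IDs;
- `timeline_ok` — the article is not earlier than 30 days before the
  preprint (real pairs occasionally publish the article first).

The decision score is a weighted sum (defaults 0.25 / 0.15 / 0.25 / 0.10 /
0.25 over the five scored features, threshold 0.70). A registration match
accepts the pair unconditionally; a bad timeline multiplies the score by
0.5 rather than excluding the pair. Candidate pairs are pruned to those
sharing at least one normalized author key or a registration ID, and the
final assignment is one-to-one greedy by descending score, tie-broken on
smaller |date gap| then lexicographic IDs, so output is independent of
input order.

**Missing ORCIDs.** When either byline carries no ORCIDs the comparison is
uninformative; scoring it as zero would penalize exactly the records most
common in practice. The score therefore drops the ORCID term and
renormalizes the remaining weights — the standard missing-comparison
treatment in probabilistic record linkage. Without this, bylines lacking
ORCIDs that also lose one author between versions fall just below the 0.70
threshold.

Weights and threshold are package defaults calibrated on the synthetic
validation harness (there is no published reference weight set); all are
exposed in `LinkageConfig`.

**Diacritic handling.** Normalization uses NFKD decomposition plus an
explicit transliteration table for letters with no decomposition (ø, đ, ł,
ß, æ, œ), so "Sørensen" and "Sorensen" produce the same key.

## Change detection

Results are matched across versions on (normalized outcome label, metric);
duplicate keys are an error surfaced to the caller. For matched pairs:

- `result_changed` — any estimate or p value differs by more than the
  numeric tolerance (default 1e−9; transcription-rounding guard);
- `p_crossed` — a genuinely changed p value moves across α = 0.05;
- `max_relative_change` — max over matched pairs of |Δθ|/|θ₀| with θ₀ ≠ 0;
- `important_change` — `max_relative_change ≥ 0.10` and/or `p_crossed`.

Conventions, fixed where the rule leaves a measure-zero or unstated case:

- p = α exactly counts as **not** significant (strict `<`), so
  0.05 → 0.04 is a crossing;
- the ≥ threshold comparison uses a 1e−9 relative epsilon so a change of
  exactly 10% (e.g. 2.0 → 1.8, binary-float 0.0999…98) is inclusive;
- event rates are compared on the ratio scale (percent values as numbers,
  24 → 35 is a 45.8% change), not percentage points; the rule speaks of
  change "of the initial value";
- an initial estimate of zero can trigger `result_changed` but never a
  magnitude-based importance call (relative change undefined);
- outcomes present in only one version are counted as added/removed and do
  not set `result_changed`.

Abstract conclusions are coded as direction × uncertainty. Pre-coded
(human) assessments always win; otherwise a cue lexicon codes free text:
direction by majority of matched positive vs negative cue phrases (tie or
none → neutral), uncertainty = reported iff any hedge cue matches
("might", "may", "further studies", "should be confirmed", …). The lexicon
is a reproducible surrogate for human coding, adequate for template-like
sentences, not for arbitrary scientific prose.

Methods profiles (blinding, missing data, randomization/allocation,
participant inclusion, confounder adjustment) compare field-wise after
whitespace normalization; null vs non-null counts as a change (information
added or removed affects a risk-of-bias appraisal).

Per study, up to three pair records are emitted (first vs latest preprint
version; first preprint version vs article; latest preprint version vs
article when > 1 versions exist); study-level flags are the OR over pairs.

## Descriptive synthesis

- Percentages are integers rounded half away from zero, with the
  denominators used in the emulated tables: preprint share over all
  studies, published and multi-version shares over preprint-reported
  studies, change shares over multi-source studies, per-pair-type shares
  over studies having that pair. A `consistency_check` re-derives every
  percentage from its own counts after each run.
- Quantiles use linear interpolation between order statistics (type 7) —
  no convention is stated by the emulated tables, so one is fixed here.
- Time-to-publication uses the Kaplan–Meier product-limit estimator
  (lifelines), event = journal publication, censoring of unpublished
  preprints at the configurable cutoff (default 2020-09-02). With no
  censoring it equals the empirical survivor function (property-tested).
- Usage metrics divide by days since first online publication, clamped to
  a minimum of 1 day to make same-day retrieval well defined. Citation
  share is preprint/(preprint+article), null when both are zero.
- The conclusion-transition matrix is 6×6 over direction × uncertainty,
  first preprint version → latest available source (article if present,
  else latest preprint version); a 3×3 direction-only aggregation is
  derivable from it.

## Synthetic corpus: what it states and what it does not

The generator's defaults are the emulated corpus conditions: 556 studies,
P(preprint) = 0.61, P(article | preprint) = 0.195, P(>1 version |
preprint) = 0.27, and change rates 0.45/0.30/0.21/0.24 (any / results /
important / conclusion) among multi-source studies. Publication delay is
log-normal with median 76 days and σ = 0.49, chosen so the quartiles are
≈ 55 and 106 days, the two printed anchors; delays are right-skewed in
practice, which the log-normal captures with two parameters.

Values the emulated corpus does not state were fixed once at realistic
levels: 30% RCTs; registration IDs on 80% of RCTs; 3–12 authors per
byline with 50% ORCID coverage; 1–3 reported outcomes per study; extra
preprint versions via a truncated geometric (median version count 1, IQR
1–2, range capped at 6); default metadata-perturbation level 0.3.

**Coupled change planting.** The four printed change rates are mutually
inconsistent with independent planting: independence of result (0.30) and
conclusion (0.24) changes gives an any-change rate of 46.8%, not 45%. The
generator therefore couples them so all four marginals hold exactly in
expectation: P(conclusion | result) = (p_r + p_c − p_any)/p_r ≈ 0.30,
P(conclusion | no result) ≈ 0.214. `independent_changes=True` restores
independent planting. Sample-size changes are planted only alongside
result changes, at rate 1/3 (matching the reported 18 of 54 changed
pairs). Planted conclusion transitions start from
positive/no-uncertainty in ~45% of cases, reproducing the dominant
observed flow (positive without → positive with uncertainty reporting).

Planted changes are constructed to satisfy the classifier's rules exactly
(non-important shifts of 2–8%, important shifts of 10–60% or a p value
moved across 0.05), and every later source carries the same final content,
so the OR of pair verdicts equals the planted study-level flags for every
seed — this is what the generator/detector consistency tests establish.

Randomness is a single corpus seed with per-record substreams derived by
SHA-256 hashing of (seed, record id), so realizations are independent of
insertion order and stable under corpus growth.

What a green test does **not** establish: the generator produces
template-based titles and conclusion sentences from small lexicons; it
does not emulate real scientific prose, OCR/transcription noise beyond the
listed perturbations, many-to-many linkage ambiguity (each study has at
most one article), retractions/corrections, or correlations between
change types beyond the planted coupling. Corpus-level medians that depend
on the unreleased real dataset (observed 76-day delay, 29% citation share)
are covered only as synthetic-recovery properties.

## Limitations

- The linkage weights are calibrated on synthetic perturbations; real
  metadata divergence (journal-imposed title rewrites, author-list
  expansion after peer review) is likely harsher.
- The conclusion lexicon handles hedging and valence cues, not negation
  scope ("did not prove efficacy" would be miscoded positive); pre-coded
  assessments should be supplied where available.
- Greedy one-to-one assignment is not globally optimal; with near-tied
  candidates a Hungarian assignment could differ. At realistic score
  separations this has not been observed on the validation harness.
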