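# evidencedrift

When the same study is reported in several places — a preprint with multiple
dated versions, and later a peer-reviewed journal article — the reported
evidence can differ between those sources. For fast-moving literatures such
as COVID-19 intervention research, systematic reviewers who cite whichever
source they found first risk building syntheses on outdated numbers.

`evidencedrift` is a meta-research pipeline for quantifying that
instability. It provides:

- **Record linkage** — decide which journal articles report the same study
  as a given preprint, from bibliographic metadata alone (author ORCIDs,
  normalized author names, byline order, title words, trial-registration
  IDs, publication timelines).
- **Change detection** — compare evidence-source pairs (first preprint
  version vs article, latest preprint vs article, first vs latest preprint
  version) and classify changes in reported results and abstract
  conclusions. A result change is *important* when any effect estimate
  moves by ≥ 10% of its initial value, `|Δθ|/|θ₀| ≥ 0.10`, and/or a p value
  crosses the α = 0.05 threshold. Conclusions are coded as direction
  (positive / neutral / negative toward the intervention) × uncertainty
  (hedged or not), and any change on either axis counts.
- **Descriptive synthesis** — corpus summary tables with the field's
  standard denominators, Kaplan–Meier time-to-publication curves (event =
  journal publication, censoring at a cutoff date), 6×6 conclusion-state
  transition matrices, and usage metrics (citations, attention score,
  post-publication comments) normalized per day of online exposure.
- **A synthetic-corpus generator** — corpora with known ground-truth links
  and planted changes, so every stage is testable end to end without any
  data download. Defaults emulate a 556-study intervention-research corpus
  (61% preprint-reported; 19.5% of preprints published, log-normal delay
  with median 76 days; 27% multi-version; change rates 45/30/21/24% among
  multi-source studies).

## Worked example

```python
import datetime as dt
import evidencedrift as ed
from evidencedrift.descriptive_synthesis import (
    km_unpublished, publication_delays, summarize_corpus,
)

studies, truth = ed.generate_corpus(ed.GeneratorParams(seed=0))
records = [r for s in studies for r in ed.compare_sources(s)]
summary = summarize_corpus(studies, None, records)

print(summary.n_preprint_reported, summary.pct_preprint_reported)
print(summary.changes.counts["any"], summary.changes.percentages["any"])
print(summary.median_delay_days, summary.delay_iqr)

curve = km_unpublished(publication_delays(studies, dt.date(2020, 9, 2)))
print(round(curve.probability_at(90), 3))
```

Output (seed 0):

```
321 58
63 48
74.0 (45.5, 106.0)
0.855
```

Of the 556 simulated studies, 321 (58%) were first reported as preprints;
among the 132 studies with more than one evidence source or version, 63
(48%) changed in at least one evidence component. The median
preprint-to-article delay is 74 days (IQR 45.5–106), and a preprint has an
estimated 85.5% probability of still being unpublished as a journal
article 90 days after it first appeared online. A single seed scatters
around the generator parameters (61%, 45%, 76 days); the realized values
converge to them as the corpus grows.

## Command-line interface

Each stage is also a subcommand, sharing a flat `key = value` config file
(flags win):

```sh
evidencedrift simulate  --seed 1 --out corpus.jsonl --truth truth.json
evidencedrift link      --corpus corpus.jsonl --out links.csv
evidencedrift detect    --corpus corpus.jsonl --out changes.csv
evidencedrift summarize --corpus corpus.jsonl --changes changes.csv \
                        --cutoff 2020-09-02 --out report/
evidencedrift run-all   --seed 1 --out run/        # all of the above
```

Corpora are JSON Lines (one study per line); bibliographic input is
CSL-JSON; tabular outputs are CSV with a `#` provenance header recording
the tool version, seed and config hash. Reruns with the same seed and
config are byte-identical.

## Acceptance script

`scripts/acceptance.py` rebuilds the linkage-validation experiment from
scratch: it generates 740 true preprint–article pairs plus 300 decoy
articles at the default metadata-perturbation level, runs the matcher at
default weights and threshold, and writes the percentage of true pairs
recovered as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, conventions and limitations.
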