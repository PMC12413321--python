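# transportnlp

Rule-based detection of **transportation insecurity** mentions in free-text
ophthalmology clinic notes, with an evaluation harness, cohort analytics,
and a synthetic-corpus generator.

Transportation insecurity — the lack of reliable means to get to medical
appointments — is a common barrier to eye care and is rarely captured in
structured EHR fields. It does surface in the free text of clinic notes
("had to cx that appt., no ride"). This package implements a validated
rule-based extraction approach for flagging such mentions at scale, aimed at
clinical-informatics teams who want to identify patients for referral to
transportation resources, and at researchers studying health-related social
needs in EHR text.

## The algorithm

A note is flagged when any sentence contains a **transport term** and a
**need cue** within a bounded character gap, in either order, both anchored
on word boundaries:

```
\b(%reTransportation)\b .{0,g}? \b(%reNeeds)\b      or the mirror image
```

* `%reTransportation` = `transportation | ride | driv(e|ing)`
* `%reNeeds` = 48 cue expressions (`due to`, `(un)?able`, `issue(s)`,
  `arrang(es|ed|e|ing)?`, `no`, …)
* `g` = maximum gap, default 50 characters; matching never crosses a
  sentence boundary.

Domain-specific refinements are part of the method:

* **"transit" is not a transport term** — it collides with the transit
  phase of fluorescein angiography.
* **Driving complaints in visual-function contexts are excluded** — in a
  cataract clinic, "difficulty driving at night from glare" describes
  eyesight, not access to care. A default-on exclusion rule suppresses
  driving matches when the sentence carries a visual-function cue.
* **Embedded questionnaire blocks are stripped** before matching, so
  templated lines like `Transportation needs: on file` cannot create
  artifactual hits.
* **No negation or hypothetical-language handling** — "denies
  transportation issues" matches. This blind spot is a documented property
  of the validated rule set; the evaluation module measures it (error
  taxonomy: contextual vs linguistic failures) rather than patching it.

Downstream analytics aggregate note-level flags to patients and compute
prevalence, matched-phrase frequency tables, unadjusted odds ratios
(OR = ad/bc with Woolf 95% CIs, Haldane–Anscombe correction for zero
cells), adjusted odds ratios from binary logistic regression (IRLS via
statsmodels, Wald CIs), yearly mention rates, and inter-event intervals.

## Worked example

```python
from datetime import date
from transportnlp import (RawNote, annotate_note, clean_note,
                          compile_patterns, default_lexicon)

lexicon = default_lexicon()
patterns = compile_patterns(lexicon, max_gap=50)
texts = [
    "She is unable to stay for an injection due to ride issues today and wishes to observe.",
    "Huge change os, noticed 3 months ago, had appt in Aug. 2016, had to cx that appt., no ride.",
    "Fluorescein angiography transit phase unremarkable.",
    "Reports difficulty driving at night from glare.",
]
for i, text in enumerate(texts):
    note = clean_note(RawNote(f"p{i}", f"n{i}", date(2022, 3, 1), "office visit", text))
    result = annotate_note(note, patterns, list(lexicon.exclusion_rules))
    phrase = result.mentions[0].matched_phrase if result.mentions else "-"
    print(f"{result.note_id}  {'FLAGGED' if result.flagged else 'clean':7s}  {phrase}")
```

prints

```
n0  FLAGGED  due to ride issues
n1  FLAGGED  no ride
n2  clean    -
n3  clean    -
```

The first two notes are flagged with the exact expression that triggered
the rule; the angiography note is clean because "transit" is not in the
dictionary, and the glare note is clean because the visual-function
exclusion suppressed the `difficulty … driving` match.

The same pipeline runs from the shell on a fully synthetic corpus (no
real data required anywhere):

```bash
transportnlp simulate --n-patients 200 --need-prevalence 0.05 --seed 7 --out-dir sim
transportnlp detect   --notes sim/notes.jsonl --out-dir det
transportnlp evaluate --results det/note_results.csv --gold sim/gold.csv --out metrics.json
transportnlp analyze  --results det/note_results.csv --notes sim/notes.jsonl \
                      --demographics sim/demographics.csv --out-dir analytics
```

```
wrote 2930 notes for 200 patients to sim
2930 notes -> 22 mentions, 22 flagged notes, 17 flagged patients
precision 0.864, recall 0.950, F1 0.905, accuracy 99.9%
17/200 patients flagged (8.5%)
```

The synthetic corpus plants both canonical positive sentences and the
documented failure modes (agency names, transplantation typos, negated
phrasing, invisible synonyms such as "mobility issues"), so precision and
recall land below 1 by design: the generator's truth log attributes every
error to its planted category.

## Layout

| Module | Role |
| --- | --- |
| `transportnlp.lexicon` | term dictionaries, exclusion rules, pattern compilation |
| `transportnlp.preprocess` | deduplication, template stripping, sentence segmentation |
| `transportnlp.matcher` | sentence-level co-occurrence matching, note annotation |
| `transportnlp.evaluate` | confusion counts, precision/recall/F1, error taxonomy |
| `transportnlp.analytics` | patient aggregation, odds ratios, longitudinal tables |
| `transportnlp.synthcorpus` | seeded synthetic corpus with gold labels and truth log |
| `transportnlp.io` / `transportnlp.cli` | JSONL/CSV formats, run manifests, CLI |

See `docs/methods.md` for the full statistical and design documentation.
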