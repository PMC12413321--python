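# Methods

This note documents the detection rule, its preprocessing and evaluation
conventions, the cohort statistics, and the synthetic-data model, including
the design choices made where the design was genuinely open.

## Detection rule

A mention of transportation insecurity is a sentence-level co-occurrence of
a *transport term* and a *need cue*:

```
\b(T)\b .{0,g}? \b(N)\b        (transport first)
\b(N)\b .{0,g}? \b(T)\b        (need first)
```

with `T ∈ {transportation, ride, driv(e|ing)}` and `N` one of 48 cue
expressions (full set in `src/transportnlp/data/default_lexicon.yaml`).
Matching is case-insensitive; multi-word cues ("due to", "time allowance")
match across any whitespace run; both ends of each term are anchored with
`\b`.

**Gap bound.** The dot in the printed rule is realized as a non-greedy
any-character gap of at most `max_gap` characters, default **50**, confined
to one sentence. A bound is necessary — phrases like "difficulty with
transportation" need a multi-character gap, while an unbounded gap would
join unrelated clauses across a long sentence. 50 characters spans roughly
eight words, enough for every documented matched expression.

**Mention spans.** Each transport-term occurrence contributes at most one
mention, spanning from the nearest qualifying need cue *before* it to the
nearest qualifying need cue *after* it (either side may be absent). This
is what renders a cue–term–cue expression such as "due to ride issues" as
one mention with that exact phrase. Overlapping mentions from different
transport occurrences are deduplicated, shortest span first, ties to the
earlier start. The reported `matched_phrase` is the span lowercased with
whitespace collapsed. An alternative policy (minimal span among all
directional matches) was considered and rejected because it splits
cue–term–cue expressions in two.

**The "no" cue.** The cue `no` is not part of the clinically reviewed term
set, but documented matched expressions include "no transportation" and
"no ride", which are unreachable without it. It ships in the default
lexicon flagged `provenance: inferred` and can be disabled in config.

**Exclusions.** "transit" is absent from the transport terms (fluorescein
angiography collision). Driving terms are present exactly as validated,
with a default-on exclusion rule that suppresses a mention whose transport
term matches `driv(e|ing)` when the sentence also matches
`glare|night|vision|blurr|cataract|see(ing)?`. Keeping the term plus a
contextual exclusion — rather than deleting the term — preserves both
behaviors and makes each independently configurable. Exclusion rules can
only remove matches, never add them.

**Known blind spots, by design.** The rule set has no negation,
uncertainty, or synonym handling: "denies transportation issues" matches
(a contextual false positive) and "mobility issues" never matches (a
linguistic false negative). These are properties of the validated
algorithm; the evaluation and synthetic-data layers exist to measure them.

## Preprocessing

* **Deduplication** removes exact duplicates after whitespace collapsing,
  keeping the first occurrence. Fuzzy duplicate detection is deliberately
  out of scope.
* **Template stripping** removes any line matching a configurable pattern
  list (default: generic transportation-questionnaire phrasings). Removal
  is line-wise, idempotent, and leaves all other bytes untouched.
* **Sentence segmentation** splits at hard line breaks and at
  `[.?!]` followed by whitespace and an uppercase letter or digit, guarded
  by a clinical abbreviation list (`Dr.`, `o.s.`, `o.u.`, `b.i.d.`, month
  abbreviations, …). Clinical notes are telegraphic, so line breaks are
  treated as strong boundaries. Offsets are 0-based half-open into the
  stripped text; every non-whitespace character belongs to exactly one
  sentence. The upstream system's sentence detector is not documented, so
  parity is claimed only for the fixture sentences exercised in the tests.

## Evaluation

Evaluation is **note-level**: a prediction is the boolean flag, gold labels
come from expert annotation. Precision = TP/(TP+FP) (reported as 0 with an
explicit `degenerate_precision` flag when nothing is predicted positive),
recall = TP/(TP+FN), F1 = their harmonic mean, accuracy = (TP+TN)/N.
Metrics are kept unrounded and additionally rounded (2 decimals; accuracy
as a percentage with 1 decimal) for display. Error tags on disagreement
notes are tallied into a fixed taxonomy — contextual errors (negation,
possible/probable language) and linguistic errors (synonym mismatch,
implied inference), plus `other`; tags on agreement notes are ignored with
a warning.

## Cohort statistics

* **Prevalence**: flagged patients / all patients, percent to 1 decimal.
* **Odds ratios**: OR = ad/bc on an exposed/reference 2×2; Woolf CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. When any cell is zero, the
  Haldane–Anscombe 0.5 correction is applied to all four cells and the
  result is flagged. An exact-style (conditional hypergeometric) interval
  via scipy is available for sparse tables; the published intervals for
  near-zero cells are consistent with an exact-type method, so small
  differences from the Woolf default are expected there.
* **Adjusted odds ratios**: binary logistic regression on a dummy-coded
  design with declared reference levels (age 18–<60, male, White,
  Hispanic/Latino), fit by IRLS (statsmodels GLM, binomial family,
  deviance tolerance 1e-8, max 100 iterations), Wald 95% intervals.
  Patients with a declined/missing level on any included factor are
  excluded from the fit, mirroring how such rows carry no odds ratio in
  standard cohort tables. Coefficients diverging toward separation
  (|β| > 15 or non-convergence) are flagged, never clipped; infinite
  interval bounds are reported as such. For a single binary factor the
  fitted OR equals the 2×2 cross-product ratio to 1e-6 (tested).
* **Yearly rates**: among flagged patients only, flagged notes / all notes
  per calendar year, percent to 1 decimal.
* **Inter-event intervals**: patients grouped by mention-event count k;
  for k ≥ 2 the median (IQR) of all consecutive within-patient gaps in
  days; for every k the median (IQR) of days from first encounter to first
  mention. One event is counted per flagged note. Quartiles use linear
  interpolation (numpy default, type-7), so IQRs are exactly reproducible.
  "Time from the first encounter" is defined as first encounter → *first*
  mention event for every group, the least ambiguous reading for k > 1.

## Synthetic corpus

The generator emulates the study conditions, not clinical narrative:

* **Utilization**: notes per patient ~ negative binomial with mean 15.2
  and SD 25.19 (the published cohort's descriptives), truncated at 1 —
  a heavy right tail like real utilization.
* **Need status**: Bernoulli per patient, default prevalence 0.006. With
  planted per-factor effects, need follows a logistic model whose
  intercept is solved (Brent root-finding) so the marginal prevalence
  still matches the request.
* **Mentions**: flagged patients receive 1 + Poisson(0.42) mention notes
  (mean 1.42), each containing one canonical positive sentence drawn from
  the documented matched-expression vocabulary.
* **Demographics**: sampled to the published cohort margins (50% under
  60, 57.8% female, 76.5% White, …); encounter dates uniform over
  2016-01 … 2023-02 to exercise the yearly and interval analytics.
* **Traps**: per-note probabilities on non-need patients' notes for agency
  names, transplantation typos, fluorescein transit, driving/visual
  complaints, confirmed support, negated and hypothetical phrasing, and
  embedded questionnaire blocks; plus a per-flagged-patient probability
  (default 0.15) of one extra need note phrased with an invisible synonym
  ("mobility issues"). Gold labels follow the category (synonym notes are
  gold-positive and undetectable — the recall gap; negation/hypothetical
  notes are gold-negative and detected — false positives). True real-world
  trap frequencies are unknown; the defaults are order-of-magnitude
  choices and every planted sentence is recorded in a truth log, so tests
  assert against the generator's own bookkeeping rather than against
  assumed rates.
* Each note starts with a unique header line so exact-text deduplication
  never collapses independently generated notes — a concession to
  testability, documented here because real corpora have no such guarantee.
* Trap sentences are paraphrase-templates of documented failure fragments,
  not verbatim clinical text. Generation is fully deterministic per seed.

**What passing tests do and do not show.** The synthetic corpus contains
short templated sentences with known trap frequencies; real notes are
longer, messier, and contain failure modes no template anticipates.
Perfect recall on the canonical corpus shows the matcher implements the
rule faithfully, not that the rule captures every real-world phrasing —
the post-hoc-style analytics quantify exactly that gap.

## Simulation experiment sizes

Parameter recovery fits a planted age-band odds ratio of 3.0 on a
50,000-patient cohort; the null-coverage experiment runs 150 replicates of
5,000 patients and checks per-coefficient Wald coverage of the null
against a 90% floor (nominal 95%). Both experiments simulate at a need
prevalence of 0.05 rather than the cohort default 0.006 so each replicate
carries enough cases (≈250 at n=5,000) for the Wald interval to be
meaningful; this is an experiment-design choice about statistical power,
independent of the cohort emulation defaults.

## Known limitations

* No cross-sentence matching; a cue and term split by the segmenter's
  boundary will not pair.
* The lexicon is English-only and tuned to ophthalmology documentation.
* Patient-level demographics come from the first visit; changes over the
  study window are not modeled.
* Chi-square/Fisher p-values beyond what the OR intervals imply, survival
  modeling, and geographic/SES covariates are out of scope.
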