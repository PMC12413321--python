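"""Seeded synthetic clinical-note corpus generator.

Emulates a deidentified ophthalmology note corpus at the published cohort's
operating point: ~15.2 notes per patient with a heavy right tail (negative
binomial, SD ~25), a 0.6% patient prevalence of documented transportation
need, and ~1.42 mention notes per flagged patient.  Planted content comes in
three kinds:

* canonical positive sentences built from the documented matched-expression
  vocabulary ("due to transportation issues", "no ride", ...) — gold
  positive and matched by the default configuration by construction;
* trap sentences reproducing the documented failure modes — agency names
  (Department of Transportation), "transportation" typos for
  transplantation/transposition, the fluorescein-angiography "transit"
  phase, driving-as-visual-function complaints, confirmed-support and
  negated/hypothetical phrasing, synonym expressions ("mobility issues")
  the lexicon cannot see, and embedded questionnaire blocks;
* neutral clinical filler.

Every note carries a gold label and a truth-log entry, so the full pipeline
is testable without any real data.  Generation is fully deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analytics import PatientRecord
from .errors import ConfigError, DataError
from .evaluate import (
    GoldLabel,
    MetricsReport,
    TaxonomyTally,
    confusion_counts,
    classification_metrics,
    taxonomy_tally,
)
from .matcher import NoteResult
from .preprocess import RawNote

# --------------------------------------------------------------- templates

#: category -> (gold polarity, sentence templates).  Scrubber placeholders
#: ([PERSONALNAME], [DATE]) are left in the text as ordinary tokens, the way
#: they appear in scrubbed notes.
TEMPLATES: dict[str, tuple[bool, tuple[str, ...]]] = {
    "positive_due_to": (
        True,
        (
            "He states that he never returned for any post-operative exams "
            "after the surgery in [DATE] due to transportation issues.",
            "Missed prior follow up due to transportation.",
        ),
    ),
    "positive_ride_issues": (
        True,
        (
            "She is unable to stay for an injection due to ride issues today "
            "and wishes to observe.",
        ),
    ),
    "positive_no_transportation": (
        True,
        ("Pt called to reschedule, she has no transportation.",),
    ),
    "positive_no_ride": (True, ("Had to cx that appt, no ride.",)),
    "positive_arrange": (
        True,
        ("Daughter will arrange transportation for the next appointment.",),
    ),
    "positive_difficulty": (
        True,
        ("Reports difficulty with transportation this winter.",),
    ),
    "positive_issues": (
        True,
        ("Transportation issues prevented attendance today.",),
    ),
    "positive_options": (
        True,
        ("Discussed transportation options with social work.",),
    ),
    "positive_unable_get": (
        True,
        ("Unable to get transportation to clinic today.",),
    ),
    "positive_needs": (
        True,
        ("Patient needs transportation assistance for return visit.",),
    ),
    "dot_agency": (
        False,
        (
            "Referred for vision screening due to Pennsylvania Department of "
            "Transportation requirements.",
            "Patient retired from the Department of Transportation, "
            "discussed job history.",
        ),
    ),
    "typo_transplant": (
        False,
        ("Discussed corneal transportation scheduling for next month.",),
    ),
    "fluorescein_transit": (
        False,
        (
            "Fluorescein angiography transit phase unremarkable.",
            "FA shows normal arm to eye transit time.",
        ),
    ),
    "driving_visual": (
        False,
        (
            "Reports difficulty driving at night from glare.",
            "Trouble driving at night with glare and halos, cataract "
            "evaluation scheduled.",
        ),
    ),
    "confirmed_support": (
        False,
        (
            "Son agrees to be his transportation to and from appointments "
            "and assist with care.",
            "Patient has reliable transportation with her daughter.",
        ),
    ),
    "negation": (
        False,
        (
            "Denies any transportation issues at this time.",
            "No transportation concerns reported today.",
        ),
    ),
    "hypothetical": (
        False,
        (
            "May have difficulty with transportation for early morning "
            "visits.",
            "Will call if transportation issues arise before surgery.",
        ),
    ),
    "synonym_mobility": (
        True,
        (
            "Patient reports ongoing mobility issues affecting clinic "
            "attendance.",
            "Mobility restrictions make it hard to come in for visits.",
        ),
    ),
    "template_block": (
        False,
        (
            "Social history questionnaire:\n"
            "Transportation needs: on file\n"
            "Do you have reliable transportation to medical appointments: yes",
        ),
    ),
}

POSITIVE_CATEGORIES = tuple(c for c in TEMPLATES if c.startswith("positive_"))

#: Taxonomy tag attached to each trap category's gold label (used when the
#: detector and the gold label disagree).
TRAP_TAXONOMY = {
    "negation": "contextual:negation",
    "hypothetical": "contextual:possible_probable",
    "synonym_mobility": "linguistic:synonym_mismatch",
    "dot_agency": "other",
    "typo_transplant": "other",
    "confirmed_support": "other",
}

_FILLER = (
    "Visual acuity stable in both eyes.",
    "Intraocular pressure well controlled on current drops.",
    "Dilated fundus exam performed, no new findings.",
    "Follow up in {months} months.",
    "Patient seen by Dr. [PERSONALNAME] today.",
    "Refill request processed for latanoprost.",
    "Telephone encounter regarding medication schedule.",
    "Discussed findings and plan with the patient.",
)

_DEFAULT_TRAP_MIX = {
    # per-note probabilities on non-need patients' notes ...
    "dot_agency": 2e-4,
    "typo_transplant": 2e-4,
    "fluorescein_transit": 3e-3,
    "driving_visual": 3e-3,
    "confirmed_support": 2e-4,
    "negation": 5e-4,
    "hypothetical": 5e-4,
    "template_block": 0.03,
    # ... except synonym_mobility: per-flagged-patient probability of one
    # extra gold-positive note the lexicon cannot see.
    "synonym_mobility": 0.15,
}

_DEFAULT_MARGINS = {
    "age_band": {"18-<60": 0.50, "60-<70": 0.24, "70-<80": 0.168, ">=80": 0.092},
    "sex": {"Female": 0.578, "Male": 0.422},
    "race": {
        "White": 0.765,
        "Black": 0.148,
        "Asian": 0.043,
        "Native American and Alaska Native": 0.0025,
        "Pacific Islander": 0.0012,
        "Declined or missing": 0.0403,
    },
    "ethnicity": {
        "Non-Hispanic or Latino": 0.915,
        "Hispanic or Latino": 0.013,
        "Declined or missing": 0.072,
    },
}

_WINDOW = (date(2016, 1, 1), date(2023, 2, 28))


@dataclass(frozen=True)
class SimParams:
    n_patients: int = 1000
    notes_per_patient_mean: float = 15.2
    notes_per_patient_sd: float = 25.19
    need_prevalence: float = 0.006
    mentions_per_flagged_mean: float = 1.42
    trap_mix: dict = field(default_factory=lambda: dict(_DEFAULT_TRAP_MIX))
    demographic_margins: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARGINS.items()}
    )
    planted_effects: dict = field(default_factory=dict)  # factor -> level -> OR
    window: tuple[date, date] = _WINDOW
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.need_prevalence <= 1.0:
            raise ConfigError("need_prevalence must lie in [0, 1]")
        if self.mentions_per_flagged_mean < 1.0:
            raise ConfigError("mentions_per_flagged_mean must be >= 1")
        unknown = set(self.trap_mix) - set(_DEFAULT_TRAP_MIX)
        if unknown:
            raise ConfigError(f"unknown trap categories: {sorted(unknown)}")
        if any(not 0.0 <= v <= 1.0 for v in self.trap_mix.values()):
            raise ConfigError("trap_mix values must lie in [0, 1]")
        if sum(self.trap_mix.values()) > 1.0 + 1e-9:
            raise ConfigError("trap_mix proportions must sum to <= 1")
        for factor, margins in self.demographic_margins.items():
            total = sum(margins.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(
                    f"margins for {factor!r} sum to {total}, expected 1"
                )
        for factor in self.planted_effects:
            if factor not in self.demographic_margins:
                raise ConfigError(f"planted effect on unknown factor {factor!r}")


@dataclass(frozen=True)
class SyntheticCorpus:
    notes: tuple[RawNote, ...]
    gold: tuple[GoldLabel, ...]
    demographics: pd.DataFrame
    truth_log: tuple[dict, ...]


def sample_sentence(category: str, rng: np.random.Generator) -> tuple[str, bool]:
    """One filled template for a category plus its gold polarity."""
    if category not in TEMPLATES:
        raise ValueError(f"unknown template category {category!r}")
    gold, options = TEMPLATES[category]
    return str(rng.choice(options)), gold


def _negbin_counts(rng, n, mean, sd):
    var = sd * sd
    if var <= mean:  # no overdispersion requested: Poisson
        draws = rng.poisson(mean, size=n)
    else:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=n)
    return np.maximum(draws, 1)


def _sample_categorical(rng, margins: dict, n: int) -> np.ndarray:
    levels = list(margins)
    probs = np.asarray([margins[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _need_probabilities(params: SimParams, demo: pd.DataFrame) -> np.ndarray:
    """Per-patient need probability under the planted log-odds effects,
    intercept calibrated so the marginal prevalence matches the request."""
    prev = params.need_prevalence
    eta = np.zeros(len(demo))
    for factor, effects in params.planted_effects.items():
        for level, or_value in effects.items():
            eta += np.log(or_value) * (demo[factor].to_numpy() == level)
    if not params.planted_effects:
        return np.full(len(demo), prev)
    if prev in (0.0, 1.0):
        return np.full(len(demo), prev)

    def mean_minus_target(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta))))) - prev

    b0 = brentq(mean_minus_target, -25.0, 25.0, xtol=1e-10)
    return 1.0 / (1.0 + np.exp(-(b0 + eta)))


def generate_cohort(params: SimParams) -> list[PatientRecord]:
    """Patient-level cohort only (demographics + planted need status), for
    association/regression experiments that do not require note text.  A
    flagged patient carries one placeholder mention event."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    demo = pd.DataFrame(
        {
            factor: _sample_categorical(rng, margins, n)
            for factor, margins in params.demographic_margins.items()
        }
    )
    need = rng.random(n) < _need_probabilities(params, demo)
    start = params.window[0]
    return [
        PatientRecord(
            patient_id=f"P{i:06d}",
            age_band=demo.at[i, "age_band"],
            sex=demo.at[i, "sex"],
            race=demo.at[i, "race"],
            ethnicity=demo.at[i, "ethnicity"],
            first_encounter_date=start,
            total_notes=1,
            mention_events=(start,) if need[i] else (),
        )
        for i in range(n)
    ]


def generate_corpus(params: SimParams) -> SyntheticCorpus:
    """Full synthetic corpus: notes with planted sentences, gold labels,
    demographics and a truth log.  Deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    demo = pd.DataFrame(
        {
            factor: _sample_categorical(rng, margins, n)
            for factor, margins in params.demographic_margins.items()
        }
    )
    need = rng.random(n) < _need_probabilities(params, demo)
    n_notes = _negbin_counts(
        rng, n, params.notes_per_patient_mean, params.notes_per_patient_sd
    )

    day0, day1 = params.window[0].toordinal(), params.window[1].toordinal()
    note_traps = [c for c in _DEFAULT_TRAP_MIX if c != "synonym_mobility"]
    trap_p = np.asarray([params.trap_mix.get(c, 0.0) for c in note_traps])

    notes: list[RawNote] = []
    gold: list[GoldLabel] = []
    truth: list[dict] = []
    first_dates: list[date] = []

    for i in range(n):
        pid = f"P{i:06d}"
        k_notes = int(n_notes[i])
        days = np.sort(rng.integers(day0, day1 + 1, size=k_notes))
        first_dates.append(date.fromordinal(int(days[0])))

        planted: dict[int, str] = {}
        if need[i]:
            k_mentions = min(
                1 + int(rng.poisson(params.mentions_per_flagged_mean - 1.0)),
                k_notes,
            )
            for j in rng.choice(k_notes, size=k_mentions, replace=False):
                planted[int(j)] = str(rng.choice(POSITIVE_CATEGORIES))
            if rng.random() < params.trap_mix.get("synonym_mobility", 0.0):
                free = [j for j in range(k_notes) if j not in planted]
                if free:
                    planted[int(rng.choice(free))] = "synonym_mobility"

        for j in range(k_notes):
            note_id = f"N{i:06d}-{j:03d}"
            category = planted.get(j)
            if category is None and not need[i]:
                u = rng.random()
                cum = 0.0
                for c, p in zip(note_traps, trap_p):
                    cum += p
                    if u < cum:
                        category = c
                        break

            months = int(rng.integers(1, 13))
            filler_idx = rng.choice(
                len(_FILLER), size=int(rng.integers(2, 5)), replace=False
            )
            body = [_FILLER[f].format(months=months) for f in filler_idx]
            label = False
            if category is not None:
                sent, label = sample_sentence(category, rng)
                if category == "template_block":
                    body.insert(0, sent)
                else:
                    body.insert(int(rng.integers(0, len(body) + 1)), sent)
            # Unique header keeps exact-text deduplication from collapsing
            # independently generated notes.
            text = f"Clinic note {note_id}.\n" + "\n".join(body)
            note_type = str(
                rng.choice(
                    ["office visit", "telephone", "refill"], p=[0.7, 0.2, 0.1]
                )
            )
            notes.append(
                RawNote(
                    patient_id=pid,
                    note_id=note_id,
                    encounter_date=date.fromordinal(int(days[j])),
                    note_type=note_type,
                    text=text,
                )
            )
            tags = ()
            if category in TRAP_TAXONOMY:
                tags = (TRAP_TAXONOMY[category],)
            gold.append(GoldLabel(note_id=note_id, label=label, error_tags=tags))
            if category is not None:
                truth.append(
                    {
                        "note_id": note_id,
                        "patient_id": pid,
                        "category": category,
                        "gold": bool(label),
                        "encounter_date": date.fromordinal(int(days[j])).isoformat(),
                    }
                )

    demo_out = demo.copy()
    demo_out.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    demo_out["first_encounter_date"] = [d.isoformat() for d in first_dates]
    return SyntheticCorpus(
        notes=tuple(notes),
        gold=tuple(gold),
        demographics=demo_out,
        truth_log=tuple(truth),
    )


def truth_metrics(
    corpus: SyntheticCorpus, results: list[NoteResult]
) -> tuple[MetricsReport, TaxonomyTally]:
    """Score pipeline results against the corpus's own gold labels and tally
    planted-category errors."""
    result_ids = {r.note_id for r in results}
    gold_ids = {g.note_id for g in corpus.gold}
    if not gold_ids <= result_ids:
        missing = sorted(gold_ids - result_ids)
        raise DataError(
            f"results missing {len(missing)} corpus note(s): "
            + ", ".join(missing[:10])
        )
    metrics = classification_metrics(
        confusion_counts(list(results), list(corpus.gold))
    )
    tally = taxonomy_tally(list(corpus.gold), list(results))
    return metrics, tally
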