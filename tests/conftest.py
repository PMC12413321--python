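"""Shared fixtures: default lexicon/patterns, worked-example sentences, and
an independent brute-force co-occurrence oracle used to cross-check the
compiled matcher."""

from __future__ import annotations

import re
from datetime import date

import pytest
from hypothesis import settings

from transportnlp import (
    RawNote,
    compile_patterns,
    default_lexicon,
)
from transportnlp.lexicon import NEED, TRANSPORT, Lexicon

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def patterns(lexicon):
    return compile_patterns(lexicon, max_gap=50, case_insensitive=True)


#: (sentence, expected normalized matched phrase) — documented worked
#: examples of the algorithm's matched expressions.
WORKED_POSITIVE = [
    (
        "She is unable to stay for an injection due to ride issues today "
        "and wishes to observe.",
        "due to ride issues",
    ),
    (
        "He states that he never returned for any post-operative exams "
        "after the surgery in December due to transportation issues.",
        "due to transportation issues",
    ),
    (
        "It was decided by the Pt to use Ozurdex today for [PERSONALNAME] "
        "but no ozrudex in the office today and she has no transportation.",
        "no transportation",
    ),
    (
        "Huge change os, noticed 3 months ago, had appt in Aug. 2016, had "
        "to cx that appt., no ride.",
        "no ride",
    ),
]

#: Documented false-positive classes — matched by design.
KNOWN_FALSE_POSITIVES = [
    "Referred for vision screening due to Pennsylvania Department of "
    "Transportation requirements.",
    "Discussed corneal transportation scheduling for next month.",
    "Son agrees to be his transportation to and from appointments and "
    "assist with care.",
    "Denies any transportation issues at this time.",
]

#: Not matched: "transit" is out of the dictionary; synonyms are invisible;
#: driving complaints in visual-function context are excluded.
KNOWN_NEGATIVE = [
    "Fluorescein angiography transit phase unremarkable.",
    "Patient reports ongoing mobility issues affecting clinic attendance.",
    "Reports difficulty driving at night from glare.",
    "Visual acuity stable in both eyes.",
]


def oracle_sentence_match(text: str, lexicon: Lexicon, max_gap: int) -> bool:
    """Brute-force pair scan: every transport occurrence crossed with every
    need occurrence, same sentence, either order, character gap <= max_gap.
    Deliberately independent of the compiled-pattern implementation."""

    def occurrences(category):
        occ = []
        for entry in lexicon.terms(category):
            pat = re.compile(
                rf"\b(?:{entry.pattern.replace(' ', chr(92) + 's+')})\b",
                re.IGNORECASE,
            )
            occ.extend((m.start(), m.end()) for m in pat.finditer(text))
        return occ

    t_occ = occurrences(TRANSPORT)
    if not t_occ:
        return False
    n_occ = occurrences(NEED)
    for ts, te in t_occ:
        for ns, ne in n_occ:
            if 0 <= ns - te <= max_gap or 0 <= ts - ne <= max_gap:
                return True
    return False


def make_note(text: str, note_id: str = "n1", patient_id: str = "p1",
              when: date = date(2020, 6, 1), note_type: str = "office visit") -> RawNote:
    return RawNote(
        patient_id=patient_id,
        note_id=note_id,
        encounter_date=when,
        note_type=note_type,
        text=text,
    )
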