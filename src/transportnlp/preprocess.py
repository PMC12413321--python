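"""Note normalization: deduplication, questionnaire-template stripping and
sentence segmentation.

Clinical notes are telegraphic; hard line breaks are treated as sentence
boundaries, and an abbreviation guard keeps common clinical shorthand
("Dr.", "o.u.", "b.i.d.", month abbreviations) from splitting sentences.
Scrubber placeholders such as ``[PERSONALNAME]`` are ordinary tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from importlib import resources

from .errors import PatternError


@dataclass(frozen=True)
class RawNote:
    patient_id: str
    note_id: str
    encounter_date: date
    note_type: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """Half-open 0-based character span into a note's stripped text."""

    index: int
    start: int
    end: int
    content: str


@dataclass(frozen=True)
class CleanNote(RawNote):
    stripped_text: str = ""
    sentences: tuple[Sentence, ...] = ()


# Tokens (lowercased, trailing period excluded) that do not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "vs", "approx", "prn", "etc",
    "o.s", "o.d", "o.u", "q.d", "b.i.d", "t.i.d", "q.i.d",
    "jan", "feb", "mar", "apr", "jun", "jul", "aug", "sep", "sept",
    "oct", "nov", "dec",
}

_TERMINAL = re.compile(r"[.?!]+")
_NEXT_STARTS_SENTENCE = re.compile(r"\s+[\"'(\[]?[A-Z0-9]")
_LAST_TOKEN = re.compile(r"([A-Za-z](?:\.?[A-Za-z])*)$")


def deduplicate_notes(notes: list[RawNote]) -> list[RawNote]:
    """Drop exact duplicates (whitespace-collapsed text), keeping the first
    occurrence; order otherwise preserved.  Idempotent."""
    seen: set[str] = set()
    kept: list[RawNote] = []
    for note in notes:
        key = " ".join(note.text.split())
        if key in seen:
            continue
        seen.add(key)
        kept.append(note)
    return kept


def default_template_patterns() -> list[str]:
    """Questionnaire-line patterns shipped with the package."""
    text = (
        resources.files("transportnlp.data")
        .joinpath("template_patterns.txt")
        .read_text(encoding="utf-8")
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


def _compile_templates(templates: list[str]) -> list[re.Pattern]:
    compiled = []
    for i, pat in enumerate(templates):
        try:
            compiled.append(re.compile(pat))
        except re.error as exc:
            raise PatternError(f"template[{i}]", pat, str(exc)) from None
    return compiled


def strip_template_blocks(text: str, templates: list[str] | None = None) -> str:
    """Remove every line matched by a template pattern; all other text is
    preserved byte-identically.  Idempotent."""
    if templates is None:
        templates = default_template_patterns()
    compiled = _compile_templates(templates)
    kept = []
    for line in text.splitlines(keepends=True):
        bare = line.rstrip("\r\n")
        if any(p.search(bare) for p in compiled):
            continue
        kept.append(line)
    return "".join(kept)


def segment_sentences(text: str) -> list[Sentence]:
    """Deterministic sentence segmentation.

    Boundaries: hard line breaks, and sentence-final punctuation followed by
    whitespace and an uppercase letter or digit, unless the preceding token
    is a guarded abbreviation.  Every non-whitespace character of ``text``
    is covered by exactly one sentence.
    """
    breaks: set[int] = set()
    for i, ch in enumerate(text):
        if ch == "\n":
            breaks.add(i + 1)
    for m in _TERMINAL.finditer(text):
        end = m.end()
        if end >= len(text):
            continue
        if not _NEXT_STARTS_SENTENCE.match(text, end):
            continue
        tok = _LAST_TOKEN.search(text, 0, m.start())
        if tok and tok.group(1).lower() in _ABBREVIATIONS:
            continue
        breaks.add(end)

    sentences: list[Sentence] = []
    prev = 0
    for b in sorted(breaks | {len(text)}):
        chunk = text[prev:b]
        lead = len(chunk) - len(chunk.lstrip())
        start = prev + lead
        end = prev + len(chunk.rstrip())
        if end > start:
            sentences.append(
                Sentence(
                    index=len(sentences),
                    start=start,
                    end=end,
                    content=text[start:end],
                )
            )
        prev = b
    return sentences


def clean_note(note: RawNote, templates: list[str] | None = None) -> CleanNote:
    stripped = strip_template_blocks(note.text, templates)
    sentences = tuple(segment_sentences(stripped))
    return CleanNote(
        patient_id=note.patient_id,
        note_id=note.note_id,
        encounter_date=note.encounter_date,
        note_type=note.note_type,
        text=note.text,
        stripped_text=stripped,
        sentences=sentences,
    )


def clean_notes(
    notes: list[RawNote], templates: list[str] | None = None
) -> list[CleanNote]:
    """Full preprocessing pipeline: deduplicate, strip templates, segment."""
    if templates is None:
        templates = default_template_patterns()
    return [clean_note(n, templates) for n in deduplicate_notes(notes)]
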