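"""Sentence-level co-occurrence matching and exclusion filtering.

A sentence yields one mention per transport-term occurrence that has at
least one need cue within ``max_gap`` characters on either side, in the same
sentence.  The mention span runs from the nearest qualifying need cue before
the transport term to the nearest one after it (either side optional), which
is what makes reported phrases like "due to transportation issues" — need
cue, transport term, need cue — come out as a single expression.
Overlapping mentions from different transport occurrences are deduplicated
(shortest span wins, ties to the earlier start).

There is deliberately no negation or hypothetical-language handling:
"denies transportation issues" matches.  That blind spot is part of the
validated behavior of the rule set and is measured, not patched, by the
evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .lexicon import ExclusionRule, PatternSet
from .preprocess import CleanNote, Sentence

TRANSPORT_FIRST = "transport_first"
NEED_FIRST = "need_first"


@dataclass(frozen=True)
class MentionMatch:
    note_id: str | None
    patient_id: str | None
    sentence_index: int
    span: tuple[int, int]  # offsets within the sentence
    matched_phrase: str  # lowercased, whitespace-collapsed
    transport_term_label: str
    need_term_label: str
    direction: str  # TRANSPORT_FIRST or NEED_FIRST
    transport_text: str = ""
    need_text: str = ""


@dataclass(frozen=True)
class NoteResult:
    note_id: str
    patient_id: str
    encounter_date: object
    mentions: tuple[MentionMatch, ...]

    @property
    def flagged(self) -> bool:
        return len(self.mentions) > 0


def _occurrences(scan, labels, text):
    out = []
    for m in scan.finditer(text):
        name = m.lastgroup
        if name is None:  # nested unnamed group matched last
            name = next(k for k, v in m.groupdict().items() if v is not None)
        out.append((m.start(), m.end(), labels[int(name[1:])], m.group()))
    return out


def _normalize(phrase: str) -> str:
    return " ".join(phrase.lower().split())


def match_sentence(sentence: Sentence, patterns: PatternSet) -> list[MentionMatch]:
    """All transportation-need mentions in one sentence (pre-exclusion)."""
    text = sentence.content
    t_occ = _occurrences(patterns.transport_scan, patterns.transport_labels, text)
    if not t_occ:
        return []
    n_occ = _occurrences(patterns.need_scan, patterns.need_labels, text)
    if not n_occ:
        return []

    gap = patterns.max_gap
    candidates = []
    for ts, te, t_label, t_text in t_occ:
        before = [n for n in n_occ if n[1] <= ts and ts - n[1] <= gap]
        after = [n for n in n_occ if n[0] >= te and n[0] - te <= gap]
        nb = max(before, key=lambda n: n[1]) if before else None
        na = min(after, key=lambda n: n[0]) if after else None
        if nb is None and na is None:
            continue
        start = nb[0] if nb else ts
        end = na[1] if na else te
        if nb is not None and (na is None or ts - nb[1] <= na[0] - te):
            need = nb
        else:
            need = na
        candidates.append(
            MentionMatch(
                note_id=None,
                patient_id=None,
                sentence_index=sentence.index,
                span=(start, end),
                matched_phrase=_normalize(text[start:end]),
                transport_term_label=t_label,
                need_term_label=need[2],
                direction=NEED_FIRST if nb is not None else TRANSPORT_FIRST,
                transport_text=t_text,
                need_text=need[3],
            )
        )

    # Deduplicate overlapping spans: shortest wins, ties to earlier start.
    kept: list[MentionMatch] = []
    for cand in sorted(candidates, key=lambda m: (m.span[1] - m.span[0], m.span[0])):
        if any(
            cand.span[0] < k.span[1] and k.span[0] < cand.span[1] for k in kept
        ):
            continue
        kept.append(cand)
    kept.sort(key=lambda m: m.span)
    return kept


def apply_exclusions(
    matches: list[MentionMatch],
    sentence: Sentence,
    rules: list[ExclusionRule],
) -> list[MentionMatch]:
    """Drop matches suppressed by an enabled rule (trigger on the transport
    term, context anywhere in the sentence).  Never adds matches."""
    active = [(r.trigger_re(), r.context_re()) for r in rules if r.enabled]
    if not active:
        return list(matches)
    kept = []
    for m in matches:
        if any(
            trig.search(m.transport_text) and ctx.search(sentence.content)
            for trig, ctx in active
        ):
            continue
        kept.append(m)
    return kept


def annotate_note(
    note: CleanNote,
    patterns: PatternSet,
    rules: list[ExclusionRule] = (),
) -> NoteResult:
    """Match every sentence of a preprocessed note."""
    mentions: list[MentionMatch] = []
    for sentence in note.sentences:
        hits = match_sentence(sentence, patterns)
        hits = apply_exclusions(hits, sentence, rules)
        mentions.extend(
            replace(m, note_id=note.note_id, patient_id=note.patient_id)
            for m in hits
        )
    return NoteResult(
        note_id=note.note_id,
        patient_id=note.patient_id,
        encounter_date=note.encounter_date,
        mentions=tuple(mentions),
    )


def run_corpus(
    notes: list[CleanNote],
    patterns: PatternSet,
    rules: list[ExclusionRule] = (),
) -> list[NoteResult]:
    """Annotate a deduplicated corpus; one result per note, order preserved,
    fully deterministic."""
    return [annotate_note(n, patterns, rules) for n in notes]
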