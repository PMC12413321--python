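"""Transportation-insecurity lexicon and co-occurrence pattern compilation.

The detector's rule is a sentence-level co-occurrence: a *transport term*
(transportation / ride / driv(e|ing)) and a *need cue* ("due to", "unable",
"issue(s)", ...) occurring within a bounded character gap of each other, in
either order, both anchored on word boundaries::

    \\b(TRANSPORT)\\b .{0,max_gap}? \\b(NEED)\\b      (forward)
    \\b(NEED)\\b .{0,max_gap}? \\b(TRANSPORT)\\b      (backward)

The default term set ships in ``data/default_lexicon.yaml``.  "transit" is
deliberately not a transport term (fluorescein-angiography collision), and a
default-on exclusion rule suppresses driving matches in visual-function
contexts (glare, night vision, cataract) where "difficulty driving" is a
complaint about eyesight rather than about getting to clinic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

from .errors import ConfigError, PatternError

TRANSPORT = "transport"
NEED = "need"

#: Keys of the YAML/JSON lexicon config.
_CATEGORY_KEYS = {"transport_terms": TRANSPORT, "need_terms": NEED}


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary term: a regex source string plus its category."""

    pattern: str
    category: str  # TRANSPORT or NEED
    label: str
    enabled: bool = True
    provenance: str = "validated"

    def __post_init__(self):
        if self.category not in (TRANSPORT, NEED):
            raise ConfigError(
                f"entry {self.label!r}: category must be "
                f"'{TRANSPORT}' or '{NEED}', got {self.category!r}"
            )
        _compile_checked(self.pattern, self.label)


@dataclass(frozen=True)
class ExclusionRule:
    """Suppresses a mention when its transport term matches ``trigger`` and
    the surrounding sentence matches ``context``.  Rules only ever remove
    matches."""

    trigger: str
    context: str
    label: str = "exclusion"
    enabled: bool = True
    provenance: str = "validated"

    def __post_init__(self):
        _compile_checked(self.trigger, f"{self.label}.trigger")
        _compile_checked(self.context, f"{self.label}.context")

    def trigger_re(self) -> re.Pattern:
        return re.compile(self.trigger, re.IGNORECASE)

    def context_re(self) -> re.Pattern:
        return re.compile(self.context, re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]
    exclusion_rules: tuple[ExclusionRule, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "exclusion_rules", tuple(self.exclusion_rules))
        for cat in (TRANSPORT, NEED):
            if not any(e.category == cat for e in self.entries):
                raise ConfigError(f"lexicon has no {cat} entries")
        seen = set()
        for e in self.entries:
            key = (e.pattern, e.category)
            if key in seen:
                raise ConfigError(
                    f"duplicate ({e.pattern!r}, {e.category!r}) entry {e.label!r}"
                )
            seen.add(key)

    def terms(self, category: str, enabled_only: bool = True) -> tuple[LexiconEntry, ...]:
        return tuple(
            e
            for e in self.entries
            if e.category == category and (e.enabled or not enabled_only)
        )


@dataclass(frozen=True)
class PatternSet:
    """Compiled bidirectional co-occurrence patterns plus per-category term
    scanners used for span-level matching."""

    forward: re.Pattern
    backward: re.Pattern
    max_gap: int
    case_insensitive: bool
    transport_scan: re.Pattern = field(repr=False, compare=False, default=None)
    need_scan: re.Pattern = field(repr=False, compare=False, default=None)
    transport_labels: tuple[str, ...] = ()
    need_labels: tuple[str, ...] = ()


def _compile_checked(pattern: str, label: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise PatternError(label, pattern, str(exc)) from None


def _normalize_spaces(pattern: str) -> str:
    # Multi-word terms ("due to", "time allowance") are written with single
    # spaces; match any whitespace run so wrapped note text still hits.
    return pattern.replace(" ", r"\s+")


def default_lexicon() -> Lexicon:
    """The shipped term set (3 transport terms, 48 need cues, one
    driving/visual-function exclusion rule)."""
    text = (
        resources.files("transportnlp.data")
        .joinpath("default_lexicon.yaml")
        .read_text(encoding="utf-8")
    )
    return load_lexicon(text)


def load_lexicon(config_text: str) -> Lexicon:
    """Parse a YAML/JSON lexicon config into a validated :class:`Lexicon`.

    Raises :class:`ConfigError` naming the offending entry on malformed
    config and :class:`PatternError` on an invalid regular expression.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"lexicon config does not parse: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError("lexicon config must be a mapping")

    entries: list[LexiconEntry] = []
    for key, category in _CATEGORY_KEYS.items():
        for i, raw in enumerate(doc.get(key) or []):
            if not isinstance(raw, dict) or "pattern" not in raw:
                raise ConfigError(f"{key}[{i}] must be a mapping with a 'pattern'")
            entries.append(
                LexiconEntry(
                    pattern=str(raw["pattern"]),
                    category=category,
                    label=str(raw.get("label", raw["pattern"])),
                    enabled=bool(raw.get("enabled", True)),
                    provenance=str(raw.get("provenance", "validated")),
                )
            )
    rules: list[ExclusionRule] = []
    for i, raw in enumerate(doc.get("exclusion_rules") or []):
        if not isinstance(raw, dict) or "trigger" not in raw or "context" not in raw:
            raise ConfigError(
                f"exclusion_rules[{i}] must be a mapping with 'trigger' and 'context'"
            )
        rules.append(
            ExclusionRule(
                trigger=str(raw["trigger"]),
                context=str(raw["context"]),
                label=str(raw.get("label", f"rule-{i}")),
                enabled=bool(raw.get("enabled", True)),
                provenance=str(raw.get("provenance", "validated")),
            )
        )
    return Lexicon(entries=tuple(entries), exclusion_rules=tuple(rules))


def dump_lexicon(lexicon: Lexicon) -> str:
    """Serialize a lexicon to YAML; ``load_lexicon`` round-trips it."""
    doc = {
        "transport_terms": [],
        "need_terms": [],
        "exclusion_rules": [],
    }
    key_for = {TRANSPORT: "transport_terms", NEED: "need_terms"}
    for e in lexicon.entries:
        doc[key_for[e.category]].append(
            {
                "label": e.label,
                "pattern": e.pattern,
                "enabled": e.enabled,
                "provenance": e.provenance,
            }
        )
    for r in lexicon.exclusion_rules:
        doc["exclusion_rules"].append(
            {
                "label": r.label,
                "trigger": r.trigger,
                "context": r.context,
                "enabled": r.enabled,
                "provenance": r.provenance,
            }
        )
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def _alternation(entries: Iterable[LexiconEntry], prefix: str) -> tuple[str, tuple[str, ...]]:
    parts, labels = [], []
    for i, e in enumerate(entries):
        parts.append(f"(?P<{prefix}{i}>{_normalize_spaces(e.pattern)})")
        labels.append(e.label)
    return "|".join(parts), tuple(labels)


def compile_patterns(
    lexicon: Lexicon, max_gap: int = 50, case_insensitive: bool = True
) -> PatternSet:
    """Compile the lexicon into the bidirectional co-occurrence patterns.

    ``max_gap`` bounds the number of characters between the two terms (the
    non-greedy any-character gap of the rule); matching never crosses a
    sentence boundary because sentences are matched one at a time.
    """
    if max_gap < 1:
        raise ConfigError(f"max_gap must be >= 1, got {max_gap}")
    flags = re.IGNORECASE if case_insensitive else 0

    t_alt, t_labels = _alternation(lexicon.terms(TRANSPORT), "t")
    n_alt, n_labels = _alternation(lexicon.terms(NEED), "n")
    # Group names must be unique within one pattern, so the directional
    # patterns use plain (non-named) alternations.
    t_plain = "|".join(
        _normalize_spaces(e.pattern) for e in lexicon.terms(TRANSPORT)
    )
    n_plain = "|".join(_normalize_spaces(e.pattern) for e in lexicon.terms(NEED))
    gap = f".{{0,{max_gap}}}?"
    try:
        forward = re.compile(rf"\b(?:{t_plain})\b{gap}\b(?:{n_plain})\b", flags)
        backward = re.compile(rf"\b(?:{n_plain})\b{gap}\b(?:{t_plain})\b", flags)
        transport_scan = re.compile(rf"\b(?:{t_alt})\b", flags)
        need_scan = re.compile(rf"\b(?:{n_alt})\b", flags)
    except re.error as exc:
        raise PatternError("combined", "<lexicon alternation>", str(exc)) from None
    return PatternSet(
        forward=forward,
        backward=backward,
        max_gap=max_gap,
        case_insensitive=case_insensitive,
        transport_scan=transport_scan,
        need_scan=need_scan,
        transport_labels=t_labels,
        need_labels=n_labels,
    )
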