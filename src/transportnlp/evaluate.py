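"""Note-level evaluation against gold annotations.

Precision is the positive predictive value of the flag, recall its
sensitivity, and F1 their harmonic mean; evaluation is per note (not per
mention), matching how the gold standard is annotated.  Disagreements can
carry error-taxonomy tags splitting failures into contextual errors
(negation, possible/probable language) and linguistic errors (synonym
mismatch, implied inference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import DataError
from .matcher import NoteResult

#: Canonical error-taxonomy categories.
TAXONOMY_CATEGORIES = (
    "contextual:negation",
    "contextual:possible_probable",
    "linguistic:synonym_mismatch",
    "linguistic:implied_inference",
    "other",
)

_ALIASES = {
    "negation": "contextual:negation",
    "possible_probable": "contextual:possible_probable",
    "synonym_mismatch": "linguistic:synonym_mismatch",
    "implied_inference": "linguistic:implied_inference",
}


def canonical_category(tag: str) -> str:
    tag = tag.strip()
    tag = _ALIASES.get(tag, tag)
    if tag not in TAXONOMY_CATEGORIES:
        raise ValueError(
            f"unknown error-taxonomy category {tag!r}; "
            f"expected one of {TAXONOMY_CATEGORIES}"
        )
    return tag


@dataclass(frozen=True)
class GoldLabel:
    note_id: str
    label: bool
    error_tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    degenerate_precision: bool = False
    counts: ConfusionCounts | None = None


@dataclass(frozen=True)
class TaxonomyTally:
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        full = {c: 0 for c in TAXONOMY_CATEGORIES}
        full.update(self.counts)
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def confusion_counts(
    predictions: list[NoteResult], gold: list[GoldLabel]
) -> ConfusionCounts:
    """2x2 cross-tabulation of the note-level flag against gold labels."""
    pred_by_id = {p.note_id: p.flagged for p in predictions}
    missing = [g.note_id for g in gold if g.note_id not in pred_by_id]
    if missing:
        raise DataError(
            f"no prediction for {len(missing)} gold note(s): "
            + ", ".join(missing[:10])
        )
    tp = fp = fn = tn = 0
    for g in gold:
        p = pred_by_id[g.note_id]
        if g.label and p:
            tp += 1
        elif g.label and not p:
            fn += 1
        elif not g.label and p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def classification_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1 (harmonic mean) and accuracy from a 2x2 table.

    With no predicted positives, precision is reported as 0 with
    ``degenerate_precision`` set, so reports stay total.
    """
    if cc.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    pred_pos = cc.tp + cc.fp
    degenerate = pred_pos == 0
    precision = 0.0 if degenerate else cc.tp / pred_pos
    recall = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else 0.0
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    accuracy = (cc.tp + cc.tn) / cc.total
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        degenerate_precision=degenerate,
        counts=cc,
    )


def taxonomy_tally(
    gold: list[GoldLabel], predictions: list[NoteResult]
) -> TaxonomyTally:
    """Tally annotator error tags over prediction/gold disagreements.

    Tags attached to notes where prediction and gold agree are ignored with
    a warning; an unknown category string raises ``ValueError``.
    """
    pred_by_id = {p.note_id: p.flagged for p in predictions}
    counts = {c: 0 for c in TAXONOMY_CATEGORIES}
    for g in gold:
        if not g.error_tags:
            continue
        tags = [canonical_category(t) for t in g.error_tags]
        if g.note_id in pred_by_id and pred_by_id[g.note_id] == g.label:
            warnings.warn(
                f"note {g.note_id}: error tags on an agreement note ignored",
                stacklevel=2,
            )
            continue
        for t in tags:
            counts[t] += 1
    return TaxonomyTally(counts=counts)


def report_dict(metrics: MetricsReport) -> dict:
    """Raw and display-rounded metrics plus confusion counts, JSON-ready."""
    out = {
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "accuracy": metrics.accuracy,
        "degenerate_precision": metrics.degenerate_precision,
        "rounded": {
            "precision": round(metrics.precision, 2),
            "recall": round(metrics.recall, 2),
            "f1": round(metrics.f1, 2),
            "accuracy_percent": round(100 * metrics.accuracy, 1),
        },
    }
    if metrics.counts is not None:
        cc = metrics.counts
        out["confusion"] = {"tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn}
    return out
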