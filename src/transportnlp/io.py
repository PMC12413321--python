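"""File readers and writers: notes (JSONL/CSV), gold labels, demographics,
mention/result tables and the run manifest.

All outputs have deterministic column order so identical inputs and
configuration produce byte-identical files.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from .errors import ConfigError, DataError
from .evaluate import GoldLabel
from .lexicon import Lexicon, dump_lexicon
from .matcher import MentionMatch, NoteResult
from .preprocess import RawNote

_NOTE_FIELDS = ("patient_id", "note_id", "encounter_date", "note_type", "text")

MENTION_COLUMNS = [
    "note_id",
    "patient_id",
    "encounter_date",
    "sentence_index",
    "start",
    "end",
    "matched_phrase",
    "transport_term",
    "need_term",
    "direction",
]

RESULT_COLUMNS = ["note_id", "patient_id", "encounter_date", "flagged", "mention_count"]


@dataclass(frozen=True)
class NotesReadResult:
    notes: tuple[RawNote, ...]
    rejects: tuple[dict, ...]  # {"row": int, "error": str}


def _parse_note(record: dict, row: int) -> RawNote:
    missing = [f for f in _NOTE_FIELDS if f not in record or record[f] in (None, "")]
    if missing:
        raise DataError(f"row {row}: missing field(s) {', '.join(missing)}")
    try:
        when = date.fromisoformat(str(record["encounter_date"]).strip()[:10])
    except ValueError:
        raise DataError(
            f"row {row}: unparseable encounter_date {record['encounter_date']!r}"
        ) from None
    return RawNote(
        patient_id=str(record["patient_id"]),
        note_id=str(record["note_id"]),
        encounter_date=when,
        note_type=str(record["note_type"]),
        text=str(record["text"]),
    )


def read_notes(path: str | Path, format: str | None = None) -> NotesReadResult:
    """Read notes from JSONL or CSV; malformed rows are collected, not fatal.

    ``format`` defaults from the file suffix (.jsonl/.json -> jsonl,
    .csv -> csv).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "jsonl" if suffix in (".jsonl", ".json", ".ndjson") else "csv"
    if format not in ("jsonl", "csv"):
        raise ConfigError(f"unknown notes format {format!r}")

    notes: list[RawNote] = []
    rejects: list[dict] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                    if not isinstance(record, dict):
                        raise DataError(f"row {i}: not a JSON object")
                    notes.append(_parse_note(record, i))
                except json.JSONDecodeError as exc:
                    rejects.append({"row": i, "error": f"bad JSON: {exc}"})
                except DataError as exc:
                    rejects.append({"row": i, "error": str(exc)})
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = set(reader.fieldnames or ())
            missing = set(_NOTE_FIELDS) - header
            if missing:
                raise DataError(
                    f"notes CSV missing column(s): {', '.join(sorted(missing))}"
                )
            for i, record in enumerate(reader, start=2):
                try:
                    notes.append(_parse_note(record, i))
                except DataError as exc:
                    rejects.append({"row": i, "error": str(exc)})
    return NotesReadResult(notes=tuple(notes), rejects=tuple(rejects))


def write_notes_jsonl(notes: list[RawNote], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "encounter_date": n.encounter_date.isoformat(),
                        "note_type": n.note_type,
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_gold(path: str | Path) -> list[GoldLabel]:
    """Gold CSV: note_id, label (0/1/true/false), error_tags (semicolon-
    separated, optional)."""
    out = []
    truthy = {"1", "true", "yes", "y"}
    falsy = {"0", "false", "no", "n", ""}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or "note_id" not in reader.fieldnames:
            raise DataError("gold CSV must have a note_id column")
        for i, row in enumerate(reader, start=2):
            raw = str(row.get("label", "")).strip().lower()
            if raw in truthy:
                label = True
            elif raw in falsy:
                label = False
            else:
                raise DataError(f"gold row {i}: unparseable label {raw!r}")
            tags = tuple(
                t.strip()
                for t in str(row.get("error_tags") or "").split(";")
                if t.strip()
            )
            out.append(GoldLabel(note_id=row["note_id"], label=label, error_tags=tags))
    return out


def write_gold(gold: list[GoldLabel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "label", "error_tags"])
        for g in gold:
            writer.writerow([g.note_id, int(g.label), ";".join(g.error_tags)])


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    if "patient_id" not in df.columns:
        raise DataError("demographics CSV must have a patient_id column")
    return df


def read_note_results(path: str | Path) -> list[NoteResult]:
    """Round-trip reader for the note-level results CSV.  Mentions are not
    reconstructed; mention_count is preserved through placeholder spans."""
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            count = int(row["mention_count"])
            placeholder = MentionMatch(
                note_id=row["note_id"],
                patient_id=row["patient_id"],
                sentence_index=0,
                span=(0, 1),
                matched_phrase="?",
                transport_term_label="?",
                need_term_label="?",
                direction="transport_first",
            )
            out.append(
                NoteResult(
                    note_id=row["note_id"],
                    patient_id=row["patient_id"],
                    encounter_date=date.fromisoformat(row["encounter_date"]),
                    mentions=(placeholder,) * count,
                )
            )
    return out


def lexicon_hash(lexicon: Lexicon) -> str:
    return hashlib.sha256(dump_lexicon(lexicon).encode("utf-8")).hexdigest()[:16]


def write_outputs(
    results: list[NoteResult],
    mentions: list[MentionMatch],
    reports: dict,
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Write mention and note-level CSVs plus JSON reports; returns (and
    writes) a manifest listing each file with its row count and the run
    configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dates = {r.note_id: r.encounter_date for r in results}

    mentions_path = out_dir / "mentions.csv"
    with mentions_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MENTION_COLUMNS)
        for m in mentions:
            writer.writerow(
                [
                    m.note_id,
                    m.patient_id,
                    dates.get(m.note_id, ""),
                    m.sentence_index,
                    m.span[0],
                    m.span[1],
                    m.matched_phrase,
                    m.transport_term_label,
                    m.need_term_label,
                    m.direction,
                ]
            )

    results_path = out_dir / "note_results.csv"
    with results_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.note_id,
                    r.patient_id,
                    r.encounter_date.isoformat(),
                    int(r.flagged),
                    len(r.mentions),
                ]
            )

    files = {
        "mentions.csv": len(mentions),
        "note_results.csv": len(results),
    }
    for name, payload in (reports or {}).items():
        report_path = out_dir / name
        report_path.write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        files[name] = 1

    manifest = {"files": files, "config": config or {}}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return manifest
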