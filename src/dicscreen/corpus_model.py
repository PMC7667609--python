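"""Domain records and file I/O for ICU note corpora.

A corpus on disk is four flat files: ``notes.jsonl`` (free text is hostile
to CSV), plus ``stays.csv``, ``codes.csv`` and ``gold.csv``. All timestamps
are ISO 8601; naive timestamps are interpreted as UTC. Patient and note
identifiers are opaque strings and are never parsed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CODE_SYSTEMS = ("ICD9CM", "ICD10CM")
LABEL_SOURCES = ("manual_review", "synthetic_latent")

NOTE_FIELDS = ("patient_id", "note_id", "timestamp", "text")
TABLE_SCHEMAS = {
    "stays": ("patient_id", "stay_id", "admit_ts", "discharge_ts"),
    "codes": ("patient_id", "code", "code_system", "timestamp"),
    "gold": ("patient_id", "dic_status", "source"),
}


class CorpusFormatError(ValueError):
    """A corpus file violates its schema (bad line, column, enum or datetime)."""


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO 8601 timestamp; naive values are taken as UTC."""
    if isinstance(value, datetime):
        dt = value
    else:
        try:
            dt = datetime.fromisoformat(str(value))
        except ValueError as exc:
            raise CorpusFormatError(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def format_timestamp(dt: datetime) -> str:
    return parse_timestamp(dt).isoformat()


@dataclass(frozen=True)
class ClinicalNote:
    """One timestamped free-text document tied to a patient."""

    patient_id: str
    note_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", parse_timestamp(self.timestamp))


@dataclass(frozen=True)
class ICUStay:
    patient_id: str
    stay_id: str
    admit_ts: datetime
    discharge_ts: datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "admit_ts", parse_timestamp(self.admit_ts))
        object.__setattr__(self, "discharge_ts", parse_timestamp(self.discharge_ts))
        if self.admit_ts > self.discharge_ts:
            raise CorpusFormatError(
                f"stay {self.stay_id!r}: admit {self.admit_ts} after discharge {self.discharge_ts}"
            )


@dataclass(frozen=True)
class CodeEvent:
    """One ICD diagnosis-code event (ICD-9-CM or ICD-10-CM)."""

    patient_id: str
    code: str
    code_system: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if not self.code:
            raise CorpusFormatError("code must be non-empty")
        if self.code_system not in CODE_SYSTEMS:
            raise CorpusFormatError(
                f"code_system {self.code_system!r} not one of {CODE_SYSTEMS}"
            )
        object.__setattr__(self, "timestamp", parse_timestamp(self.timestamp))


@dataclass(frozen=True)
class GoldLabel:
    """Per-patient reference DIC status (manual review or synthetic latent truth)."""

    patient_id: str
    dic_status: bool
    source: str = "manual_review"

    def __post_init__(self) -> None:
        if self.source not in LABEL_SOURCES:
            raise CorpusFormatError(f"source {self.source!r} not one of {LABEL_SOURCES}")


@dataclass
class PatientRecord:
    """All stays, notes and code events for one patient."""

    patient_id: str
    stays: list[ICUStay] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)
    codes: list[CodeEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def read_notes(path: str | Path) -> list[ClinicalNote]:
    """Read a JSONL note file: one object per line with patient_id, note_id,
    timestamp and text. Order is preserved; duplicate note_ids are rejected."""
    path = Path(path)
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: invalid JSON") from exc
            missing = [f for f in NOTE_FIELDS if f not in obj]
            if missing:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: missing field(s) {', '.join(missing)}"
                )
            try:
                note = ClinicalNote(
                    patient_id=str(obj["patient_id"]),
                    note_id=str(obj["note_id"]),
                    timestamp=obj["timestamp"],
                    text=str(obj["text"]),
                )
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: {exc}") from exc
            if note.note_id in seen:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: duplicate note_id {note.note_id!r}"
                )
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_notes(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for note in notes:
            handle.write(
                json.dumps(
                    {
                        "patient_id": note.patient_id,
                        "note_id": note.note_id,
                        "timestamp": format_timestamp(note.timestamp),
                        "text": note.text,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def _parse_bool(value: str, row: int) -> bool:
    mapping = {"0": False, "1": True, "false": False, "true": True}
    key = str(value).strip().lower()
    if key not in mapping:
        raise CorpusFormatError(f"row {row}: boolean field has value {value!r}")
    return mapping[key]


def read_table(path: str | Path, kind: str) -> list:
    """Read one of the tabular corpus files (``stays``, ``codes`` or ``gold``)
    into typed records, parsing datetimes and booleans."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    schema = TABLE_SCHEMAS[kind]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in schema]
    if unknown:
        raise CorpusFormatError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing column(s) {missing}")

    records: list = []
    seen_ids: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        values = dict(zip(frame.columns, row))
        try:
            if kind == "stays":
                rec = ICUStay(
                    patient_id=values["patient_id"],
                    stay_id=values["stay_id"],
                    admit_ts=values["admit_ts"],
                    discharge_ts=values["discharge_ts"],
                )
                if rec.stay_id in seen_ids:
                    raise CorpusFormatError(f"duplicate stay_id {rec.stay_id!r}")
                seen_ids.add(rec.stay_id)
            elif kind == "codes":
                rec = CodeEvent(
                    patient_id=values["patient_id"],
                    code=values["code"],
                    code_system=values["code_system"],
                    timestamp=values["timestamp"],
                )
            else:
                rec = GoldLabel(
                    patient_id=values["patient_id"],
                    dic_status=_parse_bool(values["dic_status"], idx),
                    source=values["source"],
                )
                if rec.patient_id in seen_ids:
                    raise CorpusFormatError(
                        f"duplicate gold label for patient {rec.patient_id!r}"
                    )
                seen_ids.add(rec.patient_id)
        except CorpusFormatError as exc:
            raise CorpusFormatError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return records


def write_table(records: Sequence, path: str | Path, kind: str) -> None:
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    rows = []
    for rec in records:
        row = {}
        for col in schema:
            value = getattr(rec, col)
            if isinstance(value, datetime):
                value = format_timestamp(value)
            elif isinstance(value, bool):
                value = int(value)
            row[col] = value
        rows.append(row)
    pd.DataFrame(rows, columns=list(schema)).to_csv(path, index=False)


def load_corpus(
    directory: str | Path,
    require_gold: bool = False,
) -> tuple[list[PatientRecord], list[GoldLabel]]:
    """Load a corpus directory (notes.jsonl, stays.csv, codes.csv, gold.csv)
    into linked patient records plus gold labels.

    notes.jsonl and stays.csv must exist; codes.csv and gold.csv may be
    absent (empty lists) unless ``require_gold`` is set.
    """
    directory = Path(directory)
    for name in ("notes.jsonl", "stays.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing corpus file: {directory / name}")
    notes = read_notes(directory / "notes.jsonl")
    stays = read_table(directory / "stays.csv", "stays")
    codes_path = directory / "codes.csv"
    codes = read_table(codes_path, "codes") if codes_path.exists() else []
    gold_path = directory / "gold.csv"
    if gold_path.exists():
        labels = read_table(gold_path, "gold")
    elif require_gold:
        raise FileNotFoundError(f"missing corpus file: {gold_path}")
    else:
        labels = []
    return link_patients(notes, stays, codes, labels), labels


def link_patients(
    notes: Iterable[ClinicalNote],
    stays: Iterable[ICUStay],
    codes: Iterable[CodeEvent],
    labels: Iterable[GoldLabel] | None = None,
) -> list[PatientRecord]:
    """Group loaded records into per-patient bundles.

    Every patient id appearing in any input gets exactly one record; missing
    children (a patient with stays but no notes, say) are legal and yield
    empty lists. Output is sorted by patient id.
    """
    by_id: dict[str, PatientRecord] = {}

    def rec(pid: str) -> PatientRecord:
        if pid not in by_id:
            by_id[pid] = PatientRecord(patient_id=pid)
        return by_id[pid]

    for stay in stays:
        rec(stay.patient_id).stays.append(stay)
    for note in notes:
        rec(note.patient_id).notes.append(note)
    for code in codes:
        rec(code.patient_id).codes.append(code)
    for label in labels or ():
        rec(label.patient_id)
    return [by_id[pid] for pid in sorted(by_id)]
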