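"""Corpus/result file formats and atomic writing.

Note corpora are UTF-8 CSV tables with the columns ``note_id``,
``patient_id``, ``group``, ``note_date`` (ISO), ``encounter_type``,
``note_type``, ``department`` and ``text``.  Predictions and gold labels
are CSV tables with ``note_id`` plus one 0/1 column per symptom.
Outputs are written atomically (temp file, then rename).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from .classifier import NoteResult, results_to_frame
from .preprocess import RawNote
from .symptoms import SYMPTOMS

NOTE_COLUMNS = ("note_id", "patient_id", "group", "note_date",
                "encounter_type", "note_type", "department", "text")


def atomic_write(path: str | Path, writer: Callable[[str], None]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_text(path: str | Path, text: str) -> None:
    atomic_write(path, lambda tmp: Path(tmp).write_text(text,
                                                        encoding="utf-8"))


def write_frame(frame: pd.DataFrame, path: str | Path,
                index: bool = False) -> None:
    atomic_write(path, lambda tmp: frame.to_csv(
        tmp, index=index, lineterminator="\n"))


def write_json(obj, path: str | Path) -> None:
    write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return dt.date.fromisoformat(s[:10])
    except ValueError:
        return None


def read_notes(path: str | Path) -> list[RawNote]:
    """Read a note corpus CSV (see module docstring for columns)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "note_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'note_id'")
    notes = []
    for _, row in frame.iterrows():
        notes.append(RawNote(
            note_id=row["note_id"],
            patient_id=row.get("patient_id", ""),
            group=row.get("group", "unknown") or "unknown",
            note_date=_parse_date(row.get("note_date", "")),
            encounter_type=row.get("encounter_type", ""),
            note_type=row.get("note_type", ""),
            department=row.get("department", ""),
            text=row.get("text", "")))
    return notes


def write_notes(notes: Iterable[RawNote], path: str | Path) -> None:
    frame = pd.DataFrame([{
        "note_id": n.note_id, "patient_id": n.patient_id,
        "group": n.group,
        "note_date": n.note_date.isoformat() if n.note_date else "",
        "encounter_type": n.encounter_type, "note_type": n.note_type,
        "department": n.department, "text": n.text} for n in notes],
        columns=list(NOTE_COLUMNS))
    write_frame(frame, path)


def write_predictions(results: Iterable[NoteResult],
                      path: str | Path) -> None:
    frame = results_to_frame(results).astype(int).reset_index()
    write_frame(frame, path)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a note-by-symptom 0/1 label table into a boolean frame."""
    frame = pd.read_csv(path)
    if "note_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'note_id'")
    missing = [sid for sid in SYMPTOMS if sid not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing symptom columns {missing}")
    frame = frame.set_index("note_id")
    return frame[list(SYMPTOMS)].astype(bool)
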