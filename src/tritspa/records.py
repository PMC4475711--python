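"""Prescription record model and file I/O.

One record is one clinical encounter: the observed symptoms, the syndromes
the practitioner differentiated, the herbs prescribed, and a binary outcome
(``good`` if the patient improved by the next encounter, else ``bad``).
Records arrive tokenized; token identity is exact string match after
whitespace trimming.

Two plain-text formats are supported:

* CSV with header ``record_id,symptoms,syndromes,herbs,outcome``; the three
  multi-valued cells hold ``;``-separated token lists.
* JSON-lines with one object per record and the same five keys; the
  multi-valued fields are JSON arrays.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

GOOD = "good"
BAD = "bad"
OUTCOMES = (GOOD, BAD)

_COLUMNS = ("record_id", "symptoms", "syndromes", "herbs", "outcome")


@dataclass(frozen=True)
class PrescriptionRecord:
    """A single prescription: token sets plus a treatment outcome.

    ``symptoms`` or ``syndromes`` may be empty (dataset variants that lack
    one entity type); ``herbs`` is always non-empty.
    """

    record_id: str
    symptoms: frozenset[str]
    syndromes: frozenset[str]
    herbs: frozenset[str]
    outcome: str

    @property
    def is_good(self) -> bool:
        return self.outcome == GOOD


def _clean_tokens(raw: Iterable[str], record_id: str, field: str) -> frozenset[str]:
    tokens = set()
    for tok in raw:
        tok = tok.strip()
        if not tok:
            continue
        tokens.add(tok)
    return frozenset(tokens)


def make_record(
    record_id: str,
    symptoms: Iterable[str],
    syndromes: Iterable[str],
    herbs: Iterable[str],
    outcome: str,
) -> PrescriptionRecord:
    """Build a validated record: trim tokens, deduplicate, check invariants."""
    record_id = str(record_id).strip()
    if not record_id:
        raise ValidationError("record_id must be a non-empty string")
    outcome = str(outcome).strip().lower()
    if outcome not in OUTCOMES:
        raise ValidationError(
            f"record {record_id!r}: unknown outcome label {outcome!r} "
            f"(expected one of {OUTCOMES})"
        )
    rec = PrescriptionRecord(
        record_id=record_id,
        symptoms=_clean_tokens(symptoms, record_id, "symptoms"),
        syndromes=_clean_tokens(syndromes, record_id, "syndromes"),
        herbs=_clean_tokens(herbs, record_id, "herbs"),
        outcome=outcome,
    )
    if not rec.herbs:
        raise ValidationError(f"record {record_id!r}: herbs must be non-empty")
    return rec


def _split_cell(cell: str) -> list[str]:
    if cell is None or not cell.strip():
        return []
    return cell.split(";")


def load_records(path: str | Path, format: str | None = None) -> list[PrescriptionRecord]:
    """Read prescription records from ``path``.

    ``format`` is ``"csv"`` or ``"jsonl"``; when omitted it is inferred from
    the file extension (``.jsonl``/``.json`` → JSON-lines, else CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".json") else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "jsonl":
        return _load_jsonl(path)
    raise FormatError(f"unknown records format {format!r} (expected csv or jsonl)")


def _load_csv(path: Path) -> list[PrescriptionRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected header {_COLUMNS}")
        missing = [c for c in _COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        records = []
        for row in reader:
            records.append(
                make_record(
                    row["record_id"],
                    _split_cell(row["symptoms"]),
                    _split_cell(row["syndromes"]),
                    _split_cell(row["herbs"]),
                    row["outcome"],
                )
            )
    return records


def _load_jsonl(path: Path) -> list[PrescriptionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            missing = [c for c in _COLUMNS if c not in obj]
            if missing:
                raise FormatError(
                    f"{path}:{lineno}: missing key(s) {', '.join(missing)}"
                )
            records.append(
                make_record(
                    obj["record_id"],
                    obj["symptoms"],
                    obj["syndromes"],
                    obj["herbs"],
                    obj["outcome"],
                )
            )
    return records


def write_records(
    records: Sequence[PrescriptionRecord], path: str | Path, format: str = "csv"
) -> None:
    """Write records in the same plain-text formats ``load_records`` reads.

    Tokens inside multi-valued cells are sorted so output is deterministic.
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_COLUMNS)
            for rec in records:
                writer.writerow(
                    [
                        rec.record_id,
                        ";".join(sorted(rec.symptoms)),
                        ";".join(sorted(rec.syndromes)),
                        ";".join(sorted(rec.herbs)),
                        rec.outcome,
                    ]
                )
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(
                    json.dumps(
                        {
                            "record_id": rec.record_id,
                            "symptoms": sorted(rec.symptoms),
                            "syndromes": sorted(rec.syndromes),
                            "herbs": sorted(rec.herbs),
                            "outcome": rec.outcome,
                        },
                        sort_keys=False,
                    )
                    + "\n"
                )
    else:
        raise FormatError(f"unknown records format {format!r} (expected csv or jsonl)")
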