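"""Reading, validation and writing of labelled protein sequence data.

Sequences are plain strings over the 20 standard amino-acid letters
(``ACDEFGHIKLMNPQRSTVWY``).  Labels are binary: 1 for the positive class
(antioxidant protein), 0 for the negative class.  Labels may arrive either
by file provenance (one FASTA per class) or via a two-column TSV table
``id<TAB>label``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_ALPHABET)

PathOrStream = Union[str, Path, io.TextIOBase]

__all__ = [
    "STANDARD_ALPHABET",
    "ProteinRecord",
    "LabeledDataset",
    "FastaParseError",
    "SequenceValidationError",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "validate_sequence",
    "validate_records",
    "load_labeled_dataset",
]


class FastaParseError(ValueError):
    """Raised when the input text is not valid FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains non-standard amino-acid letters."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence with an optional binary label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be a non-empty string")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


class LabeledDataset:
    """An ordered collection of uniquely identified, fully labelled records."""

    def __init__(self, records: Sequence[ProteinRecord]):
        records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset: {dupes[:5]}")
        if any(r.label is None for r in records):
            missing = [r.id for r in records if r.label is None]
            raise ValueError(f"all records must be labelled; unlabelled: {missing[:5]}")
        self.records: list[ProteinRecord] = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def labels(self) -> list[int]:
        return [int(r.label) for r in self.records]

    def require_both_classes(self) -> "LabeledDataset":
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError(
                f"training requires both classes; got {self.n_positive} positive "
                f"and {self.n_negative} negative records"
            )
        return self

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])


def _as_text_lines(path_or_stream: PathOrStream):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, "rt", encoding="utf-8")
    return path_or_stream


def read_fasta(path_or_stream: PathOrStream, label: Optional[int] = None) -> list[ProteinRecord]:
    """Parse FASTA text into records, preserving input order.

    Multi-line (wrapped) sequences are concatenated; surrounding whitespace
    is stripped.  If *label* is given it is attached to every record.

    Raises
    ------
    FastaParseError
        If sequence text precedes the first ``>`` header (the offending
        line number is reported).
    """
    handle = _as_text_lines(path_or_stream)
    close = isinstance(path_or_stream, (str, Path))
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError(
                f"line {lineno}: sequence data before the first '>' header"
            )
        break

    records = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        rec_id = title.split()[0] if title.split() else title
        if not rec_id:
            raise FastaParseError("empty FASTA header encountered")
        records.append(ProteinRecord(id=rec_id, sequence="".join(seq.split()), label=label))
    return records


def write_fasta(records: Iterable[ProteinRecord], path_or_stream: PathOrStream, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    handle = _as_text_lines(path_or_stream) if not isinstance(path_or_stream, (str, Path)) else open(
        path_or_stream, "wt", encoding="utf-8"
    )
    close = isinstance(path_or_stream, (str, Path))
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def read_label_table(path_or_stream: PathOrStream) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table (header required, label in {0,1})."""
    handle = _as_text_lines(path_or_stream)
    close = isinstance(path_or_stream, (str, Path))
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    if not lines:
        raise ValueError("empty label table")
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:2]] != ["id", "label"]:
        raise ValueError(f"label table must start with header 'id\\tlabel', got {lines[0]!r}")
    table: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected two tab-separated columns")
        rec_id, raw = parts[0].strip(), parts[1].strip()
        if raw not in ("0", "1"):
            raise ValueError(f"line {lineno}: label must be 0 or 1, got {raw!r}")
        if rec_id in table:
            raise ValueError(f"line {lineno}: duplicate id {rec_id!r}")
        table[rec_id] = int(raw)
    return table


def write_label_table(records: Iterable[ProteinRecord], path_or_stream: PathOrStream) -> None:
    handle = _as_text_lines(path_or_stream) if not isinstance(path_or_stream, (str, Path)) else open(
        path_or_stream, "wt", encoding="utf-8"
    )
    close = isinstance(path_or_stream, (str, Path))
    try:
        handle.write("id\tlabel\n")
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            handle.write(f"{rec.id}\t{rec.label}\n")
    finally:
        if close:
            handle.close()


Policy = Literal["error", "drop", "strip"]


def validate_sequence(record: ProteinRecord, policy: Policy = "error") -> Optional[ProteinRecord]:
    """Enforce the 20-letter standard alphabet on one record.

    Lowercase letters are uppercased first (a common FASTA dialect).  Any
    remaining non-standard character (``B J O U X Z``, gaps, digits, ...)
    is handled per *policy*:

    - ``error``: raise :class:`SequenceValidationError` listing offending
      1-based positions (the default — silent mutation is opt-in);
    - ``strip``: remove the offending characters;
    - ``drop``: return ``None`` to exclude the record.
    """
    seq = record.sequence.upper()
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _STANDARD_SET]
    if not bad:
        return record if seq == record.sequence else replace(record, sequence=seq)
    if policy == "error":
        shown = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
        raise SequenceValidationError(
            f"record {record.id!r}: {len(bad)} non-standard letter(s): {shown}"
        )
    if policy == "drop":
        return None
    if policy == "strip":
        kept = "".join(c for c in seq if c in _STANDARD_SET)
        if not kept:
            return None
        return replace(record, sequence=kept)
    raise ValueError(f"unknown validation policy {policy!r}")


def validate_records(records: Iterable[ProteinRecord], policy: Policy = "error") -> list[ProteinRecord]:
    """Apply :func:`validate_sequence` to each record, excluding dropped ones."""
    out = []
    for rec in records:
        validated = validate_sequence(rec, policy=policy)
        if validated is not None:
            out.append(validated)
    return out


def load_labeled_dataset(
    positive_fasta: Optional[PathOrStream] = None,
    negative_fasta: Optional[PathOrStream] = None,
    fasta: Optional[PathOrStream] = None,
    label_table: Optional[PathOrStream] = None,
    policy: Policy = "error",
) -> LabeledDataset:
    """Build a labelled dataset from class FASTAs or FASTA + label table."""
    if fasta is not None:
        if label_table is None:
            raise ValueError("a label table is required with a single FASTA")
        records = read_fasta(fasta)
        table = read_label_table(label_table)
        missing = [r.id for r in records if r.id not in table]
        if missing:
            raise ValueError(f"records missing from label table: {missing[:5]}")
        records = [replace(r, label=table[r.id]) for r in records]
    else:
        if positive_fasta is None or negative_fasta is None:
            raise ValueError("provide either (positive_fasta, negative_fasta) or (fasta, label_table)")
        records = read_fasta(positive_fasta, label=1) + read_fasta(negative_fasta, label=0)
    return LabeledDataset(validate_records(records, policy=policy))
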