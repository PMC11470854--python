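"""Reading, validating and labelling protein sequence datasets.

Sequences arrive as FASTA (one file per class, or a single file plus a
two-column id/label table). Validation collapses exact duplicate
sequences, handles non-standard residues (B, J, O, U, X, Z, ...) per a
configurable policy, and drops sequences too short to form a dipeptide.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

Label = Literal["positive", "negative", "unlabeled"]
Policy = Literal["reject", "drop", "strip"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled amino-acid sequence."""

    id: str
    sequence: str
    label: Label = "unlabeled"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterReport:
    """Counts of records removed by :func:`validate_and_filter`, per reason."""

    duplicates: int = 0
    invalid_residue: int = 0
    too_short: int = 0

    @property
    def total_removed(self) -> int:
        return self.duplicates + self.invalid_residue + self.too_short


@dataclass
class LabeledDataset:
    """An ordered collection of sequence records with class bookkeeping."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValueError(f"duplicate record id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records))

    @property
    def balanced(self) -> bool:
        """True iff positive and negative counts are equal."""
        counts = self.class_counts
        return counts.get("positive", 0) == counts.get("negative", 0)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into unlabeled records, preserving order.

    Sequences are uppercased; wrapped sequence lines are concatenated.
    Raises :class:`FastaParseError` (with the line number) if sequence
    data precedes the first header, and on empty files.
    """
    path = Path(path)
    text = path.read_text()
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def _with_labels(records: Iterable[SequenceRecord], label: Label) -> list[SequenceRecord]:
    return [replace(r, label=label) for r in records]


def load_labeled_fasta(
    positive: str | Path, negative: str | Path
) -> list[SequenceRecord]:
    """Load the paired-file convention: one FASTA per class."""
    return _with_labels(read_fasta(positive), "positive") + _with_labels(
        read_fasta(negative), "negative"
    )


def load_label_table(
    fasta: str | Path, table: str | Path, sep: str = "\t"
) -> list[SequenceRecord]:
    """Label a FASTA file from a two-column (id, label) delimited table."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(table).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != 2:
            raise ValueError(f"{table}: line {lineno}: expected 2 columns")
        labels[parts[0].strip()] = parts[1].strip().lower()
    records = []
    for rec in read_fasta(fasta):
        label = labels.get(rec.id)
        if label not in ("positive", "negative"):
            raise ValueError(f"record {rec.id!r}: missing or invalid label")
        records.append(replace(rec, label=label))
    return records


def load_supplementary_xlsx(path: str | Path) -> list[SequenceRecord]:
    """Thin reader for the published supplementary spreadsheet layout.

    Expects per-sheet or per-column (id, sequence) pairs for the
    patatin-like (positive) and non-patatin-like (negative) classes:
    either two sheets (first = positive, second = negative), or a single
    sheet with columns id / sequence / label.
    """
    import openpyxl  # optional dependency

    wb = openpyxl.load_workbook(str(path), read_only=True, data_only=True)
    records: list[SequenceRecord] = []

    def harvest(sheet, label: Label | None) -> None:
        header = None
        for row in sheet.iter_rows(values_only=True):
            cells = [("" if c is None else str(c).strip()) for c in row]
            if header is None:
                header = [c.lower() for c in cells]
                continue
            row_map = dict(zip(header, cells))
            seq = row_map.get("sequence", "")
            if not seq:
                continue
            rec_label = label or row_map.get("label", "unlabeled").lower()
            records.append(
                SequenceRecord(
                    id=row_map.get("id") or f"{sheet.title}_{len(records)}",
                    sequence=seq.upper(),
                    label=rec_label,  # type: ignore[arg-type]
                )
            )

    sheets = wb.worksheets
    if len(sheets) >= 2:
        harvest(sheets[0], "positive")
        harvest(sheets[1], "negative")
    else:
        harvest(sheets[0], None)
    return records


def validate_and_filter(
    records: list[SequenceRecord],
    policy: Policy = "drop",
    alphabet: str = STANDARD_ALPHABET,
    min_length: int = 2,
) -> tuple[LabeledDataset, FilterReport]:
    """Deduplicate and sanitise records; return the dataset and a report.

    Exact duplicate sequences collapse to their first occurrence.
    Records containing residues outside ``alphabet`` are rejected
    (raise), dropped, or stripped of the offending characters, per
    ``policy``. Records shorter than ``min_length`` are dropped (every
    encoder divides by N or N-1). The report's reason counts plus the
    surviving record count equal the input count.
    """
    if not records:
        raise ValueError("no input records")
    allowed = set(alphabet)
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    n_dup = n_invalid = n_short = 0
    for rec in records:
        if rec.sequence in seen:
            n_dup += 1
            continue
        seen.add(rec.sequence)
        seq = rec.sequence
        if not set(seq) <= allowed:
            if policy == "reject":
                bad = sorted(set(seq) - allowed)
                raise ValueError(
                    f"record {rec.id!r}: non-standard residues {''.join(bad)}"
                )
            if policy == "drop":
                n_invalid += 1
                continue
            seq = "".join(c for c in seq if c in allowed)
        if len(seq) < min_length:
            n_short += 1
            continue
        kept.append(rec if seq == rec.sequence else replace(rec, sequence=seq))
    if not kept:
        raise ValueError("empty dataset after filtering")
    report = FilterReport(
        duplicates=n_dup, invalid_residue=n_invalid, too_short=n_short
    )
    return LabeledDataset(kept), report
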