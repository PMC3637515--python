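"""Sequence and domain-boundary I/O.

FASTA reading/writing goes through Biopython; records are validated against
the 20-letter alphabet (plus X) on read.  Domain boundaries arrive as a TSV
``id<TAB>start<TAB>end`` with 0-based half-open coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .substitution import encode


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        encode(self.residues)  # raises on illegal characters

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainRegion:
    """A half-open slice [start, end) of a parent sequence."""

    parent_id: str
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}) for {self.parent_id!r}"
            )
        if len(self.residues) != self.end - self.start:
            raise ValueError(
                f"region residues of {self.parent_id!r} have length "
                f"{len(self.residues)}, expected {self.end - self.start}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _check_unique(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; residues are upper-cased and validated."""
    records = []
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = str(bio.seq).upper()
        if not residues:
            raise ValueError(f"sequence {bio.id!r} in {path} is empty")
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        records.append(SequenceRecord(id=bio.id, residues=residues, description=desc))
    _check_unique(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio_records = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def read_boundary_table(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a boundary TSV (header ``id  start  end``; 0-based half-open).

    Lines starting with ``#`` are comments.
    """
    rows: list[tuple[str, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != [
            "id",
            "start",
            "end",
        ]:
            raise ValueError(
                f"{path}: expected header 'id<TAB>start<TAB>end', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {row!r}")
            rows.append((row[0], int(row[1]), int(row[2])))
    return rows


def write_boundary_table(
    rows: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# 0-based half-open coordinates\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "start", "end"])
        for row in rows:
            writer.writerow(list(row))


def extract_domains(
    records: Sequence[SequenceRecord],
    boundary_table: Sequence[tuple[str, int, int]],
) -> list[DomainRegion]:
    """Slice domain regions out of full-length records.

    Every row must reference an existing id with in-bounds coordinates;
    errors name the offending row.
    """
    by_id = {rec.id: rec for rec in records}
    regions = []
    for i, (seq_id, start, end) in enumerate(boundary_table):
        rec = by_id.get(seq_id)
        if rec is None:
            raise KeyError(f"boundary row {i}: unknown sequence id {seq_id!r}")
        if not (0 <= start < end <= len(rec)):
            raise ValueError(
                f"boundary row {i}: region [{start}, {end}) out of range for "
                f"{seq_id!r} (length {len(rec)})"
            )
        regions.append(
            DomainRegion(
                parent_id=seq_id, start=start, end=end, residues=rec.residues[start:end]
            )
        )
    return regions
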