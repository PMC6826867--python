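"""Alignment data model, I/O and gapped/ungapped coordinate arithmetic.

Protein multiple-sequence alignments are the substrate of every downstream
stage: indel scanning, flank-conservation scoring, signature extraction and
reporting.  This module keeps the representation deliberately small — an
ordered list of gapped rows with species and paralog-group labels — and
provides the two coordinate maps (alignment column ↔ ungapped residue
position) that signature reporting depends on.

Conventions
-----------
* All coordinates are 1-based and inclusive, matching the way indel
  positions are conventionally printed in signature tables.
* The canonical gap character is ``'-'``; ``'.'`` is accepted on input and
  normalized.  Ambiguity codes X/B/Z are legal residues but are never
  counted as conserved matches by downstream scoring.
* FASTA headers may carry metadata as ``id|species|homolog_group``; a
  sidecar TSV (columns ``id``, ``species``, ``homolog_group``) overrides
  header-derived labels.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Union

from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

GAP = "-"
#: 20 amino acids, the three common ambiguity codes, and the gap.
RESIDUE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZ")
AMBIGUOUS = frozenset("XBZ")
ALPHABET = RESIDUE_ALPHABET | {GAP}

#: Sentinel returned by :func:`column_to_residue` for gap cells.
GAP_MARKER = None


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, illegal characters or malformed files."""


@dataclass(frozen=True)
class AlignedSequence:
    """One gapped row of a protein alignment."""

    id: str
    residues: str
    species: str = ""
    homolog_group: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentFormatError(f"row {self.id!r}: empty sequence")
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.residues)
            if c not in ALPHABET
        ]
        if bad:
            pos, c = bad[0]
            raise AlignmentFormatError(
                f"row {self.id!r}: illegal character {c!r} at position {pos}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    def is_gap(self, column: int) -> bool:
        """1-based column lookup."""
        return self.residues[column - 1] == GAP


@dataclass(frozen=True)
class RegionSpec:
    """1-based inclusive residue range on the ungapped reference row."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.start}..{self.end} on {self.seq_id!r}"
            )

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class Alignment:
    """Ordered list of equal-length gapped rows."""

    rows: list[AlignedSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows:
            width = len(self.rows[0].residues)
            for row in self.rows:
                if len(row.residues) != width:
                    raise AlignmentFormatError(
                        f"row {row.id!r} has length {len(row.residues)}, "
                        f"expected {width}"
                    )
            seen: set[str] = set()
            for row in self.rows:
                if row.id in seen:
                    raise AlignmentFormatError(f"duplicate row id {row.id!r}")
                seen.add(row.id)

    @property
    def width(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> AlignedSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(f"no row with id {seq_id!r}")

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, col: int) -> str:
        """1-based column as a string, one character per row."""
        if not (1 <= col <= self.width):
            raise IndexError(f"column {col} outside [1, {self.width}]")
        return "".join(r.residues[col - 1] for r in self.rows)

    def slice_columns(self, first: int, last: int) -> "Alignment":
        """Sub-alignment over 1-based inclusive column range."""
        if not (1 <= first <= last <= self.width):
            raise IndexError(
                f"column range {first}..{last} outside [1, {self.width}]"
            )
        return Alignment(
            [
                replace(r, residues=r.residues[first - 1 : last])
                for r in self.rows
            ]
        )

    def drop_all_gap_columns(self) -> tuple["Alignment", list[int]]:
        """Remove columns that are gaps in every row.

        Returns the normalized alignment and the 1-based indices of removed
        columns (in the original coordinate system).
        """
        removed = [
            c
            for c in range(1, self.width + 1)
            if all(r.is_gap(c) for r in self.rows)
        ]
        if not removed:
            return self, []
        keep = [c for c in range(1, self.width + 1) if c not in set(removed)]
        rows = [
            replace(r, residues="".join(r.residues[c - 1] for c in keep))
            for r in self.rows
        ]
        return Alignment(rows), removed


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------

def column_to_residue(
    aln: Alignment, seq_id: str, column: int
) -> Optional[int]:
    """Map a 1-based alignment column to the row's ungapped residue position.

    Returns ``None`` (the gap marker) when the cell at *column* is a gap.
    """
    row = aln.row(seq_id)
    if not (1 <= column <= aln.width):
        raise IndexError(f"column {column} outside [1, {aln.width}]")
    prefix = row.residues[:column]
    if prefix[-1] == GAP:
        return GAP_MARKER
    return len(prefix) - prefix.count(GAP)


def residue_to_column(aln: Alignment, seq_id: str, residue: int) -> int:
    """Inverse of :func:`column_to_residue` on non-gap cells."""
    row = aln.row(seq_id)
    if not (1 <= residue <= row.ungapped_length):
        raise IndexError(
            f"residue {residue} outside [1, {row.ungapped_length}] "
            f"for row {seq_id!r}"
        )
    count = 0
    for i, c in enumerate(row.residues):
        if c != GAP:
            count += 1
            if count == residue:
                return i + 1
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"fasta", "clustal"}


def _parse_header(description: str) -> tuple[str, str, str]:
    """Split an ``id|species|homolog_group`` FASTA header."""
    parts = description.split("|")
    seq_id = parts[0].strip()
    # Species names are stored with '_' in place of spaces so that headers
    # remain single tokens (Clustal ids cannot contain whitespace).
    species = parts[1].strip().replace("_", " ") if len(parts) > 1 else ""
    group = parts[2].strip() if len(parts) > 2 else ""
    return seq_id, species, group


def read_metadata_table(path: Union[str, Path]) -> dict[str, dict[str, str]]:
    """Read a sidecar TSV with columns id, species, homolog_group."""
    meta: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            meta[rec["id"]] = {
                "species": rec.get("species", "") or "",
                "homolog_group": rec.get("homolog_group", "") or "",
            }
    return meta


def read_alignment(
    path: Union[str, Path],
    format: str = "fasta",
    metadata: Optional[Union[str, Path, dict]] = None,
) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    ``'.'`` gaps are normalized to ``'-'``; all-gap columns are removed with
    a logged notice; row order is preserved.  Ragged rows raise
    :class:`AlignmentFormatError` naming the offending id.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if isinstance(metadata, (str, Path)):
        metadata = read_metadata_table(metadata)
    metadata = metadata or {}

    if format == "fasta":
        # SeqIO rather than AlignIO so that ragged input produces our own
        # diagnostic instead of a generic parser error.
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "clustal"))
        except ValueError as exc:
            raise AlignmentFormatError(f"{path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"{path}: no sequences found")

    rows = []
    for rec in records:
        seq_id, species, group = _parse_header(rec.description or rec.id)
        if seq_id in metadata:
            species = metadata[seq_id].get("species", species) or species
            group = metadata[seq_id].get("homolog_group", group) or group
        residues = str(rec.seq).upper().replace(".", GAP)
        rows.append(
            AlignedSequence(
                id=seq_id, residues=residues, species=species,
                homolog_group=group,
            )
        )

    widths = {len(r.residues) for r in rows}
    if len(widths) > 1:
        expected = len(rows[0].residues)
        offender = next(r for r in rows if len(r.residues) != expected)
        raise AlignmentFormatError(
            f"{path}: ragged alignment — row {offender.id!r} has length "
            f"{len(offender.residues)}, expected {expected}"
        )

    aln = Alignment(rows)
    aln, removed = aln.drop_all_gap_columns()
    if removed:
        logger.info(
            "%s: removed %d all-gap column(s): %s", path, len(removed), removed
        )
    return aln


def _compose_header(row: AlignedSequence) -> str:
    species = row.species.replace(" ", "_")
    if row.homolog_group:
        return f"{row.id}|{species}|{row.homolog_group}"
    if species:
        return f"{row.id}|{species}"
    return row.id


def write_alignment(
    aln: Alignment,
    path: Union[str, Path],
    format: str = "fasta",
    line_width: int = 60,
) -> None:
    """Write the alignment; re-reading reproduces row ids, labels and residues."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected {_FORMATS}")
    if not aln.rows:
        raise ValueError("refusing to write an alignment with no rows")
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for row in aln.rows:
                fh.write(f">{_compose_header(row)}\n")
                for i in range(0, len(row.residues), line_width):
                    fh.write(row.residues[i : i + line_width] + "\n")
    else:
        # Hand-rolled writer: Biopython's Clustal writer truncates ids at 30
        # characters, which breaks id|species|group headers on re-read.
        headers = [_compose_header(r) for r in aln.rows]
        pad = max(len(h) for h in headers) + 3
        with open(path, "w") as fh:
            fh.write("CLUSTAL X (2.1) multiple sequence alignment\n\n\n")
            for start in range(0, aln.width, line_width):
                for header, row in zip(headers, aln.rows):
                    chunk = row.residues[start : start + line_width]
                    fh.write(f"{header:<{pad}}{chunk}\n")
                fh.write("\n")
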