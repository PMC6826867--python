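"""Signature presentation: dash-identity alignment blocks, CSI tables and
per-signature bundle files.

The alignment rendering follows the field's figure convention: the top
sequence is shown verbatim, a dash in any other row denotes identity with
the residue shown in the top sequence, a blank cell denotes a gap (kept
visually distinct from identity dashes), and the signature columns are
boxed with ``[`` ``]`` markers.  A decoder is provided so tests can assert
the rendering is lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .alignment import GAP, AlignedSequence, Alignment, RegionSpec
from .taxonomy import SpecificityCall, TaxonomyTree

#: Rendered symbol for a gap cell in non-top rows (identity dashes keep '-').
GAP_SYMBOL = " "
BOX_OPEN = "["
BOX_CLOSE = "]"


@dataclass(frozen=True)
class CSIRecord:
    """A validated conserved signature indel, one table row of output.

    ``indel_type`` is ``ins`` or ``del`` when outgroup polarization
    succeeded, ``ambiguous`` when no scorable outgroup was available.
    """

    protein_name: str
    gene_name: str
    accession: str
    indel_size: int
    indel_type: str
    region: Optional[RegionSpec]
    specificity: SpecificityCall
    flags: tuple[str, ...] = ()
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.indel_size < 1:
            raise ValueError("indel_size must be >= 1")
        if self.indel_type not in ("ins", "del", "ambiguous"):
            raise ValueError(f"bad indel_type {self.indel_type!r}")

    @property
    def indel_label(self) -> str:
        return f"{self.indel_size} aa {self.indel_type}"

    @property
    def position_label(self) -> str:
        return str(self.region) if self.region else ""


# ---------------------------------------------------------------------------
# dash-identity formatting
# ---------------------------------------------------------------------------

def _row_label(row: AlignedSequence) -> str:
    species = row.species.replace(" ", "_")
    if species:
        return f"{row.id}|{species}"
    return row.id


def format_signature(
    window: Alignment,
    top_id: Optional[str] = None,
    box: Optional[tuple[int, int]] = None,
    row_offsets: Optional[dict[str, int]] = None,
) -> str:
    """Render a signature window as a dash-identity text block.

    *box* is the 1-based inclusive column span of the signature; columns
    are delimited with ``[`` and ``]`` in every row.  Each row is framed by
    the 1-based residue coordinates of its first and last shown residue
    (offset per row via *row_offsets* when the window is an excerpt of a
    longer sequence).
    """
    if not window.rows:
        raise ValueError("empty window")
    top_id = top_id or window.rows[0].id
    top = window.row(top_id)
    if box is not None and not (1 <= box[0] <= box[1] <= window.width):
        raise ValueError(f"box {box} outside window of width {window.width}")
    row_offsets = row_offsets or {}

    ordered = [top] + [r for r in window.rows if r.id != top_id]
    labels = [_row_label(r) for r in ordered]
    pad = max(len(l) for l in labels) + 2

    def render_cells(row: AlignedSequence) -> str:
        if row.id == top_id:
            cells = row.residues
        else:
            out = []
            for c_top, c in zip(top.residues, row.residues):
                if c == GAP:
                    out.append(GAP_SYMBOL)
                elif c == c_top:
                    out.append("-")
                else:
                    out.append(c)
            cells = "".join(out)
        if box is not None:
            c1, c2 = box
            cells = cells[: c1 - 1] + BOX_OPEN + cells[c1 - 1 : c2] + BOX_CLOSE + cells[c2:]
        return cells

    lines = [
        f"; dash = identity with top sequence; blank = gap; "
        f"box marks signature columns",
        f"; top = {_row_label(top)}; coordinates are 1-based residue positions",
    ]
    for row, label in zip(ordered, labels):
        offset = row_offsets.get(row.id, 0)
        n_res = row.ungapped_length
        first = offset + 1 if n_res else 0
        last = offset + n_res
        lines.append(
            f"{label:<{pad}}{first:>6}  {render_cells(row)}  {last}"
        )
    return "\n".join(lines) + "\n"


def decode_signature(text: str) -> Alignment:
    """Inverse of :func:`format_signature` (coordinates are discarded)."""
    rows = []
    top_residues: Optional[str] = None
    cell_slice: Optional[tuple[int, int]] = None
    for line in text.rstrip("\n").split("\n"):
        if not line or line.startswith(";"):
            continue
        label = line.split(None, 1)[0]
        if cell_slice is None:
            # The top row is rendered verbatim (gaps as '-', never blank),
            # so its cell field contains no spaces; locate it once and use
            # the same fixed-width slice for every following row.
            rest = line[len(label):]
            coord = rest.split(None, 1)[0]
            start = len(label) + rest.index(coord) + len(coord) + 2
            cells_field = line[start:].rpartition("  ")[0]
            cell_slice = (start, start + len(cells_field))
        cells = line[cell_slice[0] : cell_slice[1]]
        cells = cells.replace(BOX_OPEN, "").replace(BOX_CLOSE, "")
        parts = label.split("|")
        seq_id = parts[0]
        species = parts[1].replace("_", " ") if len(parts) > 1 else ""
        if top_residues is None:
            top_residues = cells
            residues = cells
        else:
            residues = "".join(
                GAP if c == GAP_SYMBOL else (t if c == "-" else c)
                for t, c in zip(top_residues, cells)
            )
        rows.append(
            AlignedSequence(id=seq_id, residues=residues, species=species)
        )
    return Alignment(rows)


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "protein_name",
    "gene_name",
    "accession",
    "indel",
    "position",
    "specificity",
    "exceptions",
    "flags",
]


def export_csi_table(
    records: Sequence[CSIRecord],
    path: Union[str, Path],
    taxonomy: Optional[TaxonomyTree] = None,
) -> None:
    """Write one TSV row per record, Table-style.

    Ordering is deterministic: most specific clade first (taxonomy depth
    when a taxonomy is given, clade name otherwise), then gene name.
    Printed ranges use an ASCII hyphen.  Duplicate (accession, position)
    pairs are rejected.
    """
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.accession, rec.position_label)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)

    def rank(rec: CSIRecord):
        clade = rec.specificity.clade
        if taxonomy is not None and clade in taxonomy.clades:
            depth = -taxonomy.clade_depth(clade)
        else:
            depth = 0
        return (depth, clade, rec.gene_name, rec.accession, rec.position_label)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for rec in sorted(records, key=rank):
            writer.writerow(
                [
                    rec.protein_name,
                    rec.gene_name,
                    rec.accession,
                    rec.indel_label,
                    rec.position_label,
                    rec.specificity.clade,
                    ",".join(sorted(rec.specificity.exceptions)),
                    ",".join(rec.flags),
                ]
            )


def read_csi_table(path: Union[str, Path]) -> list[CSIRecord]:
    """Re-parse an exported table into records (specificity carries only
    the clade and exception list; bearers are not serialized)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            size_s, _, type_s = rec["indel"].partition(" aa ")
            region = None
            if rec["position"]:
                start_s, _, end_s = rec["position"].partition("-")
                region = RegionSpec(
                    seq_id=rec["accession"] or "ref",
                    start=int(start_s),
                    end=int(end_s),
                )
            exceptions = frozenset(
                e for e in rec["exceptions"].split(",") if e
            )
            out.append(
                CSIRecord(
                    protein_name=rec["protein_name"],
                    gene_name=rec["gene_name"],
                    accession=rec["accession"],
                    indel_size=int(size_s),
                    indel_type=type_s,
                    region=region,
                    specificity=SpecificityCall(
                        clade=rec["specificity"],
                        bearers=frozenset(),
                        exceptions=exceptions,
                    ),
                    flags=tuple(f for f in rec["flags"].split(",") if f),
                )
            )
    return out


# ---------------------------------------------------------------------------
# per-CSI signature bundle
# ---------------------------------------------------------------------------

def write_signature_file(
    csi: CSIRecord,
    path: Union[str, Path],
    window: Optional[Alignment] = None,
    box: Optional[tuple[int, int]] = None,
    hits_summary: Optional[dict] = None,
    truth: Optional[dict] = None,
) -> None:
    """Self-contained per-CSI bundle: YAML metadata front matter, the
    dash-identity alignment block, and the screen summary."""
    meta = {
        "format": "csiscan-signature/1",
        "protein_name": csi.protein_name,
        "gene_name": csi.gene_name,
        "accession": csi.accession,
        "indel": csi.indel_label,
        "position": csi.position_label,
        "specificity": csi.specificity.clade,
        "exceptions": sorted(csi.specificity.exceptions),
        "flags": list(csi.flags),
    }
    if truth:
        meta["truth"] = truth
    parts = ["---\n" + yaml.safe_dump(meta, sort_keys=False) + "---\n"]
    if window is not None:
        parts.append(
            "\n# alignment\n"
            + format_signature(window, box=box)
        )
    if hits_summary is not None:
        parts.append(
            "\n# screen\n" + yaml.safe_dump(hits_summary, sort_keys=True)
        )
    Path(path).write_text("".join(parts))


def read_signature_file(
    path: Union[str, Path]
) -> tuple[dict, Optional[Alignment], Optional[dict]]:
    """Parse a signature bundle back into (metadata, window, screen summary)."""
    text = Path(path).read_text()
    if not text.startswith("---\n"):
        raise ValueError(f"{path}: missing YAML front matter")
    _, meta_text, rest = text.split("---\n", 2)
    meta = yaml.safe_load(meta_text)
    window = None
    summary = None
    if "\n# alignment\n" in rest:
        block = rest.split("\n# alignment\n", 1)[1]
        block = block.split("\n# screen\n", 1)[0]
        window = decode_signature(block)
    if "\n# screen\n" in rest:
        summary = yaml.safe_load(rest.split("\n# screen\n", 1)[1])
    return meta, window, summary
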