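"""Single-copy family selection, supermatrix concatenation and gap trimming.

The phylogenomic side of the pipeline: choose protein families that are
present in a single copy in at least a given fraction of the input
genomes (default 80%), concatenate their per-family alignments into one
supermatrix with gap padding for absent genomes, and remove columns
dominated by gaps (a documented, deliberately simple stand-in for
heuristic alignment trimmers).  Tree inference itself is delegated to
external tools; the module emits relaxed-PHYLIP/FASTA supermatrices and a
RAxML-style partition file for them.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .alignment import GAP, AlignedSequence, Alignment, write_alignment

logger = logging.getLogger(__name__)


@dataclass
class FamilyTable:
    """family_id -> {genome -> [sequence ids]} plus the genome roster."""

    members: dict[str, dict[str, list[str]]]
    roster: tuple[str, ...]

    @classmethod
    def from_tsv(cls, path: Union[str, Path], roster: Optional[Sequence[str]] = None):
        """Read a TSV with columns family_id, genome, sequence_id."""
        members: dict[str, dict[str, list[str]]] = {}
        genomes: list[str] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for rec in reader:
                fam = members.setdefault(rec["family_id"], {})
                fam.setdefault(rec["genome"], []).append(rec["sequence_id"])
                if rec["genome"] not in genomes:
                    genomes.append(rec["genome"])
        return cls(members=members, roster=tuple(roster or genomes))

    def single_copy_presence(self, family_id: str) -> set[str]:
        """Genomes contributing exactly one member; duplicated genomes are
        disqualified (logged)."""
        present = set()
        for genome, seqs in self.members.get(family_id, {}).items():
            if genome not in self.roster:
                continue
            if len(seqs) == 1:
                present.add(genome)
            else:
                logger.info(
                    "family %s: genome %s contributes %d members, "
                    "disqualified from presence count",
                    family_id, genome, len(seqs),
                )
        return present


def select_families(
    table: FamilyTable, min_fraction: float = 0.8
) -> list[str]:
    """Families with single-copy presence in >= ceil(fraction * roster).

    Presence is counted after duplicate disqualification, so a paralogous
    expansion in one genome both removes that genome and can push the
    family below threshold.
    """
    if not table.roster:
        raise ValueError("genome roster is empty")
    need = math.ceil(min_fraction * len(table.roster))
    out = []
    for fam in sorted(table.members):
        if len(table.single_copy_presence(fam)) >= need:
            out.append(fam)
    return out


def concatenate_alignments(
    per_family: Mapping[str, Alignment],
    roster: Sequence[str],
) -> tuple[Alignment, dict[str, tuple[int, int]]]:
    """Concatenate per-family alignments (rows keyed by genome id) into a
    supermatrix.

    Total width is the sum of family widths; a genome absent from a family
    is padded with gaps across that family's block.  The returned
    partition map gives each family's 1-based inclusive column interval.
    """
    partitions: dict[str, tuple[int, int]] = {}
    pieces: dict[str, list[str]] = {g: [] for g in roster}
    col = 0
    for fam_id, aln in per_family.items():
        counts: dict[str, int] = {}
        for row in aln.rows:
            counts[row.id] = counts.get(row.id, 0) + 1
        dup = [g for g, c in counts.items() if c > 1]
        if dup:
            raise ValueError(
                f"family {fam_id}: conflicting duplicate rows for {dup}"
            )
        width = aln.width
        partitions[fam_id] = (col + 1, col + width)
        col += width
        by_genome = {row.id: row.residues for row in aln.rows}
        for g in roster:
            pieces[g].append(by_genome.get(g, GAP * width))
    rows = [
        AlignedSequence(id=g, residues="".join(pieces[g])) for g in roster
    ]
    return Alignment(rows), partitions


def trim_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and the 1-based indices (original
    coordinates) of removed columns.  Idempotent by construction.
    """
    n = aln.n_rows
    removed = [
        c
        for c in range(1, aln.width + 1)
        if sum(1 for r in aln.rows if r.is_gap(c)) / n > max_gap_fraction
    ]
    if not removed:
        return aln, []
    removed_set = set(removed)
    keep = [c for c in range(1, aln.width + 1) if c not in removed_set]
    rows = [
        AlignedSequence(
            id=r.id,
            residues="".join(r.residues[c - 1] for c in keep),
            species=r.species,
            homolog_group=r.homolog_group,
        )
        for r in aln.rows
    ]
    return Alignment(rows), removed


def remap_partitions(
    partitions: Mapping[str, tuple[int, int]],
    removed_columns: Sequence[int],
) -> dict[str, tuple[int, int]]:
    """Shift partition intervals to post-trim coordinates.

    Families whose every column was removed are dropped from the map.
    """
    removed = sorted(set(removed_columns))
    import bisect

    def new_pos(col: int) -> int:
        return col - bisect.bisect_right(removed, col)

    out: dict[str, tuple[int, int]] = {}
    removed_set = set(removed)
    for name, (start, end) in partitions.items():
        kept = [c for c in range(start, end + 1) if c not in removed_set]
        if kept:
            out[name] = (new_pos(kept[0]), new_pos(kept[-1]))
    return out


# ---------------------------------------------------------------------------
# writers for external tree inference
# ---------------------------------------------------------------------------

def write_phylip(aln: Alignment, path: Union[str, Path]) -> None:
    """Relaxed PHYLIP (full names, single block)."""
    pad = max(len(r.id) for r in aln.rows) + 2
    with open(path, "w") as fh:
        fh.write(f"{aln.n_rows} {aln.width}\n")
        for row in aln.rows:
            fh.write(f"{row.id:<{pad}}{row.residues}\n")


def write_partitions(
    partitions: Mapping[str, tuple[int, int]], path: Union[str, Path]
) -> None:
    """RAxML-style partition file: ``PROT, name = start-end`` per family."""
    with open(path, "w") as fh:
        for name, (start, end) in partitions.items():
            fh.write(f"PROT, {name} = {start}-{end}\n")


def write_supermatrix(
    aln: Alignment,
    partitions: Mapping[str, tuple[int, int]],
    prefix: Union[str, Path],
) -> None:
    """Emit <prefix>.phy, <prefix>.fasta and <prefix>.partitions."""
    prefix = Path(prefix)
    write_phylip(aln, prefix.with_suffix(".phy"))
    write_alignment(aln, prefix.with_suffix(".fasta"), format="fasta")
    write_partitions(partitions, prefix.with_suffix(".partitions"))
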