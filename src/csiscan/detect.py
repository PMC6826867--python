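"""Candidate indel scanning and flank-conservation assessment.

A conserved signature indel (CSI) is an insertion or deletion of fixed
length, at a fixed position in a protein, flanked on both sides by
conserved sequence, and uniquely shared by a monophyletic group.  This
module finds the raw material for such signatures in a protein alignment:

1. :func:`scan_candidate_indels` — maximal column blocks whose gap pattern
   bipartitions the rows into a residue-bearing set and a gap set;
2. :func:`assess_flanks` — the flank-conservation rule (at least
   ``min_conserved`` conserved columns on each side within a window of
   ``window`` columns, defaults 4 within 45);
3. :func:`extract_signature_region` — the indel plus its flanking residues
   on a reference row, the unit used for homolog screening and reporting;
4. :func:`call_csi` — the final accept/reject decision combining length
   uniformity, flank conservation and taxonomic specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import (
    AMBIGUOUS,
    GAP,
    Alignment,
    RegionSpec,
    column_to_residue,
    residue_to_column,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlankParams:
    """Tunables of the flank-conservation rule.

    ``window``
        Alignment columns examined on each side of the indel (40–50; the
        midpoint 45 is the default).
    ``min_conserved``
        Conserved columns required per side (4–5; the weaker bound 4 is the
        default).
    ``conservation_fraction``
        Minimum fraction of non-gap rows sharing the modal residue for a
        column to count as conserved.
    ``max_edge_distance``
        Minimum distance (columns) between an indel and either alignment
        terminus; closer candidates are terminal-extension artifacts.
    """

    window: int = 45
    min_conserved: int = 4
    conservation_fraction: float = 0.8
    max_edge_distance: int = 20

    def __post_init__(self) -> None:
        if not (40 <= self.window <= 50):
            raise ValueError(f"window {self.window} outside [40, 50]")
        if self.min_conserved < 1:
            raise ValueError("min_conserved must be >= 1")
        if not (0 < self.conservation_fraction <= 1):
            raise ValueError("conservation_fraction outside (0, 1]")


@dataclass(frozen=True)
class CandidateIndel:
    """A maximal gap-pattern block separating bearers from non-bearers.

    ``bearers`` are the rows carrying residues across the block where the
    ``non_bearers`` carry gaps.  Whether the bearers' state is derived
    (insertion) or ancestral (deletion) is decided later by outgroup
    polarization.  Rows that are gap across the block *and* its flanking
    window are unscorable missing data, listed in ``missing``.
    """

    start: int  # first alignment column, 1-based inclusive
    end: int  # last alignment column, 1-based inclusive
    length: int  # ungapped residue count of the block in bearer rows
    bearers: frozenset[str]
    non_bearers: frozenset[str]
    uniform_length: bool
    missing: frozenset[str] = frozenset()
    singleton: bool = False  # bearer set of size 1 or (n-1): likely artifact

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if not self.bearers:
            raise ValueError("bearer set must be non-empty")

    @property
    def column_span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class FlankAssessment:
    left_conserved: int
    right_conserved: int
    min_conserved: int

    @property
    def passed(self) -> bool:
        return (
            self.left_conserved >= self.min_conserved
            and self.right_conserved >= self.min_conserved
        )


@dataclass(frozen=True)
class SignatureWindow:
    """The extracted indel-plus-flanks slice used for screening/reporting."""

    alignment: Alignment
    region: RegionSpec  # reference ungapped coordinates of the window
    reference_id: str
    indel_columns: tuple[int, int]  # 1-based within the window alignment
    truncated: bool = False


@dataclass(frozen=True)
class Rejection:
    """A candidate that failed one or more signature criteria."""

    reasons: tuple[str, ...]
    candidate: Optional[CandidateIndel] = None


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _gap_pattern(aln: Alignment, col: int) -> frozenset[str]:
    return frozenset(r.id for r in aln.rows if r.is_gap(col))


def _all_gap_over(aln: Alignment, seq_id: str, first: int, last: int) -> bool:
    row = aln.row(seq_id)
    first = max(1, first)
    last = min(aln.width, last)
    return all(row.residues[c - 1] == GAP for c in range(first, last + 1))


def scan_candidate_indels(
    aln: Alignment, params: FlankParams = FlankParams()
) -> list[CandidateIndel]:
    """Find every maximal gap-pattern block that bipartitions the rows.

    A block is a maximal run of consecutive columns sharing an identical,
    non-trivial gap pattern (some rows gapped, some not).  Blocks closer
    than ``params.max_edge_distance`` columns to either terminus are
    excluded and logged.  Blocks whose boundary is ragged — an adjacent
    column where a subset or superset of the same rows is gapped, i.e.
    bearers of unequal indel lengths — are flagged ``uniform_length=False``
    rather than split.  Results are keyed by column span and independent of
    row order.
    """
    if aln.n_rows < 4:
        raise ValueError(
            f"alignment has {aln.n_rows} rows; need >= 4 for a meaningful "
            "bearer/non-bearer contrast"
        )
    n = aln.n_rows
    patterns = [_gap_pattern(aln, c) for c in range(1, aln.width + 1)]

    # maximal runs of identical patterns
    runs: list[tuple[int, int, frozenset[str]]] = []
    start = 1
    for c in range(2, aln.width + 2):
        if c > aln.width or patterns[c - 1] != patterns[start - 1]:
            runs.append((start, c - 1, patterns[start - 1]))
            start = c

    out: list[CandidateIndel] = []
    for i, (first, last, pat) in enumerate(runs):
        if not pat or len(pat) == n:
            continue
        if (
            first <= params.max_edge_distance
            or aln.width - last < params.max_edge_distance
        ):
            logger.info(
                "candidate at columns %d..%d excluded: within %d columns "
                "of an alignment terminus",
                first, last, params.max_edge_distance,
            )
            continue

        missing = frozenset(
            s
            for s in pat
            if _all_gap_over(
                aln, s, first - params.window, last + params.window
            )
        )
        non_bearers = pat - missing
        if not non_bearers:
            # every gapped row is missing data: no contrast to score
            continue
        bearers = frozenset(aln.ids) - pat

        # ragged boundary: an adjacent run whose gap set overlaps this one
        # means some rows carry a longer/shorter gap than others
        uniform = True
        for j in (i - 1, i + 1):
            if 0 <= j < len(runs):
                neighbour = runs[j][2]
                if neighbour and neighbour != pat and (neighbour & pat):
                    uniform = False
        out.append(
            CandidateIndel(
                start=first,
                end=last,
                length=last - first + 1,
                bearers=bearers,
                non_bearers=non_bearers,
                uniform_length=uniform,
                missing=missing,
                singleton=len(bearers) == 1 or len(non_bearers) == 1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# flank conservation
# ---------------------------------------------------------------------------

def column_is_conserved(
    aln: Alignment,
    col: int,
    conservation_fraction: float,
    exclude: frozenset[str] = frozenset(),
) -> bool:
    """Modal non-ambiguous residue shared by >= fraction of non-gap rows.

    Columns gapped in half or more of the rows never count; ambiguity codes
    (X/B/Z) never contribute to the modal count.
    """
    cells = [
        r.residues[col - 1] for r in aln.rows if r.id not in exclude
    ]
    n = len(cells)
    residues = [c for c in cells if c != GAP]
    if n == 0 or len(residues) * 2 <= n:
        # gapped in at least half the rows
        return False
    counts: dict[str, int] = {}
    for c in residues:
        if c not in AMBIGUOUS:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return False
    modal = max(counts.values())
    return modal >= conservation_fraction * len(residues)


def _majority_non_gap(aln: Alignment, col: int, exclude: frozenset[str]) -> bool:
    cells = [r.residues[col - 1] for r in aln.rows if r.id not in exclude]
    gaps = sum(1 for c in cells if c == GAP)
    return gaps * 2 < len(cells)


def assess_flanks(
    aln: Alignment,
    cand: CandidateIndel,
    params: FlankParams = FlankParams(),
) -> FlankAssessment:
    """Count conserved columns on each side of the candidate block.

    On each side, the nearest ``params.window`` columns that are non-gap in
    the majority of (non-missing) rows are examined, moving outward from
    the block edge; fewer may be available near a terminus.
    """
    if not (1 <= cand.start <= cand.end <= aln.width):
        raise ValueError(
            f"candidate span {cand.start}..{cand.end} outside alignment "
            f"of width {aln.width}"
        )
    exclude = cand.missing

    def count_side(cols: Sequence[int]) -> int:
        examined = 0
        conserved = 0
        for col in cols:
            if not _majority_non_gap(aln, col, exclude):
                continue
            examined += 1
            if column_is_conserved(
                aln, col, params.conservation_fraction, exclude
            ):
                conserved += 1
            if examined >= params.window:
                break
        return conserved

    left = count_side(range(cand.start - 1, 0, -1))
    right = count_side(range(cand.end + 1, aln.width + 1))
    return FlankAssessment(
        left_conserved=left,
        right_conserved=right,
        min_conserved=params.min_conserved,
    )


# ---------------------------------------------------------------------------
# signature window extraction
# ---------------------------------------------------------------------------

def extract_signature_region(
    aln: Alignment,
    cand: CandidateIndel,
    flank_residues: int = 45,
    reference_id: Optional[str] = None,
) -> SignatureWindow:
    """Slice out the indel plus ``flank_residues`` residues of the reference.

    The reference row defaults to the first bearer in row order (bearers
    are guaranteed to carry residues across the block).  The returned
    :class:`~csiscan.alignment.RegionSpec` is in ungapped reference
    coordinates — the "indel position" range quoted in signature tables.
    """
    if reference_id is None:
        reference_id = next(r.id for r in aln.rows if r.id in cand.bearers)
    elif reference_id not in aln.ids:
        raise KeyError(f"reference row {reference_id!r} absent")

    ref = aln.row(reference_id)
    start_res = column_to_residue(aln, reference_id, cand.start)
    end_res = column_to_residue(aln, reference_id, cand.end)
    if start_res is None or end_res is None:
        raise ValueError(
            f"reference row {reference_id!r} is gapped inside the candidate "
            "block; choose a bearer row"
        )

    truncated = False
    win_start = start_res - flank_residues
    if win_start < 1:
        win_start, truncated = 1, True
    win_end = end_res + flank_residues
    if win_end > ref.ungapped_length:
        win_end, truncated = ref.ungapped_length, True

    first_col = residue_to_column(aln, reference_id, win_start)
    last_col = residue_to_column(aln, reference_id, win_end)
    sub = aln.slice_columns(first_col, last_col)
    sub, _removed = sub.drop_all_gap_columns()

    # candidate block position inside the (possibly re-normalized) window
    offset = sum(
        1
        for c in range(first_col, cand.start)
        if not all(r.is_gap(c) for r in aln.rows)
    )
    span_width = cand.end - cand.start + 1
    return SignatureWindow(
        alignment=sub,
        region=RegionSpec(seq_id=reference_id, start=win_start, end=win_end),
        reference_id=reference_id,
        indel_columns=(offset + 1, offset + span_width),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# the final call
# ---------------------------------------------------------------------------

def call_csi(
    cand: CandidateIndel,
    flanks: FlankAssessment,
    specificity,  # taxonomy.SpecificityCall
    meta: Optional[dict] = None,
    polarity=None,  # taxonomy.Polarity
    region: Optional[RegionSpec] = None,
):
    """Accept a candidate as a CSI record or reject it with reasons.

    Acceptance requires uniform length across bearers, the flank rule, and
    a named specificity clade.  The function is total: it never raises on a
    failing candidate, it enumerates every failed criterion instead.
    """
    from .report import CSIRecord  # deferred: report depends on this module's types

    meta = meta or {}
    reasons: list[str] = []
    if not cand.uniform_length:
        reasons.append("non-uniform length")
    if not flanks.passed:
        reasons.append(
            "flank conservation "
            f"(left={flanks.left_conserved}, right={flanks.right_conserved}, "
            f"required={flanks.min_conserved} per side)"
        )
    if specificity is None or specificity.clade in (None, "", "none"):
        reasons.append("no named specificity clade")
    if reasons:
        return Rejection(reasons=tuple(reasons), candidate=cand)

    indel_type = "ambiguous"
    if polarity is not None:
        indel_type = {
            "insertion": "ins",
            "deletion": "del",
            "ambiguous": "ambiguous",
        }[polarity.state]
    flags = []
    if cand.singleton:
        flags.append("single-sequence")
    if specificity.exceptions:
        flags.append("exceptions")
    if meta.get("paralog_restricted"):
        flags.append("paralog-restricted")
    return CSIRecord(
        protein_name=meta.get("protein_name", ""),
        gene_name=meta.get("gene_name", ""),
        accession=meta.get("accession", ""),
        indel_size=cand.length,
        indel_type=indel_type,
        region=region,
        specificity=specificity,
        flags=tuple(flags),
        missing=tuple(sorted(cand.missing)),
    )
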