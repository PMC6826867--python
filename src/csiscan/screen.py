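"""Second-pass homolog screening of signature windows.

After a candidate signature is extracted, every homolog that a database
search returned is checked for presence or absence of the indel: hits are
filtered on E-value and search depth, each hit is aligned to the ungapped
signature window with a semi-global affine-gap dynamic-programming
aligner (the window is aligned globally, end gaps on the hit are free —
signature windows are short fragments of long subject sequences), and the
gap placement at the indel region decides the per-hit call.

E-values are taken from the BLAST tabular input and never recomputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Align import substitution_matrices

from .alignment import GAP

NEG = float("-inf")

#: Hard ceiling on screening depth.
MAX_TOP_N = 500


@dataclass(frozen=True)
class HitRecord:
    """One database hit: identifier, optional species, E-value, sequence."""

    hit_id: str
    e_value: float
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not self.sequence:
            raise ValueError("hit sequence must be non-empty")


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap costs.

    A gap of length *k* costs ``-(gap_open + k * gap_extend)`` — the
    convention of BLAST's default protein scoring (BLOSUM62, 11/1).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return _matrix_dict(self.matrix_name)[(a, b)]


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=4)
def _matrix_dict(name: str) -> dict[tuple[str, str], float]:
    mat = _load_matrix(name)
    alphabet = mat.alphabet
    out = {}
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            out[(a, b)] = float(mat[i, j])
    return out


@dataclass(frozen=True)
class PairwiseAlignment:
    """Result of aligning a signature window against one hit."""

    score: float
    aligned_window: str  # full window, '-' where hit residues are inserted
    aligned_hit: str  # matched hit substring, '-' where window residues are unmatched
    hit_start: int  # 0-based offset of the first aligned hit residue
    hit_end: int  # 0-based exclusive end


@dataclass
class ScreenResult:
    calls: dict[str, str]  # hit_id -> has_indel | lacks_indel | ambiguous
    scores: dict[str, float]
    verdict: str  # uniquely_shared | not_specific | insufficient_data
    intruders: tuple[str, ...] = ()
    in_clade_missing: tuple[str, ...] = ()

    @property
    def n_has(self) -> int:
        return sum(1 for v in self.calls.values() if v == "has_indel")

    @property
    def n_lacks(self) -> int:
        return sum(1 for v in self.calls.values() if v == "lacks_indel")

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for v in self.calls.values() if v == "ambiguous")


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Sequence[HitRecord],
    e_max: float = 1e-20,
    top_n: int = 250,
) -> list[HitRecord]:
    """Keep hits with E-value strictly below *e_max*, best first, truncated
    to *top_n* (hard ceiling 500); ties broken by hit_id for stability."""
    top_n = min(top_n, MAX_TOP_N)
    kept = [h for h in hits if h.e_value < e_max]
    kept.sort(key=lambda h: (h.e_value, h.hit_id))
    return kept[:top_n]


def read_blast_tab(path: Union[str, Path]) -> dict[str, float]:
    """Read a BLAST outfmt-6 TSV, returning subject id -> best E-value.

    Standard column order: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore.
    """
    best: dict[str, float] = {}
    with open(path, newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or rec[0].startswith("#"):
                continue
            sseqid, evalue = rec[1], float(rec[10])
            if sseqid not in best or evalue < best[sseqid]:
                best[sseqid] = evalue
    return best


def read_hits(
    tab_path: Union[str, Path],
    fasta_path: Union[str, Path],
) -> list[HitRecord]:
    """Pair a BLAST tabular hit list with its hit sequences.

    Hit FASTA headers may carry species as ``id|species`` (underscores in
    species read as spaces).  Hits present in only one of the two files
    are dropped.
    """
    evalues = read_blast_tab(tab_path)
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = (rec.description or rec.id).split("|")
        hit_id = parts[0].strip()
        species = parts[1].strip().replace("_", " ") if len(parts) > 1 else ""
        if hit_id in evalues:
            out.append(
                HitRecord(
                    hit_id=hit_id,
                    species=species,
                    e_value=evalues[hit_id],
                    sequence=str(rec.seq).upper().replace("-", ""),
                )
            )
    return out


# ---------------------------------------------------------------------------
# the aligner
# ---------------------------------------------------------------------------

def align_signature(
    window_seq: str,
    hit_seq: str,
    scoring: Scoring = Scoring(),
) -> PairwiseAlignment:
    """Optimal semi-global affine-gap alignment (Gotoh three-state DP).

    The full *window_seq* is aligned against the best-scoring substring of
    *hit_seq*: end gaps on the hit cost nothing, internal gaps cost
    ``gap_open + k * gap_extend``.  Tie-break is deterministic — prefer a
    substitution over a gap, prefer consuming the hit from the left.
    """
    if not window_seq or not hit_seq:
        raise ValueError("both sequences must be non-empty")
    a = window_seq.upper()
    b = hit_seq.upper()
    m, n = len(a), len(b)
    sub = _matrix_dict(scoring.matrix_name)
    open_cost = -(scoring.gap_open + scoring.gap_extend)  # first gap column
    ext_cost = -scoring.gap_extend

    # state matrices: M diagonal, X window-vs-gap (gap in hit),
    # Y hit-vs-gap (gap in window)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0  # free leading hit overhang
    for i in range(1, m + 1):
        X[i][0] = (open_cost if i == 1 else X[i - 1][0] + ext_cost)
        for j in range(0, n + 1):
            if j > 0:
                s = sub[(a[i - 1], b[j - 1])]
                M[i][j] = s + max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
                )
                Y[i][j] = max(
                    M[i][j - 1] + open_cost,
                    Y[i][j - 1] + ext_cost,
                    X[i][j - 1] + open_cost,
                )
            if j > 0 or i > 1:
                X[i][j] = max(
                    M[i - 1][j] + open_cost,
                    X[i - 1][j] + ext_cost,
                    Y[i - 1][j] + open_cost,
                )

    # best end: window fully consumed, trailing hit overhang free; smallest
    # end offset wins ties (leftmost placement)
    best_j, best_state, best = 0, "M", NEG
    for j in range(n + 1):
        for state, val in (("M", M[m][j]), ("X", X[m][j])):
            if val > best:
                best, best_j, best_state = val, j, state

    # traceback
    aw: list[str] = []
    ah: list[str] = []
    i, j, state = m, best_j, best_state
    hit_end = best_j
    tol = 1e-9
    while i > 0:
        if state == "M":
            s = sub[(a[i - 1], b[j - 1])]
            prev = M[i][j] - s
            if i == 1:
                nxt = "M"  # M[0][j-1] == 0 start
            elif abs(M[i - 1][j - 1] - prev) < tol:
                nxt = "M"
            elif abs(X[i - 1][j - 1] - prev) < tol:
                nxt = "X"
            else:
                nxt = "Y"
            aw.append(a[i - 1])
            ah.append(b[j - 1])
            i, j, state = i - 1, j - 1, nxt
        elif state == "X":
            if abs(X[i][j] - (M[i - 1][j] + open_cost)) < tol:
                nxt = "M"
            elif i > 1 and abs(X[i][j] - (X[i - 1][j] + ext_cost)) < tol:
                nxt = "X"
            else:
                nxt = "Y"
            aw.append(a[i - 1])
            ah.append(GAP)
            i, state = i - 1, nxt
        else:  # Y
            if abs(Y[i][j] - (M[i][j - 1] + open_cost)) < tol:
                nxt = "M"
            elif abs(Y[i][j] - (Y[i][j - 1] + ext_cost)) < tol:
                nxt = "Y"
            else:
                nxt = "X"
            aw.append(GAP)
            ah.append(b[j - 1])
            j, state = j - 1, nxt
    hit_start = j
    return PairwiseAlignment(
        score=best,
        aligned_window="".join(reversed(aw)),
        aligned_hit="".join(reversed(ah)),
        hit_start=hit_start,
        hit_end=hit_end,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned pairs over the shorter ungapped length."""
    if not seq_a or not seq_b:
        return 0.0
    window, other = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    aln = align_signature(window, other)
    matches = sum(
        1
        for x, y in zip(aln.aligned_window, aln.aligned_hit)
        if x == y and x != GAP
    )
    return matches / min(len(seq_a), len(seq_b))


# ---------------------------------------------------------------------------
# per-hit classification
# ---------------------------------------------------------------------------

def _region_columns(aln: PairwiseAlignment, start: int, end: int) -> list[int]:
    """Alignment columns (0-based) of window residues start..end (1-based)."""
    cols = []
    res = 0
    for k, c in enumerate(aln.aligned_window):
        if c != GAP:
            res += 1
            if start <= res <= end:
                cols.append(k)
    return cols


def classify_hit(
    alignment: PairwiseAlignment,
    indel_start: int,
    indel_end: int,
    indel_type: str,
    slack: int = 3,
    flank_identity_floor: float = 0.30,
) -> str:
    """Call one hit: has_indel / lacks_indel / ambiguous.

    *indel_start..indel_end* are 1-based residue positions of the indel
    block on the (residue-bearing) window sequence.  For an insertion-type
    signature a hit *has* the indel when it aligns residues across the
    whole block and *lacks* it when a contiguous hit gap covers the block
    (within *slack* columns of drift); the mapping is inverted for
    deletion-type signatures.  Straddling gap placement, flank identity
    below the floor, or the block falling into an unaligned hit overhang
    all yield ``ambiguous``.
    """
    if indel_type not in ("ins", "del"):
        raise ValueError(f"indel_type must be 'ins' or 'del', got {indel_type!r}")
    cols = _region_columns(alignment, indel_start, indel_end)
    if not cols:
        return "ambiguous"
    width = indel_end - indel_start + 1

    # flank identity outside the region
    region = set(cols)
    matches = compared = 0
    for k, (x, y) in enumerate(zip(alignment.aligned_window, alignment.aligned_hit)):
        if k in region or x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0 or matches / compared < flank_identity_floor:
        return "ambiguous"

    hit_row = alignment.aligned_hit
    gaps_in_region = sum(1 for k in cols if hit_row[k] == GAP)

    if gaps_in_region == 0:
        state = "residues"
    else:
        # maximal contiguous hit-gap run overlapping the region
        k0 = next(k for k in cols if hit_row[k] == GAP)
        run_start = k0
        while run_start > 0 and hit_row[run_start - 1] == GAP:
            run_start -= 1
        run_end = k0
        while run_end + 1 < len(hit_row) and hit_row[run_end + 1] == GAP:
            run_end += 1
        run_len = run_end - run_start + 1
        covers = run_start <= cols[0] + slack and run_end >= cols[-1] - slack
        aligned_block = run_len == width and covers
        within = (
            abs(run_start - cols[0]) <= slack
            and abs(run_end - cols[-1]) <= slack
        )
        state = "gap" if (aligned_block and within) else "partial"

    if state == "partial":
        return "ambiguous"
    if indel_type == "ins":
        return "has_indel" if state == "residues" else "lacks_indel"
    return "has_indel" if state == "gap" else "lacks_indel"


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenParams:
    e_max: float = 1e-20
    top_n: int = 250
    scoring: Scoring = field(default_factory=Scoring)
    slack: int = 3
    flank_identity_floor: float = 0.30


def screen_hits(
    window_seq: str,
    indel_start: int,
    indel_end: int,
    indel_type: str,
    hits: Sequence[HitRecord],
    in_clade_species: Iterable[str] = (),
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Filter, align and classify a hit set against one signature window.

    The verdict is ``uniquely_shared`` iff every screened in-clade hit has
    the indel and no out-of-clade hit does; ``insufficient_data`` when the
    filter leaves nothing to screen.
    """
    in_clade = set(in_clade_species)
    kept = filter_hits(hits, e_max=params.e_max, top_n=params.top_n)
    if not kept:
        return ScreenResult(
            calls={}, scores={}, verdict="insufficient_data"
        )
    calls: dict[str, str] = {}
    scores: dict[str, float] = {}
    for hit in kept:
        aln = align_signature(window_seq, hit.sequence, params.scoring)
        calls[hit.hit_id] = classify_hit(
            aln,
            indel_start,
            indel_end,
            indel_type,
            slack=params.slack,
            flank_identity_floor=params.flank_identity_floor,
        )
        scores[hit.hit_id] = aln.score

    intruders = tuple(
        sorted(
            h.hit_id
            for h in kept
            if h.species not in in_clade and calls[h.hit_id] == "has_indel"
        )
    )
    in_missing = tuple(
        sorted(
            h.hit_id
            for h in kept
            if h.species in in_clade and calls[h.hit_id] == "lacks_indel"
        )
    )
    verdict = "uniquely_shared" if not intruders and not in_missing else "not_specific"
    return ScreenResult(
        calls=calls,
        scores=scores,
        verdict=verdict,
        intruders=intruders,
        in_clade_missing=in_missing,
    )
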