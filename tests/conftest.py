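"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results from first principles
(interval enumeration, exhaustive alignment enumeration, tree-walking
LCA) so that the production implementations are checked against code that
shares none of their structure.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from csiscan.alignment import GAP, AlignedSequence, Alignment
from csiscan.detect import CandidateIndel, FlankParams
from csiscan.simulate import default_taxonomy

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


def make_alignment(rows: list[tuple[str, str]], species=None) -> Alignment:
    """Build an Alignment from (id, residues) pairs; species defaults to id."""
    species = species or {}
    return Alignment(
        [
            AlignedSequence(
                id=rid, residues=res, species=species.get(rid, rid)
            )
            for rid, res in rows
        ]
    )


def random_gapped_alignment(
    rng: random.Random,
    n_rows: int,
    base_length: int,
    n_events: int,
) -> Alignment:
    """Random alignment built from planted indel events.

    Starts from an ungapped matrix of random residues with a few conserved
    columns, then applies events that either delete a span from a row
    subset or insert a span present only in a row subset — the generative
    process that real alignment gap patterns come from.
    """
    cols = [
        [rng.choice(AA) for _ in range(n_rows)] for _ in range(base_length)
    ]
    # a sprinkling of conserved columns
    for c in rng.sample(range(base_length), k=base_length // 4):
        residue = rng.choice(AA)
        cols[c] = [residue] * n_rows
    for _ in range(n_events):
        span = rng.randint(1, 4)
        subset = rng.sample(range(n_rows), k=rng.randint(1, n_rows - 1))
        if rng.random() < 0.5:  # deletion: subset loses an existing span
            start = rng.randint(0, len(cols) - span)
            for c in range(start, start + span):
                for r in subset:
                    cols[c][r] = GAP
        else:  # insertion: new columns carried only by the subset
            at = rng.randint(0, len(cols))
            new = [
                [
                    rng.choice(AA) if r in subset else GAP
                    for r in range(n_rows)
                ]
                for _ in range(span)
            ]
            cols[at:at] = new
    rows = []
    for r in range(n_rows):
        residues = "".join(col[r] for col in cols)
        if all(c == GAP for c in residues):
            residues = rng.choice(AA) + residues[1:]
        rows.append(AlignedSequence(id=f"r{r + 1}", residues=residues, species=f"r{r + 1}"))
    aln = Alignment(rows)
    aln, _ = aln.drop_all_gap_columns()
    return aln


# ---------------------------------------------------------------------------
# oracle: candidate-indel enumeration by interval scanning
# ---------------------------------------------------------------------------

def brute_force_candidates(
    aln: Alignment, params: FlankParams
) -> list[CandidateIndel]:
    """Independent enumerator: for every start column, grow the largest
    interval with a constant gap pattern and test the candidate conditions
    directly from their definitions."""
    width = aln.width
    ids = aln.ids
    patterns = [
        frozenset(r.id for r in aln.rows if r.is_gap(c))
        for c in range(1, width + 1)
    ]
    out = []
    for a in range(1, width + 1):
        pat = patterns[a - 1]
        if not pat or len(pat) == len(ids):
            continue
        if a > 1 and patterns[a - 2] == pat:
            continue  # not left-maximal
        b = a
        while b < width and patterns[b] == pat:
            b += 1
        # edge exclusion
        if a <= params.max_edge_distance or width - b < params.max_edge_distance:
            continue
        # missing rows: gap across the block and its +/- window neighbourhood
        lo = max(1, a - params.window)
        hi = min(width, b + params.window)
        missing = frozenset(
            s
            for s in pat
            if all(aln.row(s).residues[c - 1] == GAP for c in range(lo, hi + 1))
        )
        non_bearers = pat - missing
        if not non_bearers:
            continue
        bearers = frozenset(ids) - pat
        uniform = True
        for adj in (a - 1, b + 1):
            if 1 <= adj <= width:
                q = patterns[adj - 1]
                if q and q != pat and q & pat:
                    uniform = False
        out.append(
            CandidateIndel(
                start=a,
                end=b,
                length=b - a + 1,
                bearers=bearers,
                non_bearers=non_bearers,
                uniform_length=uniform,
                missing=missing,
                singleton=len(bearers) == 1 or len(non_bearers) == 1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive semi-global affine alignment enumeration
# ---------------------------------------------------------------------------

def exhaustive_best_score(
    a: str,
    b: str,
    sub: dict,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Best semi-global affine score by enumerating every alignment.

    Plain recursion over alignment moves (no memoisation): the window *a*
    must be fully consumed; hit *b* residues before the first and after
    the last aligned column are free.  A gap run of length k costs
    ``gap_open + k * gap_extend``.
    """
    m, n = len(a), len(b)
    first_col = -(gap_open + gap_extend)
    ext = -gap_extend

    def rec(i: int, j: int, state: str) -> float:
        if i == m:
            return 0.0  # trailing hit residues free
        best = float("-inf")
        if state == "start":
            # free leading skip of the hit
            if j < n:
                best = max(best, rec(i, j + 1, "start"))
        if j < n:
            best = max(
                best, sub[(a[i], b[j])] + rec(i + 1, j + 1, "M")
            )
            if state in ("M", "Xrun", "start"):
                best = max(best, first_col + rec(i, j + 1, "Yrun"))
            if state == "Yrun":
                best = max(best, ext + rec(i, j + 1, "Yrun"))
        cost = ext if state == "Xrun" else first_col
        best = max(best, cost + rec(i + 1, j, "Xrun"))
        return best

    return rec(0, 0, "start")


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))
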