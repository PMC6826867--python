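"""Candidate scanning, flank conservation and the signature call."""

import random

import pytest

from csiscan.alignment import GAP, AlignedSequence, Alignment
from csiscan.detect import (
    CandidateIndel,
    FlankAssessment,
    FlankParams,
    Rejection,
    assess_flanks,
    call_csi,
    extract_signature_region,
    scan_candidate_indels,
)
from csiscan.taxonomy import Polarity, SpecificityCall

from conftest import AA, brute_force_candidates, random_gapped_alignment

PARAMS = FlankParams()


def conserved_backbone(width: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(AA) for _ in range(width))


def toy_insertion_alignment() -> Alignment:
    """Six rows; rows 1-3 carry 2 extra residues at columns 50-51."""
    base = conserved_backbone(118)
    rows = []
    for i in range(1, 7):
        block = "WW" if i <= 3 else "--"
        rows.append(
            AlignedSequence(
                id=f"r{i}", residues=base[:49] + block + base[49:],
                species=f"sp{i}",
            )
        )
    return Alignment(rows)


class TestScan:
    def test_gap_free_alignment_yields_nothing(self):
        base = conserved_backbone(120)
        aln = Alignment(
            [AlignedSequence(id=f"r{i}", residues=base) for i in range(1, 5)]
        )
        assert scan_candidate_indels(aln, PARAMS) == []

    def test_toy_insertion_found_once(self):
        cands = scan_candidate_indels(toy_insertion_alignment(), PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.column_span == (50, 51)
        assert c.length == 2
        assert c.bearers == {"r1", "r2", "r3"}
        assert c.non_bearers == {"r4", "r5", "r6"}
        assert c.uniform_length and not c.singleton

    def test_candidates_near_termini_excluded(self):
        base = conserved_backbone(118)
        rows = [
            AlignedSequence(
                id=f"r{i}",
                residues=("--" if i <= 2 else "WW") + base[:116],
            )
            for i in range(1, 7)
        ]
        assert scan_candidate_indels(Alignment(rows), PARAMS) == []

    def test_ragged_block_flagged_non_uniform(self):
        """Bearers of unequal gap lengths make one non-uniform candidate
        pattern instead of two independent signatures."""
        base = conserved_backbone(117)
        rows = []
        for i in range(1, 7):
            if i <= 3:
                block = "WWV"
            elif i <= 5:
                block = "--V"  # 2-residue gap
            else:
                block = "---"  # 3-residue gap
            rows.append(
                AlignedSequence(id=f"r{i}", residues=base[:50] + block + base[50:])
            )
        cands = scan_candidate_indels(Alignment(rows), PARAMS)
        assert cands and all(not c.uniform_length for c in cands)

    def test_row_order_invariance(self):
        aln = toy_insertion_alignment()
        shuffled = Alignment(list(reversed(aln.rows)))
        a = scan_candidate_indels(aln, PARAMS)
        b = scan_candidate_indels(shuffled, PARAMS)
        assert [(c.column_span, c.bearers) for c in a] == [
            (c.column_span, c.bearers) for c in b
        ]

    def test_fewer_than_four_rows_rejected(self):
        aln = Alignment(
            [AlignedSequence(id=f"r{i}", residues="ACDE") for i in range(1, 4)]
        )
        with pytest.raises(ValueError):
            scan_candidate_indels(aln, PARAMS)

    def test_matches_interval_enumeration_oracle(self):
        """Production scanner agrees with the independent interval
        enumerator on generatively gapped random alignments."""
        rng = random.Random(7)
        for _ in range(60):
            aln = random_gapped_alignment(
                rng, n_rows=rng.randint(4, 8), base_length=120,
                n_events=rng.randint(0, 6),
            )
            got = scan_candidate_indels(aln, PARAMS)
            want = brute_force_candidates(aln, PARAMS)
            assert got == want


class TestFlanks:
    def _alignment_with_block(self, left_cons: int, right_cons: int):
        """Rows identical only in the stated numbers of flank columns."""
        rng = random.Random(3)
        width = 120
        n = 6
        block = (56, 57)
        cons_cols = set(
            list(range(block[0] - left_cons, block[0]))
            + list(range(block[1] + 1, block[1] + 1 + right_cons))
        )
        cols = []
        for c in range(1, width + 1):
            if block[0] <= c <= block[1]:
                cols.append(["W" if r < 3 else GAP for r in range(n)])
            elif c in cons_cols:
                cols.append(["L"] * n)
            else:
                # every row different: never conserved at fraction 0.8
                cols.append([AA[(c + r * 3) % 20] for r in range(n)])
        rows = [
            AlignedSequence(id=f"r{r + 1}", residues="".join(col[r] for col in cols))
            for r in range(n)
        ]
        aln = Alignment(rows)
        cand = scan_candidate_indels(aln, PARAMS)[0]
        return aln, cand

    def test_three_conserved_per_side_fails_at_four(self):
        aln, cand = self._alignment_with_block(3, 3)
        fa = assess_flanks(aln, cand, PARAMS)
        assert (fa.left_conserved, fa.right_conserved) == (3, 3)
        assert not fa.passed

    def test_four_conserved_per_side_passes(self):
        aln, cand = self._alignment_with_block(4, 5)
        fa = assess_flanks(aln, cand, PARAMS)
        assert fa.left_conserved == 4 and fa.right_conserved == 5
        assert fa.passed

    def test_identical_rows_give_full_window(self):
        base = conserved_backbone(118)
        rows = [
            AlignedSequence(
                id=f"r{i}",
                residues=base[:59] + ("WW" if i <= 3 else "--") + base[59:],
            )
            for i in range(1, 7)
        ]
        aln = Alignment(rows)
        cand = scan_candidate_indels(aln, PARAMS)[0]
        fa = assess_flanks(aln, cand, PARAMS)
        assert fa.left_conserved == fa.right_conserved == PARAMS.window
        assert fa.passed

    def test_truncated_side_counts_available_columns_only(self):
        """A candidate near the terminus can only accumulate as many
        conserved columns as exist, and fails when fewer than required."""
        base = conserved_backbone(200)
        rows = [
            AlignedSequence(
                id=f"r{i}",
                residues=base[:190] + ("WW" if i <= 3 else "--") + base[190:198],
            )
            for i in range(1, 7)
        ]
        aln = Alignment(rows)
        cand = CandidateIndel(
            start=191, end=192, length=2,
            bearers=frozenset({"r1", "r2", "r3"}),
            non_bearers=frozenset({"r4", "r5", "r6"}),
            uniform_length=True,
        )
        fa = assess_flanks(aln, cand, FlankParams(min_conserved=5, window=45))
        assert fa.right_conserved <= 8
        params3 = FlankParams(window=45, min_conserved=4)
        short = CandidateIndel(
            start=196, end=197, length=2,
            bearers=frozenset({"r1"}), non_bearers=frozenset({"r2"}),
            uniform_length=True,
        )
        fa2 = assess_flanks(aln, short, params3)
        assert fa2.right_conserved <= 3 and not (
            fa2.right_conserved >= params3.min_conserved
        )

    def test_span_outside_alignment_rejected(self):
        aln, cand = self._alignment_with_block(4, 4)
        bad = CandidateIndel(
            start=500, end=501, length=2,
            bearers=cand.bearers, non_bearers=cand.non_bearers,
            uniform_length=True,
        )
        with pytest.raises(ValueError):
            assess_flanks(aln, bad, PARAMS)

    def test_threshold_monotonicity(self):
        """Raising min_conserved or conservation_fraction never passes a
        candidate that failed at the weaker setting."""
        rng = random.Random(11)
        for _ in range(20):
            aln = random_gapped_alignment(rng, 6, 120, rng.randint(1, 4))
            for cand in scan_candidate_indels(aln, PARAMS):
                weak = assess_flanks(aln, cand, FlankParams(
                    min_conserved=4, conservation_fraction=0.7))
                strong = assess_flanks(aln, cand, FlankParams(
                    min_conserved=5, conservation_fraction=0.9))
                if strong.passed:
                    assert weak.passed


class TestExtractAndCall:
    def test_region_brackets_the_indel(self):
        aln = toy_insertion_alignment()
        cand = scan_candidate_indels(aln, PARAMS)[0]
        win = extract_signature_region(aln, cand, flank_residues=24)
        assert win.reference_id == "r1"
        # reference has 120 residues; indel at residues 50-51
        assert win.region.start == 50 - 24 and win.region.end == 51 + 24
        assert win.region.start < 50 <= 51 < win.region.end

    def test_window_truncated_near_start_is_flagged(self):
        base = conserved_backbone(118)
        rows = [
            AlignedSequence(
                id=f"r{i}",
                residues=base[:25] + ("WW" if i <= 3 else "--") + base[25:],
            )
            for i in range(1, 7)
        ]
        aln = Alignment(rows)
        cand = scan_candidate_indels(aln, PARAMS)[0]
        win = extract_signature_region(aln, cand, flank_residues=45)
        assert win.truncated and win.region.start == 1

    def test_locality_rescanning_the_window_finds_same_indel(self):
        rng = random.Random(5)
        found = 0
        for _ in range(30):
            aln = random_gapped_alignment(rng, 6, 150, rng.randint(1, 5))
            for cand in scan_candidate_indels(aln, PARAMS):
                win = extract_signature_region(aln, cand, flank_residues=45)
                inner = scan_candidate_indels(
                    win.alignment,
                    FlankParams(max_edge_distance=1),
                )
                spans = {
                    (c.length, c.bearers) for c in inner
                }
                assert (cand.length, cand.bearers & frozenset(win.alignment.ids)) in {
                    (c.length, c.bearers) for c in inner
                }
                found += 1
        assert found > 0

    def test_missing_reference_rejected(self):
        aln = toy_insertion_alignment()
        cand = scan_candidate_indels(aln, PARAMS)[0]
        with pytest.raises(KeyError):
            extract_signature_region(aln, cand, reference_id="nope")

    def _uniform_candidate(self):
        return CandidateIndel(
            start=50, end=54, length=5,
            bearers=frozenset({"r1", "r2"}),
            non_bearers=frozenset({"r3", "r4"}),
            uniform_length=True,
        )

    def test_call_accepts_good_candidate(self):
        spec = SpecificityCall(clade="Caenorhabditis", bearers=frozenset({"a"}))
        flanks = FlankAssessment(5, 6, min_conserved=4)
        rec = call_csi(
            self._uniform_candidate(), flanks, spec,
            meta={"gene_name": "parg-1"},
            polarity=Polarity(state="insertion", outgroup_support=3),
        )
        assert not isinstance(rec, Rejection)
        assert rec.indel_label == "5 aa ins"
        assert rec.specificity.clade == "Caenorhabditis"

    def test_call_rejects_failed_flanks_with_reason(self):
        spec = SpecificityCall(clade="Caenorhabditis", bearers=frozenset({"a"}))
        out = call_csi(
            self._uniform_candidate(),
            FlankAssessment(3, 6, min_conserved=4),
            spec,
        )
        assert isinstance(out, Rejection)
        assert any("flank conservation" in r for r in out.reasons)

    def test_call_rejects_non_uniform_candidate(self):
        cand = CandidateIndel(
            start=50, end=54, length=5,
            bearers=frozenset({"r1"}), non_bearers=frozenset({"r3"}),
            uniform_length=False,
        )
        out = call_csi(
            cand,
            FlankAssessment(6, 6, min_conserved=4),
            SpecificityCall(clade="none", bearers=frozenset()),
        )
        assert isinstance(out, Rejection)
        assert "non-uniform length" in out.reasons
        assert "no named specificity clade" in out.reasons


def test_flank_params_validation():
    with pytest.raises(ValueError):
        FlankParams(window=39)
    with pytest.raises(ValueError):
        FlankParams(window=51)
    with pytest.raises(ValueError):
        FlankParams(conservation_fraction=0.0)
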