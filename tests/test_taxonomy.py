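"""Clade calls, paralog handling and indel polarization."""

import random

import dendropy
import pytest

from csiscan.alignment import AlignedSequence, Alignment
from csiscan.detect import CandidateIndel
from csiscan.simulate import default_sim_tree, default_taxonomy
from csiscan.taxonomy import (
    Polarity,
    TaxonomyTree,
    UnresolvableSpeciesError,
    evaluate_specificity,
    partition_homolog_groups,
    polarize_indel,
)

from conftest import AA

CAENO = [
    "Caenorhabditis elegans",
    "Caenorhabditis briggsae",
    "Caenorhabditis nigoni",
    "Caenorhabditis brenneri",
    "Caenorhabditis remanei",
    "Caenorhabditis japonica",
]


def block_alignment(bearer_species, other_species, length=2, group=None):
    """Width-120 alignment with a block at columns 51..50+length carried
    by the bearer species and gapped in the others."""
    rng = random.Random(0)
    base = "".join(rng.choice(AA) for _ in range(120 - length))
    rows = []
    for i, sp in enumerate(list(bearer_species) + list(other_species)):
        has = sp in bearer_species
        block = "W" * length if has else "-" * length
        rows.append(
            AlignedSequence(
                id=f"s{i}", species=sp,
                homolog_group=(group or {}).get(sp, ""),
                residues=base[:50] + block + base[50:],
            )
        )
    aln = Alignment(rows)
    cand = CandidateIndel(
        start=51, end=50 + length, length=length,
        bearers=frozenset(r.id for r in rows if r.species in bearer_species),
        non_bearers=frozenset(
            r.id for r in rows if r.species not in bearer_species
        ),
        uniform_length=True,
    )
    return aln, cand


class TestTaxonomyTree:
    def test_lineage_table_round_trip(self, tmp_path):
        p = tmp_path / "lineage.tsv"
        p.write_text(
            "species\tlineage\n"
            "Caenorhabditis elegans\tNematoda, Chromadorea, Caenorhabditis\n"
            "Homo sapiens\toutgroup\n"
        )
        tax = TaxonomyTree.from_lineage_table(p)
        assert tax.lineage("Caenorhabditis elegans") == (
            "Nematoda", "Chromadorea", "Caenorhabditis",
        )
        assert tax.is_outgroup("Homo sapiens")

    def test_newick_internal_labels_become_clades(self, tmp_path):
        nwk = "((A:1,B:1)Genus1:1,(C:1,D:1)Genus2:1)Family:1;"
        tax = TaxonomyTree.from_newick(nwk)
        assert tax.lineage("A") == ("Family", "Genus1")
        assert tax.smallest_named_clade(["A", "B"]) == "Genus1"
        assert tax.smallest_named_clade(["A", "C"]) == "Family"

    def test_conflicting_clade_placement_rejected(self):
        with pytest.raises(ValueError, match="clade"):
            TaxonomyTree(
                {
                    "sp1": ("Root", "X"),
                    "sp2": ("Root", "Other", "X"),
                }
            )

    def test_unknown_species_raises(self):
        tax = default_taxonomy()
        with pytest.raises(UnresolvableSpeciesError, match="Canis familiaris"):
            tax.lineage("Canis familiaris")

    def test_lca_matches_dendropy_mrca_oracle(self):
        """Our named-clade LCA agrees with dendropy's MRCA computed on the
        same tree rendered to newick."""
        sim_tree = default_sim_tree()
        tax = default_taxonomy()
        dtree = dendropy.Tree.get(data=sim_tree.to_newick(), schema="newick")
        dtree.is_rooted = True
        labels = {
            t.label.replace("_", " "): t for t in dtree.taxon_namespace
        }
        rng = random.Random(13)
        nematodes = sorted(tax.species - tax.outgroups)
        for _ in range(100):
            sample = rng.sample(nematodes, k=rng.randint(1, 5))
            mrca = dtree.mrca(taxa=[labels[sp] for sp in sample])
            # deepest *named* ancestor at or above the MRCA
            node = mrca
            while node is not None and not node.label:
                node = node.parent_node
            expected = node.label if node is not None else None
            assert tax.smallest_named_clade(sample) == expected

    def test_outgroup_in_set_yields_no_clade(self):
        tax = default_taxonomy()
        assert (
            tax.smallest_named_clade(
                ["Caenorhabditis elegans", "Plasmodium falciparum"]
            )
            is None
        )


class TestEvaluateSpecificity:
    def test_all_caenorhabditis_bearers_call_the_genus(self, taxonomy):
        others = ["Diploscapter pachys", "Brugia malayi", "Trichuris muris",
                  "Plasmodium falciparum"]
        aln, cand = block_alignment(CAENO, others)
        call = evaluate_specificity(cand, aln, taxonomy)
        assert call.clade == "Caenorhabditis"
        assert call.exceptions == frozenset()
        assert call.intruders == frozenset()

    def test_in_clade_absence_fails_at_zero_tolerance(self, taxonomy):
        bearers = CAENO[:5]
        others = [CAENO[5], "Diploscapter pachys", "Trichuris muris"]
        aln, cand = block_alignment(bearers, others)
        call = evaluate_specificity(cand, aln, taxonomy, tolerance=0)
        assert call.clade == "none"
        assert call.exceptions == {CAENO[5]}

    def test_tolerance_and_allowlist_admit_documented_exception(self, taxonomy):
        """A class-level signature absent from one deep-branching species
        is recoverable with tolerance 1 or a named allowlist."""
        chromadorea = CAENO + [
            "Diploscapter pachys", "Brugia malayi", "Haemonchus contortus",
            "Ancylostoma ceylanicum",
        ]
        others = ["Strongyloides ratti", "Trichuris muris",
                  "Trichinella spiralis", "Eimeria necatrix"]
        aln, cand = block_alignment(chromadorea, others)
        strict = evaluate_specificity(cand, aln, taxonomy, tolerance=0)
        assert strict.clade == "none"
        tolerant = evaluate_specificity(cand, aln, taxonomy, tolerance=1)
        assert tolerant.clade == "Chromadorea"
        assert tolerant.exceptions == {"Strongyloides ratti"}
        allowed = evaluate_specificity(
            cand, aln, taxonomy,
            exception_allowlist=["Strongyloides ratti"],
        )
        assert allowed.clade == "Chromadorea"

    def test_tolerance_monotonicity(self, taxonomy):
        bearers = CAENO[:4]
        others = CAENO[4:] + ["Diploscapter pachys", "Trichuris muris"]
        aln, cand = block_alignment(bearers, others)
        succeeded = False
        for tol in range(0, 4):
            call = evaluate_specificity(cand, aln, taxonomy, tolerance=tol)
            if succeeded:
                assert call.clade != "none"
            succeeded = succeeded or call.clade != "none"
        assert succeeded  # 2 exceptions fit within tolerance <= 3

    def test_every_species_bearing_calls_the_root(self, taxonomy):
        bearers = CAENO + ["Diploscapter pachys", "Strongyloides ratti",
                           "Brugia malayi", "Haemonchus contortus",
                           "Ancylostoma ceylanicum", "Trichinella spiralis",
                           "Trichinella pseudospiralis", "Trichuris muris"]
        aln, cand = block_alignment(bearers, ["Plasmodium falciparum"])
        call = evaluate_specificity(cand, aln, taxonomy)
        assert call.clade == "Nematoda"

    def test_outgroup_bearer_is_an_intruder(self, taxonomy):
        aln, cand = block_alignment(
            CAENO + ["Plasmodium falciparum"],
            ["Diploscapter pachys", "Trichuris muris"],
        )
        call = evaluate_specificity(cand, aln, taxonomy)
        assert call.clade == "none"
        assert call.intruders == {"Plasmodium falciparum"}

    def test_missing_species_do_not_count_as_exceptions(self, taxonomy):
        """Clade members absent from the alignment are reported missing,
        not as exceptions, and do not break the call."""
        aln, cand = block_alignment(
            CAENO[:4], ["Diploscapter pachys", "Trichuris muris"]
        )
        call = evaluate_specificity(cand, aln, taxonomy)
        assert call.clade == "Caenorhabditis"
        assert call.missing == set(CAENO[4:])

    def test_paralog_isolation(self, taxonomy):
        """A second homolog group lacking the indel flags the call as
        paralog-restricted without changing the clade."""
        others = ["Diploscapter pachys", "Trichuris muris"]
        aln, cand = block_alignment(
            CAENO, others,
            group={sp: "g1" for sp in CAENO + others},
        )
        extra = [
            AlignedSequence(
                id=f"p{i}", species=sp, homolog_group="g2",
                residues=aln.rows[0].residues[:50] + "--"
                + aln.rows[0].residues[52:],
            )
            for i, sp in enumerate(CAENO[:3])
        ]
        aln2 = Alignment(list(aln.rows) + extra)
        cand2 = CandidateIndel(
            start=cand.start, end=cand.end, length=cand.length,
            bearers=cand.bearers,
            non_bearers=cand.non_bearers | frozenset(r.id for r in extra),
            uniform_length=True,
        )
        base = evaluate_specificity(cand, aln, taxonomy)
        with_paralogs = evaluate_specificity(cand2, aln2, taxonomy)
        assert with_paralogs.clade == base.clade == "Caenorhabditis"
        assert with_paralogs.paralog_restricted
        assert not base.paralog_restricted


class TestPolarity:
    def test_outgroups_lacking_block_mean_insertion(self, taxonomy):
        aln, cand = block_alignment(
            CAENO, ["Trichuris muris", "Plasmodium falciparum",
                    "Eimeria necatrix"],
        )
        out_ids = [r.id for r in aln.rows if taxonomy.is_outgroup(r.species)]
        pol = polarize_indel(cand, aln, out_ids)
        assert pol == Polarity(state="insertion", outgroup_support=2)

    def test_no_outgroups_is_ambiguous(self, taxonomy):
        aln, cand = block_alignment(CAENO, ["Trichuris muris"])
        assert polarize_indel(cand, aln, []) == Polarity(
            state="ambiguous", outgroup_support=0
        )

    def test_swapping_roles_flips_polarity(self, taxonomy):
        aln, cand = block_alignment(
            CAENO, ["Trichuris muris", "Plasmodium falciparum"],
        )
        out_ids = [r.id for r in aln.rows if taxonomy.is_outgroup(r.species)]
        flipped = CandidateIndel(
            start=cand.start, end=cand.end, length=cand.length,
            bearers=cand.non_bearers, non_bearers=cand.bearers,
            uniform_length=True,
        )
        assert polarize_indel(cand, aln, out_ids).state == "insertion"
        # with outgroups carrying residues instead, the gap is derived
        aln2, cand2 = block_alignment(
            ["Trichuris muris", "Plasmodium falciparum"], CAENO,
        )
        out_ids2 = [r.id for r in aln2.rows if taxonomy.is_outgroup(r.species)]
        assert polarize_indel(cand2, aln2, out_ids2).state == "deletion"

    def test_polarity_invariant_under_row_reordering(self, taxonomy):
        aln, cand = block_alignment(
            CAENO, ["Trichuris muris", "Plasmodium falciparum"],
        )
        out_ids = [r.id for r in aln.rows if taxonomy.is_outgroup(r.species)]
        shuffled = Alignment(list(reversed(aln.rows)))
        assert polarize_indel(cand, aln, out_ids) == polarize_indel(
            cand, shuffled, out_ids
        )


class TestHomologGroups:
    def test_single_sequence_per_species_one_group(self):
        seqs = [
            AlignedSequence(id=f"s{i}", species=f"sp{i}", residues="ACDEFGHIKL")
            for i in range(3)
        ]
        groups = partition_homolog_groups(seqs)
        assert set(groups.values()) == {"g1"}

    def test_divergent_pair_splits_below_threshold(self):
        a = "ACDEFGHIKLMNPQRSTVWY" * 2
        b = "AWYEFGAIKPMNPQCCVWYA" + "GGGGGGGGGGGGGGGGGGGG"  # ~40% identity
        seqs = [
            AlignedSequence(id="x1", species="sp1", residues=a),
            AlignedSequence(id="x2", species="sp1", residues=b),
        ]
        groups = partition_homolog_groups(seqs, identity_threshold=0.5)
        assert groups["x1"] != groups["x2"]

    def test_prelabelled_groups_pass_through(self):
        seqs = [
            AlignedSequence(id="a", species="sp", homolog_group="nrfl-1a",
                            residues="ACDE"),
            AlignedSequence(id="b", species="sp", homolog_group="nrfl-1b",
                            residues="ACDE"),
        ]
        groups = partition_homolog_groups(seqs)
        assert groups == {"a": "nrfl-1a", "b": "nrfl-1b"}

    def test_empty_input(self):
        assert partition_homolog_groups([]) == {}
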