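"""Clade-structured protein-family simulator with planted signature indels.

Stands in for a genome-wide comparative scan: families of homologous
protein sequences are evolved down a fixed species tree, a conserved
signature indel of chosen length and polarity is planted on the stem
branch of a target clade with frozen (invariant) flanking sites, and
lineage-specific background indels plus substitution noise are layered on
top.  The generator emits the *true* alignment alongside the unaligned
sequences, so every pipeline stage can be tested without an external MSA
tool, and a ground-truth record for benchmarking.

The substitution process is deliberately simple — uniform random
replacement at variable sites, no rate matrix — because the pipeline
under test is pattern-based, not likelihood-based.  Background indels are
placed on terminal branches only (single-lineage indels, the dominant
pattern among non-signature indels in real families).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import GAP, AlignedSequence, Alignment, write_alignment
from .screen import HitRecord
from .taxonomy import OUTGROUP_TOKEN, TaxonomyTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SimSpecError(ValueError):
    """Invalid simulation specification (e.g., overlapping frozen zones)."""


@dataclass(frozen=True)
class SimTree:
    """A rooted tree node: species leaf or (optionally named) clade.

    ``length`` is the per-variable-site substitution probability on the
    branch above the node.
    """

    name: str
    length: float = 0.0
    children: tuple["SimTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def find(self, name: str) -> Optional["SimTree"]:
        if self.name == name:
            return self
        for c in self.children:
            hit = c.find(name)
            if hit is not None:
                return hit
        return None

    def to_newick(self) -> str:
        def render(node: "SimTree") -> str:
            label = node.name.replace(" ", "_")
            if node.is_leaf:
                return f"{label}:{node.length}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}:{node.length}"

        return render(self) + ";"


def default_sim_tree() -> SimTree:
    """The default study taxonomy: six *Caenorhabditis* species plus
    *Diploscapter* (family Rhabditoidea), further Chromadorea, an Enoplea
    clade, and four apicomplexan outgroups."""

    def leaf(name: str, length: float) -> SimTree:
        return SimTree(name=name, length=length)

    caeno = SimTree(
        name="Caenorhabditis",
        length=0.10,
        children=tuple(
            leaf(sp, 0.05)
            for sp in (
                "Caenorhabditis elegans",
                "Caenorhabditis briggsae",
                "Caenorhabditis nigoni",
                "Caenorhabditis brenneri",
                "Caenorhabditis remanei",
                "Caenorhabditis japonica",
            )
        ),
    )
    rhabditoidea = SimTree(
        name="Rhabditoidea",
        length=0.10,
        children=(caeno, leaf("Diploscapter pachys", 0.15)),
    )
    chromadorea = SimTree(
        name="Chromadorea",
        length=0.10,
        children=(
            rhabditoidea,
            leaf("Strongyloides ratti", 0.25),
            leaf("Brugia malayi", 0.22),
            leaf("Haemonchus contortus", 0.22),
            leaf("Ancylostoma ceylanicum", 0.22),
        ),
    )
    enoplea = SimTree(
        name="Enoplea",
        length=0.12,
        children=(
            leaf("Trichinella spiralis", 0.08),
            leaf("Trichinella pseudospiralis", 0.08),
            leaf("Trichuris muris", 0.15),
        ),
    )
    nematoda = SimTree(
        name="Nematoda", length=0.20, children=(chromadorea, enoplea)
    )
    outgroup = SimTree(
        name=OUTGROUP_TOKEN,
        length=0.10,
        children=tuple(
            leaf(sp, 0.30)
            for sp in (
                "Cryptosporidium muris",
                "Plasmodium falciparum",
                "Babesia bigemina",
                "Eimeria necatrix",
            )
        ),
    )
    return SimTree(name="", length=0.0, children=(nematoda, outgroup))


def taxonomy_from_sim_tree(tree: SimTree) -> TaxonomyTree:
    """Lineage map over the tree's named internal nodes; species under an
    ``outgroup``-labelled subtree become declared outgroups."""
    lineages: dict[str, tuple[str, ...]] = {}

    def walk(node: SimTree, path: tuple[str, ...], is_out: bool) -> None:
        if node.name == OUTGROUP_TOKEN:
            is_out = True
        if node.is_leaf:
            lineages[node.name] = (OUTGROUP_TOKEN,) if is_out else path
            return
        new_path = path + (node.name,) if node.name and not is_out else path
        for c in node.children:
            walk(c, new_path, is_out)

    walk(tree, (), False)
    return TaxonomyTree(lineages)


def default_taxonomy() -> TaxonomyTree:
    return taxonomy_from_sim_tree(default_sim_tree())


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedCSI:
    """One signature indel to plant on the stem branch of *clade*.

    ``position`` is the 1-based root residue after which an insertion is
    placed, or before which a deletion block ``position+1 ..
    position+length`` is removed.  ``flank_freeze_width`` root residues on
    each side are frozen in every lineage so the signature has the
    conserved flanks the detection rule requires.
    """

    clade: str
    length: int
    indel_type: str  # ins | del
    position: int
    flank_freeze_width: int = 10

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimSpecError("planted CSI length must be >= 1")
        if self.indel_type not in ("ins", "del"):
            raise SimSpecError(f"bad indel_type {self.indel_type!r}")

    def frozen_zone(self) -> tuple[int, int]:
        """Inclusive 1-based root-position interval no other event may touch."""
        lo = self.position - self.flank_freeze_width + 1
        if self.indel_type == "ins":
            hi = self.position + self.flank_freeze_width
        else:
            hi = self.position + self.length + self.flank_freeze_width
        return lo, hi


@dataclass(frozen=True)
class ParalogSpec:
    """Duplicate the gene at the stem of *clade*: each member species gains
    a second homolog group evolved with extra divergence and without the
    planted signature (duplication precedes the signature event)."""

    clade: str
    extra_divergence: float = 0.15


@dataclass(frozen=True)
class SimSpec:
    tree: SimTree = field(default_factory=default_sim_tree)
    root_length: int = 400
    frozen_fraction: float = 0.4
    planted_csis: tuple[PlantedCSI, ...] = ()
    background_indel_rate: float = 0.3  # expected events per terminal branch
    background_indel_max_len: int = 5
    paralog: Optional[ParalogSpec] = None
    edge_margin: int = 20  # planted indels must sit this far from termini
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frozen_fraction <= 1):
            raise SimSpecError("frozen_fraction outside [0, 1]")
        zones = []
        for csi in self.planted_csis:
            if self.tree.find(csi.clade) is None:
                raise SimSpecError(f"clade {csi.clade!r} not in tree")
            lo, hi = csi.frozen_zone()
            if lo < self.edge_margin or hi > self.root_length - self.edge_margin:
                raise SimSpecError(
                    f"planted CSI at {csi.position} too close to a terminus"
                )
            zones.append((lo, hi, csi))
        zones.sort()
        for (lo1, hi1, a), (lo2, hi2, b) in zip(zones, zones[1:]):
            if lo2 <= hi1:
                raise SimSpecError(
                    f"planted CSI at {b.position} overlaps the frozen zone "
                    f"of the CSI at {a.position}"
                )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTruth:
    clade: str
    length: int
    indel_type: str
    position: int  # root coordinate
    column_span: tuple[int, int]  # 1-based columns in the emitted alignment
    bearer_species: frozenset[str]  # species carrying the derived state


@dataclass
class SimTruth:
    planted: list[PlantedTruth]
    rows: pd.DataFrame  # id, species, homolog_group, is_outgroup


@dataclass
class FamilySim:
    alignment: Alignment  # the true alignment, gap-annotated
    sequences: dict[str, str]  # id -> ungapped sequence
    truth: SimTruth
    spec: SimSpec


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _species_id(species: str, group: str = "") -> str:
    base = species.replace(" ", "_")
    return f"{base}~{group}" if group else base


def simulate_family(spec: SimSpec) -> FamilySim:
    """Evolve one protein family down the tree; pure function of the seed."""
    rng = np.random.default_rng(spec.seed)
    L = spec.root_length
    root = {
        (i, 0, 0): AMINO_ACIDS[k]
        for i, k in enumerate(rng.integers(0, 20, size=L), start=1)
    }

    # frozen root positions: planted zones first, then random fill
    frozen: set[int] = set()
    for csi in spec.planted_csis:
        lo, hi = csi.frozen_zone()
        frozen.update(range(lo, hi + 1))
    target = int(spec.frozen_fraction * L)
    free = [p for p in range(1, L + 1) if p not in frozen]
    if len(frozen) < target:
        extra = rng.choice(len(free), size=target - len(frozen), replace=False)
        frozen.update(free[i] for i in extra)

    csis_by_clade: dict[str, list[PlantedCSI]] = {}
    for csi in spec.planted_csis:
        csis_by_clade.setdefault(csi.clade, []).append(csi)

    zones = [c.frozen_zone() for c in spec.planted_csis]

    def in_zone(pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in zones)

    event_counter = [0]
    frozen_keys: set[tuple] = set()  # inserted columns that never mutate

    def mutate(state: dict, prob: float) -> dict:
        out = dict(state)
        keys = [
            k
            for k in out
            if not (k[1] == 0 and k[0] in frozen) and k not in frozen_keys
        ]
        if not keys or prob <= 0:
            return out
        hits = rng.random(len(keys)) < prob
        for k, hit in zip(keys, hits):
            if hit:
                old = out[k]
                repl = AMINO_ACIDS[int(rng.integers(0, 19))]
                out[k] = repl if repl != old else AMINO_ACIDS[19]
        return out

    def plant(state: dict, csi: PlantedCSI) -> tuple[dict, list]:
        out = dict(state)
        if csi.indel_type == "ins":
            event_counter[0] += 1
            e = event_counter[0]
            new_keys = [(csi.position, e, k) for k in range(1, csi.length + 1)]
            for k in new_keys:
                out[k] = AMINO_ACIDS[int(rng.integers(0, 20))]
                frozen_keys.add(k)
            return out, new_keys
        removed = [(p, 0, 0) for p in range(csi.position + 1, csi.position + csi.length + 1)]
        for k in removed:
            out.pop(k, None)
        return out, removed

    def background_events(state: dict) -> dict:
        out = dict(state)
        n_events = int(rng.poisson(spec.background_indel_rate))
        for _ in range(n_events):
            length = int(rng.integers(1, spec.background_indel_max_len + 1))
            is_ins = bool(rng.random() < 0.5)
            for _attempt in range(50):
                p = int(rng.integers(spec.edge_margin, L - spec.edge_margin))
                if is_ins:
                    if not in_zone(p) and not in_zone(p + 1):
                        event_counter[0] += 1
                        e = event_counter[0]
                        for k in range(1, length + 1):
                            out[(p, e, k)] = AMINO_ACIDS[int(rng.integers(0, 20))]
                        break
                else:
                    span = range(p + 1, p + length + 1)
                    if all(not in_zone(q) for q in span) and p + length <= L:
                        for q in span:
                            out.pop((q, 0, 0), None)
                        break
        return out

    planted_keys: dict[PlantedCSI, list] = {}
    leaf_states: dict[str, dict] = {}
    clade_parent_state: dict[str, dict] = {}

    def evolve(node: SimTree, state: dict) -> None:
        state = mutate(state, node.length)
        # duplication precedes the signature event: the second homolog group
        # branches off before any CSI is planted on this stem
        if spec.paralog and node.name == spec.paralog.clade:
            clade_parent_state.setdefault("~paralog~", dict(state))
        if node.name in csis_by_clade:
            for csi in csis_by_clade[node.name]:
                state, keys = plant(state, csi)
                planted_keys[csi] = keys
        if node.is_leaf:
            leaf_states[node.name] = background_events(state)
            return
        for child in node.children:
            evolve(child, state)

    evolve(spec.tree, root)

    # paralog copies: independent descent from the duplication point
    paralog_states: dict[str, dict] = {}
    if spec.paralog is not None:
        clade_node = spec.tree.find(spec.paralog.clade)
        if clade_node is None:
            raise SimSpecError(f"paralog clade {spec.paralog.clade!r} not in tree")
        start = clade_parent_state.get("~paralog~")
        if start is None:  # clade carries no planted CSI; state at stem
            raise SimSpecError(
                "paralog duplication requires the clade to be reached during "
                "evolution"
            )

        def evolve_paralog(node: SimTree, state: dict) -> None:
            state = mutate(state, node.length + spec.paralog.extra_divergence
                           if node.is_leaf else node.length)
            if node.is_leaf:
                paralog_states[node.name] = background_events(state)
                return
            for child in node.children:
                evolve_paralog(child, state)

        for child in clade_node.children:
            evolve_paralog(child, start)

    # assemble the true alignment
    has_paralog = spec.paralog is not None
    taxonomy = taxonomy_from_sim_tree(spec.tree)
    rows_info = []
    row_states: list[tuple[str, str, str, dict]] = []
    for sp in spec.tree.leaves():
        group = "g1" if has_paralog else ""
        row_states.append((_species_id(sp, group), sp, group, leaf_states[sp]))
    for sp in spec.tree.leaves():
        if sp in paralog_states:
            row_states.append(
                (_species_id(sp, "g2"), sp, "g2", paralog_states[sp])
            )

    all_keys = sorted(set().union(*(set(s) for _, _, _, s in row_states)))
    key_col = {k: i + 1 for i, k in enumerate(all_keys)}
    rows = []
    for rid, sp, group, state in row_states:
        residues = "".join(state.get(k, GAP) for k in all_keys)
        rows.append(
            AlignedSequence(
                id=rid, residues=residues, species=sp, homolog_group=group
            )
        )
        rows_info.append(
            {
                "id": rid,
                "species": sp,
                "homolog_group": group,
                "is_outgroup": taxonomy.is_outgroup(sp),
            }
        )
    aln = Alignment(rows)

    planted_truth = []
    for csi in spec.planted_csis:
        keys = planted_keys.get(csi)
        if keys is None:
            raise SimSpecError(
                f"clade {csi.clade!r} was never reached during evolution"
            )
        cols = sorted(key_col[k] for k in keys if k in key_col)
        clade_node = spec.tree.find(csi.clade)
        bearer_species = frozenset(clade_node.leaves())
        span = (cols[0], cols[-1])
        planted_truth.append(
            PlantedTruth(
                clade=csi.clade,
                length=csi.length,
                indel_type=csi.indel_type,
                position=csi.position,
                column_span=span,
                bearer_species=bearer_species,
            )
        )

    truth = SimTruth(planted=planted_truth, rows=pd.DataFrame(rows_info))
    sim = FamilySim(
        alignment=aln,
        sequences={r.id: r.ungapped for r in rows},
        truth=truth,
        spec=spec,
    )
    _self_check(sim)
    return sim


def _self_check(sim: FamilySim) -> None:
    """Generation-time consistency check: truth matches emitted sequences."""
    aln = sim.alignment
    for pt in sim.truth.planted:
        first, last = pt.column_span
        group_of = {
            r["id"]: r["homolog_group"] for _, r in sim.truth.rows.iterrows()
        }
        for row in aln.rows:
            block = row.residues[first - 1 : last]
            in_clade = row.species in pt.bearer_species
            is_main = group_of[row.id] in ("", "g1")
            gapped = all(c == GAP for c in block)
            if pt.indel_type == "ins":
                expect_residues = in_clade and is_main
            else:
                expect_residues = not (in_clade and is_main)
            if expect_residues and gapped:
                raise SimSpecError(
                    f"self-check failed: {row.id} unexpectedly lacks the "
                    f"planted block at columns {pt.column_span}"
                )
            if not expect_residues and not gapped:
                raise SimSpecError(
                    f"self-check failed: {row.id} unexpectedly carries the "
                    f"planted block at columns {pt.column_span}"
                )


# ---------------------------------------------------------------------------
# hit-set generation for the screening stage
# ---------------------------------------------------------------------------

def generate_hit_set(
    window_seq: str,
    indel_start: int,
    indel_end: int,
    indel_type: str,
    n_in_clade: int,
    n_out_clade: int,
    divergence: float,
    seed: int,
    freeze_width: int = 10,
    in_species: Optional[Sequence[str]] = None,
    out_species: Optional[Sequence[str]] = None,
) -> tuple[list[HitRecord], dict[str, bool]]:
    """Synthesize a screened hit set for one signature window.

    *window_seq* is the residue-bearing window; *indel_start..indel_end*
    its indel block (1-based).  In-clade hits carry the indel (for ``del``
    signatures that means they lack the block residues), out-clade hits do
    not; every hit is mutated per-site at *divergence* outside the frozen
    flanks, and E-values are assigned monotone in realized divergence.
    """
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    with_block = window_seq
    without_block = window_seq[: indel_start - 1] + window_seq[indel_end:]
    frozen = set(
        range(max(1, indel_start - freeze_width), indel_end + freeze_width + 1)
    )

    def mutated(seq: str, has_block: bool) -> tuple[str, float]:
        # positions map back to with-block coordinates for the freeze mask
        out = []
        changed = 0
        pos_in_window = 0
        for i, c in enumerate(seq, start=1):
            if has_block:
                wpos = i
            else:
                wpos = i if i < indel_start else i + (indel_end - indel_start + 1)
            if wpos in frozen or rng.random() >= divergence:
                out.append(c)
            else:
                repl = AMINO_ACIDS[int(rng.integers(0, 19))]
                out.append(repl if repl != c else AMINO_ACIDS[19])
                changed += 1
        return "".join(out), changed / max(1, len(seq))

    hits: list[HitRecord] = []
    labels: dict[str, bool] = {}
    in_species = list(in_species or [])
    out_species = list(out_species or [])
    for i in range(n_in_clade):
        base = with_block if indel_type == "ins" else without_block
        seq, frac = mutated(base, base is with_block)
        hid = f"in{i + 1}"
        sp = in_species[i % len(in_species)] if in_species else f"inclade sp{i + 1}"
        hits.append(
            HitRecord(
                hit_id=hid,
                species=sp,
                e_value=10 ** (-35 + 30 * frac),
                sequence=seq,
            )
        )
        labels[hid] = True
    for i in range(n_out_clade):
        base = without_block if indel_type == "ins" else with_block
        seq, frac = mutated(base, base is with_block)
        hid = f"out{i + 1}"
        sp = out_species[i % len(out_species)] if out_species else f"outclade sp{i + 1}"
        hits.append(
            HitRecord(
                hit_id=hid,
                species=sp,
                e_value=10 ** (-35 + 30 * frac),
                sequence=seq,
            )
        )
        labels[hid] = False
    return hits, labels


# ---------------------------------------------------------------------------
# benchmark suite
# ---------------------------------------------------------------------------

DEFAULT_BENCHMARK_CLADES = (
    "Caenorhabditis",
    "Rhabditoidea",
    "Chromadorea",
    "Nematoda",
)


@dataclass
class BenchmarkSuite:
    cases: list[tuple[str, FamilySim]]
    manifest: pd.DataFrame


def make_benchmark_suite(
    n_families: int,
    fraction_with_csi: float,
    seed: int,
    spec_template: Optional[SimSpec] = None,
    planted_clades: Optional[Sequence[str]] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> BenchmarkSuite:
    """Simulate *n_families* independent families, a stated fraction
    carrying exactly one planted CSI; deterministic under *seed*.

    *planted_clades*, when given, is cycled over the planted families in
    order (e.g., to reproduce a published per-clade census); otherwise
    target clades are drawn uniformly from the four nested study clades.
    """
    rng = np.random.default_rng(seed)
    template = spec_template or SimSpec()
    n_planted = round(n_families * fraction_with_csi)
    planted_flags = [i < n_planted for i in range(n_families)]

    cases: list[tuple[str, FamilySim]] = []
    records = []
    for i in range(n_families):
        fid = f"fam{i + 1:04d}"
        child_seed = int(rng.integers(0, 2**31 - 1))
        csis: tuple[PlantedCSI, ...] = ()
        if planted_flags[i]:
            if planted_clades:
                clade = planted_clades[
                    sum(planted_flags[: i + 1]) % len(planted_clades) - 1
                ]
            else:
                clade = DEFAULT_BENCHMARK_CLADES[
                    int(rng.integers(0, len(DEFAULT_BENCHMARK_CLADES)))
                ]
            length = int(rng.integers(1, 7))
            indel_type = "ins" if rng.random() < 0.7 else "del"
            lo = template.edge_margin + 60
            hi = template.root_length - template.edge_margin - 60
            position = int(rng.integers(lo, hi))
            csis = (
                PlantedCSI(
                    clade=clade,
                    length=length,
                    indel_type=indel_type,
                    position=position,
                ),
            )
        spec = dataclasses.replace(
            template, planted_csis=csis, seed=child_seed
        )
        sim = simulate_family(spec)
        cases.append((fid, sim))
        if csis:
            records.append(
                {
                    "family_id": fid,
                    "has_csi": True,
                    "clade": csis[0].clade,
                    "length": csis[0].length,
                    "indel_type": csis[0].indel_type,
                    "position": csis[0].position,
                }
            )
        else:
            records.append(
                {
                    "family_id": fid,
                    "has_csi": False,
                    "clade": "",
                    "length": 0,
                    "indel_type": "",
                    "position": 0,
                }
            )
    manifest = pd.DataFrame(
        records,
        columns=[
            "family_id", "has_csi", "clade", "length", "indel_type", "position",
        ],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        for fid, sim in cases:
            write_alignment(
                sim.alignment, out_dir / f"{fid}.true.fasta", format="fasta"
            )
            with open(out_dir / f"{fid}.fasta", "w") as fh:
                for rid, seq in sim.sequences.items():
                    fh.write(f">{rid}\n{seq}\n")
    return BenchmarkSuite(cases=cases, manifest=manifest)
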