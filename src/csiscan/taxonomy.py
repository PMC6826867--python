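"""Taxonomic specificity of candidate indels.

Given a rooted taxonomy with named clades (genus, family, class, phylum
...), decide the smallest named clade whose members uniquely share a
candidate indel, report in-clade exceptions and out-of-clade intruders,
handle paralog-restricted signatures (present in only one of several
within-species homolog groups), and polarize each indel as an insertion or
a deletion by comparing to outgroup character states.

The taxonomy is always supplied by the user — as a newick tree with
internal node labels or a lineage table mapping each species to its
ordered clade path from the root (e.g. ``Nematoda, Chromadorea,
Rhabditoidea, Caenorhabditis``).  Species outside the focal phylum are
declared with the reserved lineage token ``outgroup``; they can never be
part of a specificity clade but they anchor insertion/deletion polarity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

from .alignment import GAP, AlignedSequence, Alignment
from .detect import CandidateIndel

#: Reserved lineage token declaring a species a non-member outgroup.
OUTGROUP_TOKEN = "outgroup"


class UnresolvableSpeciesError(KeyError):
    """An alignment row's species is neither in the taxonomy nor declared outgroup."""


@dataclass(frozen=True)
class SpecificityCall:
    """The clade verdict for one candidate in one homolog group.

    ``clade`` is ``"none"`` when the call fails (intruders present, or more
    in-clade absences than tolerated); ``candidate_clade`` then records the
    clade that was tested.
    """

    clade: str
    bearers: frozenset[str]
    exceptions: frozenset[str] = frozenset()
    intruders: frozenset[str] = frozenset()
    missing: frozenset[str] = frozenset()
    candidate_clade: str = ""
    homolog_group: str = ""
    paralog_restricted: bool = False


@dataclass(frozen=True)
class Polarity:
    state: str  # insertion | deletion | ambiguous
    outgroup_support: int

    def __post_init__(self) -> None:
        if self.state not in ("insertion", "deletion", "ambiguous"):
            raise ValueError(f"bad polarity state {self.state!r}")


class TaxonomyTree:
    """Rooted taxonomy as per-species named-clade paths.

    The representation is a lineage map: ``species -> (root, ..., genus)``
    over *named* clades only.  Outgroup species map to the empty path and
    are tracked separately.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        self._outgroups: set[str] = set()
        for sp, path in lineages.items():
            path = tuple(path)
            if len(path) == 1 and path[0].lower() == OUTGROUP_TOKEN:
                self._outgroups.add(sp)
                self._lineages[sp] = ()
            else:
                self._lineages[sp] = path
        names: dict[str, tuple[str, ...]] = {}
        for sp, path in self._lineages.items():
            for i, clade in enumerate(path):
                prefix = path[: i + 1]
                if names.setdefault(clade, prefix) != prefix:
                    raise ValueError(
                        f"clade {clade!r} appears at two different positions "
                        "in the taxonomy; clade names must be unique"
                    )
        self._clade_paths = names

    # -- constructors -------------------------------------------------

    @classmethod
    def from_lineage_table(cls, path: Union[str, Path]) -> "TaxonomyTree":
        """TSV with columns ``species`` and ``lineage`` (comma-separated,
        root first)."""
        lineages: dict[str, tuple[str, ...]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for rec in reader:
                lineages[rec["species"]] = tuple(
                    t.strip() for t in rec["lineage"].split(",") if t.strip()
                )
        return cls(lineages)

    @classmethod
    def from_newick(
        cls,
        source: Union[str, Path],
        outgroups: Iterable[str] = (),
    ) -> "TaxonomyTree":
        """Parse a rooted newick tree whose internal node labels name clades.

        Leaves are species; unlabelled internal nodes contribute nothing to
        lineages.  *outgroups* declares species that should be treated as
        non-members even if present in the tree.
        """
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick")
        outgroups = set(outgroups)
        lineages: dict[str, tuple[str, ...]] = {}
        for leaf in tree.leaf_node_iter():
            sp = leaf.taxon.label
            if sp in outgroups:
                lineages[sp] = (OUTGROUP_TOKEN,)
                continue
            path = []
            for node in leaf.ancestor_iter(inclusive=False):
                label = node.label or (node.taxon.label if node.taxon else None)
                if label:
                    path.append(label)
            lineages[sp] = tuple(reversed(path))
        return cls(lineages)

    def to_lineage_table(self, path: Union[str, Path]) -> None:
        """Write the species -> clade-path map back out as a lineage TSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["species", "lineage"])
            for sp in sorted(self._lineages):
                path_ = self._lineages[sp]
                lineage = OUTGROUP_TOKEN if sp in self._outgroups else ", ".join(path_)
                writer.writerow([sp, lineage])

    # -- queries ------------------------------------------------------

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._lineages)

    @property
    def outgroups(self) -> frozenset[str]:
        return frozenset(self._outgroups)

    @property
    def clades(self) -> frozenset[str]:
        return frozenset(self._clade_paths)

    def is_outgroup(self, species: str) -> bool:
        return species in self._outgroups

    def lineage(self, species: str) -> tuple[str, ...]:
        try:
            return self._lineages[species]
        except KeyError:
            raise UnresolvableSpeciesError(
                f"species {species!r} is not in the taxonomy and is not a "
                "declared outgroup"
            ) from None

    def clade_depth(self, clade: str) -> int:
        """1 = root; larger = more specific."""
        return len(self._clade_paths[clade])

    def clade_leaves(self, clade: str) -> frozenset[str]:
        prefix = self._clade_paths[clade]
        return frozenset(
            sp
            for sp, path in self._lineages.items()
            if path[: len(prefix)] == prefix
        )

    def smallest_named_clade(self, species: Iterable[str]) -> Optional[str]:
        """LCA over named clades: the deepest clade containing every species.

        Returns ``None`` if the set is empty, contains an outgroup, or the
        lineages share no named prefix.
        """
        paths = []
        for sp in species:
            lin = self.lineage(sp)
            if not lin:
                return None
            paths.append(lin)
        if not paths:
            return None
        common = paths[0]
        for p in paths[1:]:
            k = 0
            while k < len(common) and k < len(p) and common[k] == p[k]:
                k += 1
            common = common[:k]
            if not common:
                return None
        return common[-1]


# ---------------------------------------------------------------------------
# homolog-group partitioning
# ---------------------------------------------------------------------------

def partition_homolog_groups(
    seqs: Sequence[AlignedSequence],
    identity_threshold: float = 0.5,
) -> dict[str, str]:
    """Assign every sequence to exactly one homolog (paralog) group.

    Supplied ``homolog_group`` labels are respected verbatim when any row
    carries one.  Otherwise groups are formed by single-linkage clustering
    on ungapped pairwise identity at *identity_threshold*, computed with
    the screening aligner.  Group names ``g1, g2, ...`` are ordered by
    first appearance in row order.
    """
    if not seqs:
        return {}
    if any(s.homolog_group for s in seqs):
        return {s.id: s.homolog_group or "g1" for s in seqs}

    from .screen import pairwise_identity  # deferred: screen is independent

    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                pairwise_identity(seqs[i].ungapped, seqs[j].ungapped)
                >= identity_threshold
            ):
                parent[find(j)] = find(i)

    labels: dict[int, str] = {}
    out: dict[str, str] = {}
    for i, s in enumerate(seqs):
        root = find(i)
        if root not in labels:
            labels[root] = f"g{len(labels) + 1}"
        out[s.id] = labels[root]
    return out


# ---------------------------------------------------------------------------
# specificity evaluation
# ---------------------------------------------------------------------------

def evaluate_specificity(
    cand: CandidateIndel,
    aln: Alignment,
    taxonomy: TaxonomyTree,
    tolerance: int = 0,
    exception_allowlist: Iterable[str] = (),
    focal: str = "bearers",
) -> SpecificityCall:
    """Decide which named clade, if any, a candidate indel is specific for.

    The focal rows (``bearers`` by default; ``non_bearers`` when outgroup
    polarization shows the gap state is the derived one) define the bearer
    species set.  The clade tested is the smallest named clade containing
    all bearer species.  The call succeeds iff no species outside the clade
    carries the indel and the number of in-clade absences, beyond any named
    allowlist, is at most *tolerance*.  Evaluation is per homolog group:
    rows of other groups are ignored, and the call is flagged
    paralog-restricted when another group of a bearer species lacks the
    indel.
    """
    if focal not in ("bearers", "non_bearers"):
        raise ValueError(f"focal must be 'bearers' or 'non_bearers', got {focal!r}")
    for row in aln.rows:
        taxonomy.lineage(row.species)  # raises UnresolvableSpeciesError

    focal_ids = cand.bearers if focal == "bearers" else cand.non_bearers
    other_ids = cand.non_bearers if focal == "bearers" else cand.bearers

    groups = {aln.row(i).homolog_group for i in focal_ids}
    restrict = groups.pop() if len(groups) == 1 else None

    def in_universe(row: AlignedSequence) -> bool:
        if row.id in cand.missing:
            return False
        return restrict is None or row.homolog_group == restrict

    universe = [r for r in aln.rows if in_universe(r)]
    bearer_species = frozenset(
        r.species for r in universe if r.id in focal_ids
    )
    non_bearer_species = frozenset(
        r.species for r in universe if r.id in other_ids
    )

    intruders = frozenset(
        sp for sp in bearer_species if taxonomy.is_outgroup(sp)
    )
    clade = taxonomy.smallest_named_clade(bearer_species - intruders) or ""

    if clade:
        leaves = taxonomy.clade_leaves(clade)
        scorable = frozenset(r.species for r in universe)
        exceptions = (leaves & scorable) - bearer_species
        missing = leaves - scorable
    else:
        exceptions = frozenset()
        missing = frozenset()

    # paralog restriction: a bearer species also contributes rows to
    # another homolog group, and those rows lack the indel (they are either
    # in the opposing partition or outside it entirely)
    paralog_restricted = restrict is not None and any(
        r.homolog_group != restrict
        and r.species in bearer_species
        and r.id not in focal_ids
        for r in aln.rows
    )

    allow = set(exception_allowlist)
    countable = exceptions - allow if clade else frozenset()
    ok = bool(clade) and not intruders and len(countable) <= tolerance
    return SpecificityCall(
        clade=clade if ok else "none",
        bearers=bearer_species,
        exceptions=exceptions,
        intruders=intruders,
        missing=missing,
        candidate_clade=clade,
        homolog_group=restrict or "",
        paralog_restricted=paralog_restricted,
    )


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize_indel(
    cand: CandidateIndel,
    aln: Alignment,
    outgroup_ids: Iterable[str],
) -> Polarity:
    """Insertion or deletion, decided by outgroup character states.

    If every scorable outgroup row lacks residues across the block the
    bearer state is derived — an insertion; if every outgroup carries
    residues, the gap state is derived — a deletion; otherwise ambiguous.
    """
    lacks = carries = 0
    for oid in outgroup_ids:
        if oid in cand.missing or oid not in aln.ids:
            continue
        row = aln.row(oid)
        cells = row.residues[cand.start - 1 : cand.end]
        if all(c == GAP for c in cells):
            lacks += 1
        elif all(c != GAP for c in cells):
            carries += 1
        # partially gapped outgroup rows are unscorable
    support = lacks + carries
    if support == 0 or (lacks and carries):
        return Polarity(state="ambiguous", outgroup_support=support)
    return Polarity(
        state="insertion" if lacks else "deletion",
        outgroup_support=support,
    )
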