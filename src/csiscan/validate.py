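"""Validation of curated homolog families against expected signatures.

For users who assemble curated homolog alignments for published signature
proteins (e.g., from the NCBI records cited in a signature table), this
module runs the discovery pipeline over each family and compares what it
finds with the expected indel size, polarity and specificity level,
producing a per-family scorecard and a per-clade census.

The expected-signature manifest is a TSV with columns::

    protein_name  gene_name  accession  alignment_file
    expected_indel  (e.g. "5 aa ins")
    expected_specificity  (a named clade)

Alignment files are aligned FASTA with ``id|species|group`` headers,
relative to the manifest's directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .alignment import Alignment, read_alignment
from .detect import FlankParams
from .pipeline import analyze_family
from .taxonomy import TaxonomyTree


def validate_family(
    aln: Alignment,
    taxonomy: TaxonomyTree,
    expected_indel: str,
    expected_specificity: str,
    flank_params: FlankParams = FlankParams(),
    tolerance: int = 0,
    exception_allowlist: Iterable[str] = (),
) -> dict:
    """Run discovery on one curated family and score it against expectation.

    Returns observed indel/specificity of the best-matching detection (the
    one whose clade matches, else the first detection) and a ``matched``
    flag requiring indel label and clade to agree exactly.
    """
    result = analyze_family(
        aln,
        taxonomy,
        flank_params=flank_params,
        tolerance=tolerance,
        exception_allowlist=exception_allowlist,
    )
    observed_indel = ""
    observed_clade = ""
    matching = [
        d
        for d in result.detections
        if d.record.specificity.clade == expected_specificity
    ]
    pick = matching[0] if matching else (
        result.detections[0] if result.detections else None
    )
    if pick is not None:
        observed_indel = pick.record.indel_label
        observed_clade = pick.record.specificity.clade
    return {
        "n_detections": len(result.detections),
        "observed_indel": observed_indel,
        "observed_specificity": observed_clade,
        "matched": (
            observed_indel == expected_indel
            and observed_clade == expected_specificity
        ),
    }


def validate_curated_families(
    manifest: Union[str, Path, pd.DataFrame],
    taxonomy: TaxonomyTree,
    base_dir: Optional[Union[str, Path]] = None,
    flank_params: FlankParams = FlankParams(),
    tolerance: int = 0,
    exception_allowlist: Iterable[str] = (),
) -> pd.DataFrame:
    """Score every family in an expected-signature manifest.

    Returns the manifest with observed columns and ``matched`` appended;
    use :func:`specificity_census` on the result for per-clade counts.
    """
    if isinstance(manifest, (str, Path)):
        base_dir = base_dir or Path(manifest).parent
        manifest = pd.read_csv(manifest, sep="\t")
    base_dir = Path(base_dir or ".")
    rows = []
    for _, rec in manifest.iterrows():
        aln = read_alignment(base_dir / rec["alignment_file"])
        outcome = validate_family(
            aln,
            taxonomy,
            expected_indel=rec["expected_indel"],
            expected_specificity=rec["expected_specificity"],
            flank_params=flank_params,
            tolerance=tolerance,
            exception_allowlist=exception_allowlist,
        )
        rows.append({**rec.to_dict(), **outcome})
    return pd.DataFrame(rows)


def specificity_census(
    scorecard: pd.DataFrame,
    taxonomy: Optional[TaxonomyTree] = None,
    matched_only: bool = True,
) -> pd.Series:
    """Count validated signatures per specificity clade.

    Most specific clade first when a taxonomy is supplied (the usual way a
    per-level census is printed: genus, family, class, phylum).
    """
    use = scorecard[scorecard["matched"]] if matched_only else scorecard
    counts = use.groupby("observed_specificity").size()
    if taxonomy is not None:
        order = sorted(
            counts.index,
            key=lambda c: (
                -taxonomy.clade_depth(c) if c in taxonomy.clades else 0,
                c,
            ),
        )
        counts = counts.reindex(order)
    return counts
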