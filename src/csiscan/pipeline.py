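"""End-to-end signature discovery over one family alignment.

Composes the stages: scan for candidate indels, polarize each against the
outgroups, evaluate taxonomic specificity for the derived-state lineage
set, apply the flank-conservation rule, extract the signature window and
emit validated CSI records (or structured rejections).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .alignment import Alignment
from .detect import (
    CandidateIndel,
    FlankParams,
    Rejection,
    SignatureWindow,
    assess_flanks,
    call_csi,
    extract_signature_region,
    scan_candidate_indels,
)
from .report import CSIRecord
from .taxonomy import Polarity, TaxonomyTree, evaluate_specificity, polarize_indel


@dataclass
class DetectedCSI:
    record: CSIRecord
    window: SignatureWindow
    candidate: CandidateIndel
    polarity: Polarity


@dataclass
class PipelineResult:
    detections: list[DetectedCSI]
    rejections: list[Rejection]

    @property
    def records(self) -> list[CSIRecord]:
        return [d.record for d in self.detections]


def analyze_family(
    aln: Alignment,
    taxonomy: TaxonomyTree,
    flank_params: FlankParams = FlankParams(),
    tolerance: int = 0,
    exception_allowlist: Iterable[str] = (),
    flank_residues: int = 45,
    meta: Optional[dict] = None,
) -> PipelineResult:
    """Run the full discovery procedure on one family alignment.

    Outgroup rows (species declared outgroup in the taxonomy) polarize
    each candidate; when the gap state is the derived one (a deletion),
    specificity is evaluated for the gap-carrying lineage set rather than
    the residue-carrying one.
    """
    outgroup_ids = [
        r.id for r in aln.rows if taxonomy.is_outgroup(r.species)
    ]
    detections: list[DetectedCSI] = []
    rejections: list[Rejection] = []
    for cand in scan_candidate_indels(aln, flank_params):
        polarity = polarize_indel(cand, aln, outgroup_ids)
        focal = "non_bearers" if polarity.state == "deletion" else "bearers"
        spec_call = evaluate_specificity(
            cand,
            aln,
            taxonomy,
            tolerance=tolerance,
            exception_allowlist=exception_allowlist,
            focal=focal,
        )
        flanks = assess_flanks(aln, cand, flank_params)
        window = extract_signature_region(
            aln, cand, flank_residues=flank_residues
        )
        rec_meta = dict(meta or {})
        rec_meta.setdefault("paralog_restricted", spec_call.paralog_restricted)
        outcome = call_csi(
            cand,
            flanks,
            spec_call,
            meta=rec_meta,
            polarity=polarity,
            region=window.region,
        )
        if isinstance(outcome, Rejection):
            rejections.append(outcome)
        else:
            detections.append(
                DetectedCSI(
                    record=outcome,
                    window=window,
                    candidate=cand,
                    polarity=polarity,
                )
            )
    return PipelineResult(detections=detections, rejections=rejections)
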