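"""Deterministic annotation-driven evidence assignment for sections 1-3.

Sections 4 and 5 (case, case-control, and family evidence) are never assigned
automatically; they arrive via evidence worksheets only. The rules here cover
exactly the decision points that drive inter-laboratory discordance: genomic
content (section 1), established dosage-sensitivity and benign regions
(section 2), and protein-coding gene count with optional gene-family
collapsing (section 3).

Only ``curated=True`` regions ever contribute points ("established"
evidence); uncurated reports and partial dosage-region overlaps produce
review flags instead of guessed points.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import AnnotationSet, CNVCall, contains, genes_in, overlap_bp
from .rubric import EvidenceAssignment, Rubric

__all__ = [
    "ReviewFlag",
    "assign_section1",
    "assign_section2",
    "assign_section3",
    "assign_all",
]

# biotypes that count as genomic content for section 1
CONTENT_BIOTYPES = ("protein_coding", "other_functional_element")


@dataclass(frozen=True)
class ReviewFlag:
    """A request for human review, naming the region that triggered it."""

    cnv_id: str
    code: str  # e.g. "partial_dosage_overlap", "uncurated_region"
    region_name: str
    message: str = ""


def assign_section1(cnv: CNVCall, ann: AnnotationSet, rubric: Rubric) -> EvidenceAssignment:
    """Content (1A) when the CNV overlaps a protein-coding gene or other
    known functional element by >= 1 bp; no-content (1B) otherwise."""
    hits = ann.genes_overlapping(cnv.interval, biotypes=CONTENT_BIOTYPES)
    cat = rubric.by_role("content" if hits else "no_content")
    just = (
        f"overlaps {len(hits)} protein-coding/functional element(s)"
        if hits
        else "no protein-coding gene or known functional element overlapped"
    )
    return EvidenceAssignment(cat.code, cat.default_points, just, provenance="auto")


def _hi_roles(dosage_type: str) -> tuple[str, ...]:
    return ("HI_gene", "HI_region") if dosage_type == "loss" else ("TS_gene", "TS_region")


def assign_section2(
    cnv: CNVCall, ann: AnnotationSet, rubric: Rubric
) -> tuple[list[EvidenceAssignment], list[ReviewFlag]]:
    """Dosage-sensitivity and benign-region evidence.

    Loss: full containment of an established HI gene/region scores the
    full-overlap category; containment within an established benign region
    scores the benign category; partial dosage overlaps flag for review.

    Gain: full containment of an established TS gene/region scores the
    full-overlap category; a breakpoint inside an established HI gene scores
    the breakpoint category (2K); a gain spanning an HI gene without
    disrupting it scores the non-disruptive category (2J) — never both.

    Uncurated regions never contribute points, only flags.
    """
    assignments: list[EvidenceAssignment] = []
    flags: list[ReviewFlag] = []
    dosage_roles = _hi_roles(cnv.dosage_type)

    # established (curated) dosage-sensitive regions of the matching mechanism
    full_hits = []
    partial_hits = []
    for reg in ann.regions_overlapping(cnv.interval, roles=dosage_roles, curated=True):
        if contains(cnv.interval, reg.interval):
            full_hits.append(reg)
        else:
            partial_hits.append(reg)
    if full_hits:
        cat = rubric.by_role("dosage_full_overlap")
        names = ",".join(r.name for r in full_hits)
        assignments.append(
            EvidenceAssignment(
                cat.code, cat.default_points, f"complete overlap of {names}", "auto"
            )
        )
    for reg in partial_hits:
        flags.append(
            ReviewFlag(
                cnv.id,
                "partial_dosage_overlap",
                reg.name,
                f"partial overlap of established {reg.role} {reg.name}; review content",
            )
        )

    # established benign regions: containment of the CNV within the region
    for reg in ann.regions_overlapping(cnv.interval, roles=("benign_region",), curated=True):
        if contains(reg.interval, cnv.interval):
            cat = rubric.by_role("benign_containment")
            assignments.append(
                EvidenceAssignment(
                    cat.code,
                    cat.default_points,
                    f"completely contained within benign region {reg.name}",
                    "auto",
                )
            )
            break
        flags.append(
            ReviewFlag(
                cnv.id,
                "partial_benign_overlap",
                reg.name,
                f"overlaps benign region {reg.name} without containment; review",
            )
        )

    # gains over HI genes: breakpoint reading (2K) vs non-disruptive span (2J)
    if cnv.dosage_type == "gain":
        hi_genes = ann.regions_overlapping(cnv.interval, roles=("HI_gene",), curated=True)
        bp_hit = None
        spanned = None
        for reg in hi_genes:
            # a breakpoint coordinate equal to a gene boundary counts as
            # inside: single-base resolution of clinical calls is unreliable
            bp_inside = any(
                reg.interval.start <= bp <= reg.interval.end for bp in cnv.breakpoints
            )
            if bp_inside:
                bp_hit = bp_hit or reg
            elif contains(cnv.interval, reg.interval):
                spanned = spanned or reg
        if bp_hit is not None:
            cat = rubric.by_role("gain_breakpoint_in_hi")
            assignments.append(
                EvidenceAssignment(
                    cat.code,
                    cat.default_points,
                    f"breakpoint within established HI gene {bp_hit.name}",
                    "auto",
                )
            )
        elif spanned is not None:
            cat = rubric.by_role("gain_spans_hi")
            assignments.append(
                EvidenceAssignment(
                    cat.code,
                    cat.default_points,
                    f"spans established HI gene {spanned.name} without disruption",
                    "auto",
                )
            )

    # uncurated reports overlapping the CNV: flag only, never points
    for reg in ann.regions_overlapping(cnv.interval, curated=False):
        if overlap_bp(reg.interval, cnv.interval) > 0:
            flags.append(
                ReviewFlag(
                    cnv.id,
                    "uncurated_region",
                    reg.name,
                    f"uncurated report {reg.name} ({reg.role}) overlaps; "
                    "not applied as established evidence",
                )
            )
    return assignments, flags


def assign_section3(
    cnv: CNVCall,
    ann: AnnotationSet,
    rubric: Rubric,
    collapse_families: bool = False,
) -> EvidenceAssignment:
    """Protein-coding gene count mapped through the rubric's count bins."""
    hits = [
        g
        for g in genes_in(cnv, ann, collapse_families=collapse_families)
        if g.biotype == "protein_coding"
    ]
    n = len(hits)
    cat = rubric.gene_count_category(n)
    just = f"{n} protein-coding gene(s) counted (collapse_families={collapse_families})"
    return EvidenceAssignment(cat.code, cat.default_points, just, provenance="auto")


def assign_all(
    cnv: CNVCall,
    ann: AnnotationSet,
    rubric: Rubric,
    collapse_families: bool = False,
) -> tuple[list[EvidenceAssignment], list[ReviewFlag]]:
    """Sections 1-3 in order; deterministic for identical inputs."""
    s1 = assign_section1(cnv, ann, rubric)
    s2, flags = assign_section2(cnv, ann, rubric)
    s3 = assign_section3(cnv, ann, rubric, collapse_families=collapse_families)
    return [s1, *s2, s3], flags
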