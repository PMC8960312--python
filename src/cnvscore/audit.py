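"""Re-evaluation bookkeeping: initial vs final discordance patterns and
reason tagging.

Reason codes form a closed enumeration mapped to rubric sections 1-4; they
are assigned by human reviewers (or by the simulator) and tallied verbatim —
this module never infers reasons from score differences. Pattern keys are
label SETS (order- and multiplicity-insensitive), so "P or VUS" is one
pattern regardless of how many laboratories chose each side.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .concordance import conflict_class

__all__ = [
    "REASON_SECTIONS",
    "ReviewRecord",
    "ReviewGroup",
    "ReviewSummary",
    "tabulate_review",
    "reason_summary",
]

# closed reason vocabulary -> implicated rubric section
REASON_SECTIONS: dict[str, int] = {
    "S1_CONTENT_MISAPPLIED": 1,
    "S2_REGION_EVAL_ERROR": 2,
    "S2_AR_GENE_DIRECT_2A": 2,
    "S2_UNCURATED_SYNDROME": 2,
    "S2_POINT_DISAGREEMENT": 2,
    "S2_PHENOTYPE_2J_2K": 2,
    "S3_GENE_FAMILY": 3,
    "S4_GENE_OF_INTEREST": 4,
    "S4_CASE_DATA_SCRUTINY": 4,
    "S4_CASE_DATA_USE": 4,
    "S4_WEIGHT_UP_DOWN": 4,
    "S4_CASE_CONTROL_POP": 4,
    "S4_PHENOTYPE_SPECIFICITY": 4,
    "S4_SEGREGATION": 4,
    "S4_DE_NOVO": 4,
    "S4_IMPRINT_PENETRANCE": 4,
}


def reason_section(code: str) -> int:
    try:
        return REASON_SECTIONS[code]
    except KeyError:
        raise ValueError(f"unknown discordance reason code {code!r}")


@dataclass(frozen=True)
class ReviewRecord:
    """One re-evaluated CNV: initial pattern, final pattern, reason tags.

    ``forced_review=True`` marks a CNV re-reviewed despite complete initial
    concordance; otherwise the initial pattern must be discordant.
    """

    cnv_id: str
    dosage_type: str
    initial_labels: frozenset[str]
    final_labels: frozenset[str]
    reasons: frozenset[str] = frozenset()
    forced_review: bool = False

    def __post_init__(self) -> None:
        if self.dosage_type not in ("loss", "gain"):
            raise ValueError(f"bad dosage_type {self.dosage_type!r}")
        for code in self.reasons:
            reason_section(code)
        if not self.initial_labels or not self.final_labels:
            raise ValueError(f"{self.cnv_id}: label sets must be non-empty")
        if conflict_class(self.initial_labels) == "complete" and not self.forced_review:
            raise ValueError(
                f"{self.cnv_id}: initially concordant record must be forced_review"
            )

    @property
    def resolved(self) -> bool:
        return len(self.final_labels) == 1

    @property
    def final_class(self) -> Optional[str]:
        return next(iter(self.final_labels)) if self.resolved else None


@dataclass
class ReviewGroup:
    """All records sharing a dosage type and initial pattern."""

    dosage_type: str
    initial_pattern: frozenset[str]
    count: int
    resolved_classes: Counter  # agreed class -> count
    final_patterns: Counter  # frozenset pattern -> count (still discordant)

    @property
    def n_resolved(self) -> int:
        return sum(self.resolved_classes.values())

    @property
    def n_discordant(self) -> int:
        return sum(self.final_patterns.values())


@dataclass
class ReviewSummary:
    groups: list[ReviewGroup]
    totals: dict[str, tuple[int, int, int]]  # dosage_type -> (n, resolved, discordant)

    @property
    def n_records(self) -> int:
        return sum(t[0] for t in self.totals.values())

    @property
    def n_final_complete(self) -> int:
        return sum(t[1] for t in self.totals.values())

    def final_patterns(self) -> Counter:
        """All final patterns (resolved ones as singleton sets) with counts."""
        out: Counter = Counter()
        for g in self.groups:
            for cls, k in g.resolved_classes.items():
                out[frozenset([cls])] += k
            for pat, k in g.final_patterns.items():
                out[pat] += k
        return out

    def format(self) -> str:
        def pat_str(p: frozenset) -> str:
            order = {"P": 0, "LP": 1, "VUS": 2, "LB": 3, "B": 4}
            return " or ".join(sorted(p, key=order.get))

        lines = ["dosage_type\tinitial_pattern\tn\tfinal_complete\tfinal_discordant"]
        for g in self.groups:
            res = "; ".join(f"{c} {k}" for c, k in sorted(g.resolved_classes.items()))
            dis = "; ".join(
                f"{pat_str(p)} {k}" for p, k in sorted(g.final_patterns.items(), key=str)
            )
            lines.append(
                f"{g.dosage_type}\t{pat_str(g.initial_pattern)}\t{g.count}\t{res}\t{dis}"
            )
        for dt, (n, res, dis) in sorted(self.totals.items()):
            lines.append(f"{dt}\ttotal\t{n}\t{res}\t{dis}")
        return "\n".join(lines)


def tabulate_review(records: Sequence[ReviewRecord]) -> ReviewSummary:
    """Group records by (dosage type, initial pattern) and tabulate final
    outcomes; every group satisfies count = resolved + still-discordant."""
    if not records:
        raise ValueError("no review records")
    keyed: dict[tuple[str, frozenset[str]], list[ReviewRecord]] = {}
    for r in records:
        keyed.setdefault((r.dosage_type, r.initial_labels), []).append(r)
    groups = []
    totals: dict[str, list[int]] = {}
    for (dt, pattern), recs in sorted(keyed.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))):
        resolved = Counter(r.final_class for r in recs if r.resolved)
        discordant = Counter(r.final_labels for r in recs if not r.resolved)
        groups.append(ReviewGroup(dt, pattern, len(recs), resolved, discordant))
        t = totals.setdefault(dt, [0, 0, 0])
        t[0] += len(recs)
        t[1] += sum(resolved.values())
        t[2] += sum(discordant.values())
    return ReviewSummary(
        groups=groups, totals={dt: tuple(v) for dt, v in totals.items()}
    )


def reason_summary(records: Sequence[ReviewRecord]) -> dict[str, tuple[int, float]]:
    """Bucket records by the exact set of rubric sections their reasons
    implicate; returns bucket -> (count, fraction of records)."""
    if not records:
        return {}
    buckets: Counter = Counter()
    for r in records:
        if not r.reasons:
            raise ValueError(f"{r.cnv_id}: record has no reason tags")
        sections = sorted({reason_section(c) for c in r.reasons})
        if len(sections) == 1:
            label = f"Section {sections[0]} alone"
        else:
            label = " + ".join(f"Section {s}" for s in sections)
        buckets[label] += 1
    n = len(records)
    return {label: (k, k / n) for label, k in sorted(buckets.items())}
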