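"""Inter-laboratory classification comparison taxonomy and summaries.

A multiset of five-tier labels for one CNV falls into exactly one conflict
class:

* ``complete`` — every laboratory assigned the identical class;
* ``management_impact`` — P or LP co-occurs with any of VUS/LB/B (could
  change medical management);
* ``ror_impact`` — VUS co-occurs with LB or B (could change whether the
  result is returned);
* ``confidence_difference`` — disagreement confined to P vs LP or to LB vs
  B (same clinical recommendation).

Severity precedence for mixed sets is management > ROR > confidence.
Percentages are reported as round-half-up integers alongside exact
fractions, e.g. ``76% (177/234)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .rubric import CLASSES

__all__ = [
    "CONFLICT_CLASSES",
    "ClassificationMatrix",
    "ConcordanceSummary",
    "conflict_class",
    "partition_counts",
    "summarize",
    "compare_rates",
    "percent",
    "pool_counts",
]

CONFLICT_CLASSES = (
    "complete",
    "confidence_difference",
    "management_impact",
    "ror_impact",
)

_PATHOGENIC = {"P", "LP"}
_BENIGN = {"LB", "B"}


def _check_labels(labels: Iterable[str]) -> list[str]:
    out = list(labels)
    bad = [x for x in out if x not in CLASSES]
    if bad:
        raise ValueError(f"labels outside five-tier vocabulary: {bad}")
    return out


def conflict_class(labels: Iterable[str]) -> str:
    """Classify a non-empty multiset of five-tier labels (see module docs)."""
    lab = set(_check_labels(labels))
    if not lab:
        raise ValueError("empty label set")
    if len(lab) == 1:
        return "complete"
    if lab & _PATHOGENIC and lab & ({"VUS"} | _BENIGN):
        return "management_impact"
    if "VUS" in lab and lab & _BENIGN:
        return "ror_impact"
    return "confidence_difference"


def partition_counts(
    patterns: Sequence[tuple[Iterable[str], int]],
) -> dict[str, int]:
    """Tally (label-set, count) pairs into conflict classes."""
    out = {c: 0 for c in CONFLICT_CLASSES}
    for labels, count in patterns:
        if count < 0:
            raise ValueError("pattern counts must be non-negative")
        out[conflict_class(labels)] += count
    return out


def percent(k: int, n: int) -> int:
    """Integer percentage with round-half-up, e.g. 177/234 -> 76."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(
        (Decimal(k) * 100 / Decimal(n)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def pool_counts(pairs: Iterable[tuple[int, int]]) -> tuple[int, int]:
    """Sum (numerator, denominator) pairs into one pooled fraction."""
    k = n = 0
    for ki, ni in pairs:
        k += ki
        n += ni
    return k, n


def format_rate(k: int, n: int) -> str:
    return f"{percent(k, n)}% ({k}/{n})"


@dataclass
class ClassificationMatrix:
    """CNV x laboratory grid of five-tier classifications.

    ``cells`` maps ``(cnv_id, lab_id)`` to a label. Laboratories with no call
    for a CNV are simply absent and get dropped from that row before
    analysis. ``metadata`` optionally carries per-CNV fields such as
    ``dosage_type``, ``recurrent``, ``panel``, ``phase``.
    """

    cnv_ids: list[str]
    lab_ids: list[str]
    cells: dict[tuple[str, str], str]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cnv_set, lab_set = set(self.cnv_ids), set(self.lab_ids)
        for (cnv, lab), v in self.cells.items():
            if v not in CLASSES:
                raise ValueError(f"cell ({cnv}, {lab}) has invalid label {v!r}")
            if cnv not in cnv_set or lab not in lab_set:
                raise ValueError(f"cell ({cnv}, {lab}) outside declared axes")

    def row(self, cnv_id: str) -> list[str]:
        return [
            self.cells[(cnv_id, lab)]
            for lab in self.lab_ids
            if (cnv_id, lab) in self.cells
        ]


@dataclass
class ConcordanceSummary:
    n_cnvs: int
    counts: dict[str, int]  # conflict class -> count
    complete_by_class: dict[str, int]  # agreed class -> count of complete rows
    breakdowns: dict[str, "ConcordanceSummary"] = field(default_factory=dict)

    @property
    def rates(self) -> dict[str, Fraction]:
        return {c: Fraction(k, self.n_cnvs) for c, k in self.counts.items()}

    @property
    def complete_rate(self) -> Fraction:
        return Fraction(self.counts["complete"], self.n_cnvs)

    @property
    def clinically_meaningful_rate(self) -> Fraction:
        k = self.counts["complete"] + self.counts["confidence_difference"]
        return Fraction(k, self.n_cnvs)

    def format(self) -> str:
        lines = [f"n_cnvs\t{self.n_cnvs}"]
        for c in CONFLICT_CLASSES:
            lines.append(f"{c}\t{self.counts[c]}\t{format_rate(self.counts[c], self.n_cnvs)}")
        k = self.counts["complete"] + self.counts["confidence_difference"]
        lines.append(f"clinically_meaningful\t{k}\t{format_rate(k, self.n_cnvs)}")
        for cls in CLASSES:
            lines.append(f"complete_{cls}\t{self.complete_by_class.get(cls, 0)}")
        return "\n".join(lines)


def _summarize_rows(rows: Mapping[str, list[str]]) -> tuple[dict[str, int], dict[str, int]]:
    counts = {c: 0 for c in CONFLICT_CLASSES}
    complete_by_class: dict[str, int] = {c: 0 for c in CLASSES}
    for cnv_id, labels in rows.items():
        if not labels:
            raise ValueError(f"CNV {cnv_id} has no laboratory calls")
        cc = conflict_class(labels)
        counts[cc] += 1
        if cc == "complete":
            complete_by_class[labels[0]] += 1
    return counts, complete_by_class


def summarize(
    matrix: ClassificationMatrix,
    breakdown_keys: Sequence[str] = (),
) -> ConcordanceSummary:
    """Per-CNV conflict classification and aggregate rates.

    ``breakdown_keys`` selects per-CNV metadata fields (e.g. ``dosage_type``)
    to produce nested sub-summaries keyed ``"<field>=<value>"``.
    """
    if not matrix.cnv_ids:
        raise ValueError("empty classification matrix")
    rows = {cnv: matrix.row(cnv) for cnv in matrix.cnv_ids}
    counts, complete_by_class = _summarize_rows(rows)
    summary = ConcordanceSummary(
        n_cnvs=len(matrix.cnv_ids),
        counts=counts,
        complete_by_class=complete_by_class,
    )
    for key in breakdown_keys:
        values = sorted(
            {str(matrix.metadata.get(c, {}).get(key)) for c in matrix.cnv_ids}
        )
        for val in values:
            subset = [
                c
                for c in matrix.cnv_ids
                if str(matrix.metadata.get(c, {}).get(key)) == val
            ]
            sub_rows = {c: rows[c] for c in subset}
            if not sub_rows:
                continue
            sc, sb = _summarize_rows(sub_rows)
            summary.breakdowns[f"{key}={val}"] = ConcordanceSummary(
                n_cnvs=len(subset), counts=sc, complete_by_class=sb
            )
    return summary


def compare_rates(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Pearson chi-square (no continuity correction) on [[k1,n1-k1],[k2,n2-k2]].

    Returns (statistic, p_value, significant_at_alpha). Raises if any
    expected cell count is zero, where an exact test would be required.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("require 0 <= k <= n and n >= 1")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n = a + b + c + d
    for row in (a + b, c + d):
        for col in (a + c, b + d):
            if row * col == 0:
                raise ValueError(
                    "zero expected cell count; use an exact test instead"
                )
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, p < alpha
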