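"""Data-driven point-based scoring rubric for CNV classification.

A :class:`Rubric` is a table of evidence categories (sections 1-5), each with
default/min/max points, plus five-tier classification thresholds. The shipped
defaults live in ``data/loss_rubric.yaml`` and ``data/gain_rubric.yaml``;
custom rubrics load from the same YAML schema. Totals are summed exactly and
classified on the unrounded value; display rounding happens in reports only.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .genome import CNVCall, ValidationError

__all__ = [
    "EvidenceCategory",
    "ClassificationThresholds",
    "Rubric",
    "EvidenceAssignment",
    "ScoreResult",
    "RubricConfigError",
    "load_rubric",
    "dump_rubric",
    "validate_assignment",
    "total_score",
    "classify",
    "score_cnv",
    "CLASSES",
]

CLASSES = ("P", "LP", "VUS", "LB", "B")

POINT_TOL = 1e-9


class RubricConfigError(ValueError):
    """Raised for malformed rubric configuration."""


@dataclass(frozen=True)
class EvidenceCategory:
    code: str
    section: int
    rubric: str  # "loss" | "gain"
    default_points: float
    min_points: float
    max_points: float
    description: str = ""
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.section not in (1, 2, 3, 4, 5):
            raise RubricConfigError(f"{self.code}: section must be 1-5")
        if not (
            self.min_points - POINT_TOL
            <= self.default_points
            <= self.max_points + POINT_TOL
        ):
            raise RubricConfigError(
                f"{self.code}: require min <= default <= max, got "
                f"[{self.min_points}, {self.default_points}, {self.max_points}]"
            )


@dataclass(frozen=True)
class ClassificationThresholds:
    """Five-tier cut points; the open interval (lb_max, lp_min) is VUS."""

    p_min: float = 0.99
    lp_min: float = 0.90
    lb_max: float = -0.90
    b_max: float = -0.99

    def __post_init__(self) -> None:
        if not (self.b_max < self.lb_max < self.lp_min < self.p_min):
            raise RubricConfigError(
                "thresholds must satisfy b_max < lb_max < lp_min < p_min"
            )


@dataclass(frozen=True)
class EvidenceAssignment:
    """Points applied for one category by one evaluator."""

    category_code: str
    points: float
    justification: str = ""
    provenance: str = "manual"  # "auto" | "manual"

    def __post_init__(self) -> None:
        if self.provenance not in ("auto", "manual"):
            raise ValidationError(f"bad provenance {self.provenance!r}")


@dataclass
class Rubric:
    dosage_type: str
    categories: dict[str, EvidenceCategory]
    thresholds: ClassificationThresholds
    gene_count_bins: list[tuple[Optional[int], str]] = field(default_factory=list)
    exclusive_groups: list[frozenset[str]] = field(default_factory=list)
    section_caps: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sections = {c.section for c in self.categories.values()}
        missing = set(range(1, 6)) - sections
        if missing:
            raise RubricConfigError(f"rubric missing sections: {sorted(missing)}")
        s1_roles = [
            c.role
            for c in self.categories.values()
            if c.section == 1 and c.role in ("content", "no_content")
        ]
        if sorted(filter(None, s1_roles)) != ["content", "no_content"]:
            raise RubricConfigError(
                "rubric needs exactly one content/no_content pair in section 1"
            )

    def get(self, code: str) -> EvidenceCategory:
        try:
            return self.categories[code]
        except KeyError:
            raise KeyError(f"unknown category code {code!r} in {self.dosage_type} rubric")

    def __contains__(self, code: str) -> bool:
        return code in self.categories

    def by_role(self, role: str) -> EvidenceCategory:
        hits = [c for c in self.categories.values() if c.role == role]
        if len(hits) != 1:
            raise KeyError(f"no unique category with role {role!r}")
        return hits[0]

    def gene_count_category(self, n_genes: int) -> EvidenceCategory:
        """Map a protein-coding gene count through the section-3 bins."""
        if n_genes < 0:
            raise ValidationError("gene count must be non-negative")
        for max_count, code in self.gene_count_bins:
            if max_count is None or n_genes <= max_count:
                return self.get(code)
        raise RubricConfigError("gene_count_bins do not cover all counts")


def _parse_config(data: dict, source: str) -> Rubric:
    try:
        dosage_type = data["dosage_type"]
        thr = data["thresholds"]
        raw_cats = data["categories"]
    except KeyError as e:
        raise RubricConfigError(f"{source}: missing required key {e}")
    if dosage_type not in ("loss", "gain"):
        raise RubricConfigError(f"{source}: dosage_type must be loss or gain")
    thresholds = ClassificationThresholds(
        p_min=float(thr["p_min"]),
        lp_min=float(thr["lp_min"]),
        lb_max=float(thr["lb_max"]),
        b_max=float(thr["b_max"]),
    )
    categories: dict[str, EvidenceCategory] = {}
    for rec in raw_cats:
        code = str(rec["code"])
        if code in categories:
            raise RubricConfigError(f"{source}: duplicate category code {code}")
        categories[code] = EvidenceCategory(
            code=code,
            section=int(rec["section"]),
            rubric=dosage_type,
            default_points=float(rec["default"]),
            min_points=float(rec["min"]),
            max_points=float(rec["max"]),
            description=str(rec.get("description", "")),
            role=rec.get("role"),
        )
    bins: list[tuple[Optional[int], str]] = []
    for b in data.get("gene_count_bins", []):
        mc = b.get("max_count")
        code = str(b["code"])
        if code not in categories:
            raise RubricConfigError(f"{source}: gene_count_bins references unknown {code}")
        bins.append((None if mc is None else int(mc), code))
    # bins must be sorted with the open-ended bin last
    finite = [m for m, _ in bins if m is not None]
    if bins and (sorted(finite) != finite or (None in [m for m, _ in bins[:-1]])):
        raise RubricConfigError(f"{source}: gene_count_bins must be ascending, open bin last")
    groups = [frozenset(map(str, g)) for g in data.get("exclusive_groups", [])]
    for g in groups:
        for code in g:
            if code not in categories:
                raise RubricConfigError(f"{source}: exclusive group references unknown {code}")
    caps = {int(k): float(v) for k, v in (data.get("section_caps") or {}).items()}
    return Rubric(
        dosage_type=dosage_type,
        categories=categories,
        thresholds=thresholds,
        gene_count_bins=bins,
        exclusive_groups=groups,
        section_caps=caps,
    )


def _default_config_text(dosage_type: str) -> str:
    fname = f"{dosage_type}_rubric.yaml"
    return resources.files("cnvscore.data").joinpath(fname).read_text(encoding="utf-8")


def load_rubric(
    dosage_type: str, config: Union[str, Path, None] = None
) -> Rubric:
    """Load the shipped default rubric, or a custom YAML config.

    The returned rubric's ``dosage_type`` must match the requested one; a
    mismatching config is a configuration error.
    """
    if dosage_type not in ("loss", "gain"):
        raise RubricConfigError(f"dosage_type must be loss or gain, got {dosage_type!r}")
    if config is None:
        text = _default_config_text(dosage_type)
        source = f"builtin:{dosage_type}"
    else:
        text = Path(config).read_text(encoding="utf-8")
        source = str(config)
    data = yaml.safe_load(text)
    rubric = _parse_config(data, source)
    if rubric.dosage_type != dosage_type:
        raise RubricConfigError(
            f"{source}: config is for {rubric.dosage_type}, requested {dosage_type}"
        )
    return rubric


def dump_rubric(rubric: Rubric, path: Union[str, Path]) -> None:
    """Write a rubric back to YAML (round-trips through :func:`load_rubric`)."""
    data = {
        "dosage_type": rubric.dosage_type,
        "thresholds": {
            "p_min": rubric.thresholds.p_min,
            "lp_min": rubric.thresholds.lp_min,
            "lb_max": rubric.thresholds.lb_max,
            "b_max": rubric.thresholds.b_max,
        },
        "gene_count_bins": [
            {"code": code, "max_count": mc} for mc, code in rubric.gene_count_bins
        ],
        "exclusive_groups": [sorted(g) for g in rubric.exclusive_groups],
        "section_caps": {str(k): v for k, v in rubric.section_caps.items()},
        "categories": [
            {
                "code": c.code,
                "section": c.section,
                "role": c.role,
                "default": c.default_points,
                "min": c.min_points,
                "max": c.max_points,
                "description": c.description,
            }
            for c in rubric.categories.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def rubric_checksum(rubric: Rubric) -> str:
    """SHA-256 over the canonical category table, for report traceability."""
    h = hashlib.sha256()
    for code in sorted(rubric.categories):
        c = rubric.categories[code]
        h.update(
            f"{c.code}|{c.section}|{c.default_points}|{c.min_points}|{c.max_points}\n".encode()
        )
    t = rubric.thresholds
    h.update(f"{t.p_min}|{t.lp_min}|{t.lb_max}|{t.b_max}".encode())
    return h.hexdigest()[:12]


def validate_assignment(rubric: Rubric, a: EvidenceAssignment) -> EvidenceAssignment:
    """Accept an assignment iff its category exists and points are in range."""
    if a.category_code not in rubric:
        raise ValidationError(
            f"unknown category code {a.category_code!r} for {rubric.dosage_type} rubric"
        )
    cat = rubric.get(a.category_code)
    if not (cat.min_points - POINT_TOL <= a.points <= cat.max_points + POINT_TOL):
        raise ValidationError(
            f"{a.category_code}: points {a.points} outside allowed range "
            f"[{cat.min_points}, {cat.max_points}]"
        )
    return a


def total_score(assignments: Sequence[EvidenceAssignment]) -> float:
    """Sum of assignment points; at most one assignment per category code."""
    seen: set[str] = set()
    for a in assignments:
        if a.category_code in seen:
            raise ValidationError(f"duplicate assignment for category {a.category_code}")
        seen.add(a.category_code)
    return math.fsum(a.points for a in assignments)


def classify(total: float, thresholds: Optional[ClassificationThresholds] = None) -> str:
    """Five-tier classification of a summed point total."""
    t = thresholds or ClassificationThresholds()
    if total >= t.p_min:
        return "P"
    if total >= t.lp_min:
        return "LP"
    if total > t.lb_max:
        return "VUS"
    if total > t.b_max:
        return "LB"
    return "B"


def score_cnv(
    cnv: CNVCall,
    assignments: Sequence[EvidenceAssignment],
    rubric: Rubric,
) -> "ScoreResult":
    """Validate a worksheet against a rubric and classify the CNV.

    Enforces rubric/CNV dosage-type agreement, per-category point ranges,
    one-assignment-per-category, configured exclusive groups, and optional
    per-section caps on summed contribution.
    """
    if rubric.dosage_type != cnv.dosage_type:
        raise ValidationError(
            f"CNV {cnv.id} is a {cnv.dosage_type} but rubric is {rubric.dosage_type}"
        )
    validated = [validate_assignment(rubric, a) for a in assignments]
    codes = {a.category_code for a in validated}
    for group in rubric.exclusive_groups:
        applied = codes & group
        if len(applied) > 1:
            raise ValidationError(
                f"mutually exclusive categories applied together: {sorted(applied)}"
            )
    total = total_score(validated)
    if rubric.section_caps:
        by_section: dict[int, float] = {}
        for a in validated:
            sec = rubric.get(a.category_code).section
            by_section[sec] = by_section.get(sec, 0.0) + a.points
        total = math.fsum(
            min(v, rubric.section_caps[s]) if s in rubric.section_caps else v
            for s, v in by_section.items()
        )
    return ScoreResult(
        cnv_id=cnv.id,
        total_points=total,
        classification=classify(total, rubric.thresholds),
        assignments=list(validated),
    )


@dataclass
class ScoreResult:
    cnv_id: str
    total_points: float
    classification: str
    assignments: list[EvidenceAssignment]

    @property
    def display_total(self) -> str:
        return f"{self.total_points:.2f}"
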