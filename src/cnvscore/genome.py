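"""Genomic coordinate arithmetic and CNV/annotation data model.

All coordinates are 1-based inclusive. BED input (0-based half-open) is
converted at the I/O boundary; GFF3 passes through unchanged. Chromosome
labels are normalized by stripping a leading ``chr`` prefix and upper-casing
``x``/``y``; strand is ignored throughout because dosage effects are
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "GenomicInterval",
    "CNVCall",
    "GeneFeature",
    "RegionRecord",
    "AnnotationSet",
    "overlap_bp",
    "contains",
    "size_class",
    "genes_in",
    "SIZE_CLASSES",
    "ValidationError",
]

VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}

SIZE_CLASSES = ("<1 Mb", "1-5 Mb", "5-10 Mb", ">10 Mb")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) and upper-case."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c not in VALID_CHROMS:
        raise ValidationError(f"invalid chromosome label: {chrom!r}")
    return c


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval on one chromosome."""

    chrom: str
    start: int
    end: int
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValidationError("start/end must be integers")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"require 1 <= start <= end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies completely within ``outer`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def size_class(length: int) -> str:
    """Map an interval length in bp to its size bin.

    1 Mb belongs to "1-5 Mb" and 10 Mb to "5-10 Mb" (boundaries are closed on
    the left of each bin; the top bin is strictly greater than 10 Mb).
    """
    if length <= 0:
        raise ValidationError("length must be positive")
    if length < 1_000_000:
        return "<1 Mb"
    if length < 5_000_000:
        return "1-5 Mb"
    if length <= 10_000_000:
        return "5-10 Mb"
    return ">10 Mb"


@dataclass(frozen=True)
class CNVCall:
    """One copy-number loss or gain.

    ``dosage_type`` is ``loss`` or ``gain``. ``copy_number``, when given for an
    autosomal call, must be consistent with the dosage type (loss => CN < 2,
    gain => CN > 2). ``band`` carries a free-text cytoband label and is never
    parsed.
    """

    id: str
    interval: GenomicInterval
    dosage_type: str
    copy_number: Optional[int] = None
    recurrent: Optional[bool] = None
    band: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dosage_type not in ("loss", "gain"):
            raise ValidationError(
                f"dosage_type must be 'loss' or 'gain', got {self.dosage_type!r}"
            )
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise ValidationError("copy_number must be non-negative")
            if self.interval.chrom not in ("X", "Y"):
                if self.dosage_type == "loss" and self.copy_number >= 2:
                    raise ValidationError(
                        f"loss with autosomal copy_number {self.copy_number}"
                    )
                if self.dosage_type == "gain" and self.copy_number <= 2:
                    raise ValidationError(
                        f"gain with autosomal copy_number {self.copy_number}"
                    )

    @property
    def size_class(self) -> str:
        return size_class(self.interval.length)

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.interval.start, self.interval.end)


@dataclass(frozen=True)
class GeneFeature:
    """A gene (or other annotated element) with an optional family label."""

    symbol: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    family_id: Optional[str] = None

    BIOTYPES = ("protein_coding", "other_functional_element", "other")

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")
        if self.biotype not in self.BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")


REGION_ROLES = ("HI_gene", "HI_region", "TS_gene", "TS_region", "benign_region")


@dataclass(frozen=True)
class RegionRecord:
    """A dosage-sensitivity or benign region.

    ``curated=False`` records (e.g. syndrome regions reported in the literature
    but never formally curated) are never auto-applied as established evidence;
    they can only raise review flags.
    """

    name: str
    interval: GenomicInterval
    role: str
    curated: bool = True

    def __post_init__(self) -> None:
        if self.role not in REGION_ROLES:
            raise ValidationError(f"unknown region role {self.role!r}")


@dataclass
class AnnotationSet:
    """Container for gene and region tracks with interval queries."""

    genes: list[GeneFeature] = field(default_factory=list)
    regions: list[RegionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(
            self.genes, key=lambda g: (g.interval.chrom, g.interval.start, g.symbol)
        )
        self.regions = sorted(
            self.regions, key=lambda r: (r.interval.chrom, r.interval.start, r.name)
        )

    def genes_overlapping(
        self, interval: GenomicInterval, biotypes: Optional[Iterable[str]] = None
    ) -> list[GeneFeature]:
        wanted = set(biotypes) if biotypes is not None else None
        return [
            g
            for g in self.genes
            if overlap_bp(g.interval, interval) > 0
            and (wanted is None or g.biotype in wanted)
        ]

    def regions_overlapping(
        self,
        interval: GenomicInterval,
        roles: Optional[Iterable[str]] = None,
        curated: Optional[bool] = None,
    ) -> list[RegionRecord]:
        wanted = set(roles) if roles is not None else None
        return [
            r
            for r in self.regions
            if overlap_bp(r.interval, interval) > 0
            and (wanted is None or r.role in wanted)
            and (curated is None or r.curated == curated)
        ]


def genes_in(
    cnv: CNVCall, ann: AnnotationSet, collapse_families: bool = False
) -> list[GeneFeature]:
    """Genes overlapping a CNV by >= 1 bp, optionally one per gene family.

    With ``collapse_families`` the first gene (by position) of each family
    represents the whole family; genes without a ``family_id`` always count
    individually. Output is stably sorted by (chrom, start, symbol).
    """
    hits = ann.genes_overlapping(cnv.interval)
    if not collapse_families:
        return hits
    out: list[GeneFeature] = []
    seen_families: set[str] = set()
    for g in hits:
        if g.family_id is None:
            out.append(g)
        elif g.family_id not in seen_families:
            seen_families.add(g.family_id)
            out.append(g)
    return out
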