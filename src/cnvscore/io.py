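"""Readers and writers for the package's external formats.

Native tabular dialect is TSV, UTF-8, with ``.`` for missing optional
fields. Readers locate columns by header name (order-insensitive); writers
emit canonical column order. Coordinates: BED input is 0-based half-open and
converted on read; GFF3 and VCF positions are 1-based and pass through; all
in-memory coordinates are 1-based inclusive. VCF support is read-only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .audit import ReviewRecord
from .concordance import ClassificationMatrix, ConcordanceSummary
from .genome import (
    AnnotationSet,
    CNVCall,
    GeneFeature,
    GenomicInterval,
    RegionRecord,
    ValidationError,
)
from .rubric import CLASSES, EvidenceAssignment, ScoreResult

logger = logging.getLogger("cnvscore")

MISSING = "."

PathLike = Union[str, Path]

__all__ = [
    "read_cnv_table",
    "write_cnv_table",
    "read_cnv_vcf",
    "read_genes_bed",
    "read_genes_gff3",
    "read_regions",
    "write_regions",
    "read_worksheet",
    "write_worksheet",
    "read_matrix",
    "write_matrix",
    "read_summary",
    "write_summary",
    "read_review_records",
    "write_review_records",
    "write_report",
]


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def _opt(value: str) -> Optional[str]:
    return None if value in ("", MISSING) else value


# ---------------------------------------------------------------- CNV tables


def read_cnv_table(path: PathLike) -> list[CNVCall]:
    """TSV columns: id, chrom, start, end, dosage_type; optional copy_number,
    recurrent(0/1), build, band. Mixing genome builds raises."""
    df = _read_tsv(path, ["id", "chrom", "start", "end", "dosage_type"])
    calls: list[CNVCall] = []
    builds: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            build = _opt(row.get("build", "")) or "GRCh37"
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), build)
            cn = _opt(row.get("copy_number", ""))
            rec = _opt(row.get("recurrent", ""))
            calls.append(
                CNVCall(
                    id=row["id"],
                    interval=iv,
                    dosage_type=row["dosage_type"],
                    copy_number=None if cn is None else int(cn),
                    recurrent=None if rec is None else rec in ("1", "true", "True"),
                    band=_opt(row.get("band", "")),
                )
            )
            builds.add(build)
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"{path}, line {line}: {e}") from e
    if len(builds) > 1:
        raise ValidationError(
            f"{path}: mixed genome builds in one panel: {sorted(builds)}"
        )
    return calls


def write_cnv_table(calls: Sequence[CNVCall], path: PathLike) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "id": c.id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "dosage_type": c.dosage_type,
                "copy_number": MISSING if c.copy_number is None else c.copy_number,
                "recurrent": MISSING if c.recurrent is None else int(c.recurrent),
                "build": c.interval.build,
                "band": c.band or MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SVTYPE_MAP = {"DEL": "loss", "DUP": "gain"}


def read_cnv_vcf(path: PathLike) -> list[CNVCall]:
    """Structural-variant VCF records with SVTYPE DEL/DUP and an END field.

    POS/END (1-based) map directly to the inclusive interval. Records with
    other SVTYPEs are skipped with a logged warning count.
    """
    from cyvcf2 import VCF

    calls: list[CNVCall] = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for i, var in enumerate(vcf):
            svtype = var.INFO.get("SVTYPE")
            if svtype not in _SVTYPE_MAP:
                skipped += 1
                continue
            end = var.INFO.get("END")
            if end is None:
                raise ValidationError(
                    f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) lacks END"
                )
            vid = var.ID or f"{var.CHROM}_{var.POS}_{svtype}"
            calls.append(
                CNVCall(
                    id=vid,
                    interval=GenomicInterval(var.CHROM, int(var.POS), int(end)),
                    dosage_type=_SVTYPE_MAP[svtype],
                )
            )
    finally:
        vcf.close()
    if skipped:
        logger.warning("%s: skipped %d record(s) with unsupported SVTYPE", path, skipped)
    return calls


# ---------------------------------------------------------------- annotation


def read_genes_bed(
    path: PathLike,
    family_map: Optional[dict[str, str]] = None,
    biotype: str = "protein_coding",
) -> list[GeneFeature]:
    """BED4+ gene track (0-based half-open -> converted to 1-based inclusive).

    ``family_map`` is an optional sidecar mapping gene symbol -> family_id.
    """
    genes = []
    family_map = family_map or {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}, line {lineno}: need >= 4 BED columns")
            chrom, start0, end0, name = parts[:4]
            try:
                iv = GenomicInterval(chrom, int(start0) + 1, int(end0))
            except (ValueError, ValidationError) as e:
                raise ValidationError(f"{path}, line {lineno}: {e}") from e
            genes.append(
                GeneFeature(name, iv, biotype=biotype, family_id=family_map.get(name))
            )
    return genes


_GFF_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "other_functional_element",
    "lincRNA": "other_functional_element",
    "miRNA": "other_functional_element",
    "snoRNA": "other_functional_element",
    "enhancer": "other_functional_element",
}


def read_genes_gff3(path: PathLike) -> list[GeneFeature]:
    """Gene features from GFF3 (1-based inclusive, passes through).

    Biotype comes from the ``gene_biotype``/``biotype`` attribute; the gene
    symbol from ``Name``/``gene_name``/``ID``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        raw_bt = (
            feat.attributes.get("gene_biotype", feat.attributes.get("biotype", ["other"]))
        )[0]
        symbol = (
            feat.attributes.get("Name", feat.attributes.get("gene_name", [feat.id]))
        )[0]
        family = feat.attributes.get("family_id", [None])[0]
        genes.append(
            GeneFeature(
                symbol,
                GenomicInterval(feat.seqid, feat.start, feat.end),
                biotype=_GFF_BIOTYPE_MAP.get(raw_bt, "other"),
                family_id=family,
            )
        )
    return genes


def read_regions(path: PathLike) -> list[RegionRecord]:
    """Region curation TSV: name, chrom, start, end, role, curated(0/1)."""
    df = _read_tsv(path, ["name", "chrom", "start", "end", "role", "curated"])
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                RegionRecord(
                    name=row["name"],
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    role=row["role"],
                    curated=row["curated"] in ("1", "true", "True"),
                )
            )
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"{path}, line {idx + 2}: {e}") from e
    return out


def write_regions(regions: Sequence[RegionRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "role": r.role,
                "curated": int(r.curated),
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def load_annotation(
    genes_path: Optional[PathLike] = None,
    regions_path: Optional[PathLike] = None,
    family_map: Optional[dict[str, str]] = None,
) -> AnnotationSet:
    """Assemble an AnnotationSet from a gene track (BED or GFF3) and a
    region-curation TSV; either part may be omitted."""
    genes: list[GeneFeature] = []
    if genes_path is not None:
        suffix = Path(genes_path).suffix.lower()
        if suffix in (".gff", ".gff3"):
            genes = read_genes_gff3(genes_path)
        else:
            genes = read_genes_bed(genes_path, family_map=family_map)
    regions = read_regions(regions_path) if regions_path is not None else []
    return AnnotationSet(genes=genes, regions=regions)


# ---------------------------------------------------------------- worksheets


def read_worksheet(path: PathLike) -> dict[tuple[str, str], list[EvidenceAssignment]]:
    """Evidence worksheet TSV: cnv_id, lab_id, category_code, points,
    justification; optional provenance (auto/manual, default manual).
    Returns assignments grouped by (cnv_id, lab_id)."""
    df = _read_tsv(path, ["cnv_id", "lab_id", "category_code", "points"])
    out: dict[tuple[str, str], list[EvidenceAssignment]] = {}
    for idx, row in df.iterrows():
        try:
            a = EvidenceAssignment(
                category_code=row["category_code"],
                points=float(row["points"]),
                justification=_opt(row.get("justification", "")) or "",
                provenance=_opt(row.get("provenance", "")) or "manual",
            )
        except (ValueError, ValidationError) as e:
            raise ValidationError(f"{path}, line {idx + 2}: {e}") from e
        out.setdefault((row["cnv_id"], row["lab_id"]), []).append(a)
    return out


def write_worksheet(
    entries: dict[tuple[str, str], Sequence[EvidenceAssignment]], path: PathLike
) -> None:
    rows = []
    for (cnv_id, lab_id), assignments in entries.items():
        for a in assignments:
            rows.append(
                {
                    "cnv_id": cnv_id,
                    "lab_id": lab_id,
                    "category_code": a.category_code,
                    "points": a.points,
                    "justification": a.justification or MISSING,
                    "provenance": a.provenance,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ matrices


def read_matrix(
    path: PathLike, metadata_path: Optional[PathLike] = None
) -> ClassificationMatrix:
    """Classification matrix TSV: first column cnv_id, one column per lab,
    values in {P,LP,VUS,LB,B} or ``.`` for no call. Optional metadata sidecar
    TSV keyed by cnv_id."""
    df = _read_tsv(path, ["cnv_id"])
    lab_ids = [c for c in df.columns if c != "cnv_id"]
    if not lab_ids:
        raise ValidationError(f"{path}: no laboratory columns")
    cells: dict[tuple[str, str], str] = {}
    cnv_ids = list(df["cnv_id"])
    for idx, row in df.iterrows():
        for lab in lab_ids:
            v = row[lab]
            if v in ("", MISSING):
                continue
            if v not in CLASSES:
                raise ValidationError(
                    f"{path}: invalid label {v!r} at (cnv {row['cnv_id']}, lab {lab})"
                )
            cells[(row["cnv_id"], lab)] = v
    metadata: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = _read_tsv(metadata_path, ["cnv_id"])
        for _, row in mdf.iterrows():
            metadata[row["cnv_id"]] = {
                k: _opt(v) for k, v in row.items() if k != "cnv_id"
            }
    return ClassificationMatrix(cnv_ids, lab_ids, cells, metadata)


def write_matrix(matrix: ClassificationMatrix, path: PathLike) -> None:
    rows = []
    for cnv in matrix.cnv_ids:
        row = {"cnv_id": cnv}
        for lab in matrix.lab_ids:
            row[lab] = matrix.cells.get((cnv, lab), MISSING)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- summaries


def _summary_to_dict(s: ConcordanceSummary) -> dict:
    return {
        "n_cnvs": s.n_cnvs,
        "counts": s.counts,
        "complete_by_class": s.complete_by_class,
        "breakdowns": {k: _summary_to_dict(v) for k, v in s.breakdowns.items()},
    }


def _summary_from_dict(d: dict) -> ConcordanceSummary:
    return ConcordanceSummary(
        n_cnvs=d["n_cnvs"],
        counts=dict(d["counts"]),
        complete_by_class=dict(d["complete_by_class"]),
        breakdowns={k: _summary_from_dict(v) for k, v in d.get("breakdowns", {}).items()},
    )


def write_summary(summary: ConcordanceSummary, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(_summary_to_dict(summary), indent=2) + "\n", encoding="utf-8"
    )


def read_summary(path: PathLike) -> ConcordanceSummary:
    return _summary_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# -------------------------------------------------------------- review files


def _parse_labels(raw: str, where: str) -> frozenset[str]:
    labels = frozenset(x.strip() for x in raw.split(",") if x.strip())
    bad = labels - set(CLASSES)
    if bad:
        raise ValidationError(f"{where}: labels outside vocabulary: {sorted(bad)}")
    return labels


def read_review_records(path: PathLike) -> list[ReviewRecord]:
    """Review-record TSV: cnv_id, dosage_type, initial_labels (comma-joined),
    final_labels, reasons (comma-joined codes or ``.``), forced_review(0/1)."""
    df = _read_tsv(path, ["cnv_id", "dosage_type", "initial_labels", "final_labels"])
    out = []
    for idx, row in df.iterrows():
        where = f"{path}, line {idx + 2}"
        reasons_raw = _opt(row.get("reasons", "")) or ""
        reasons = frozenset(x.strip() for x in reasons_raw.split(",") if x.strip())
        try:
            out.append(
                ReviewRecord(
                    cnv_id=row["cnv_id"],
                    dosage_type=row["dosage_type"],
                    initial_labels=_parse_labels(row["initial_labels"], where),
                    final_labels=_parse_labels(row["final_labels"], where),
                    reasons=reasons,
                    forced_review=row.get("forced_review", "0") in ("1", "true", "True"),
                )
            )
        except ValueError as e:
            raise ValidationError(f"{where}: {e}") from e
    return out


def write_review_records(records: Sequence[ReviewRecord], path: PathLike) -> None:
    order = {"P": 0, "LP": 1, "VUS": 2, "LB": 3, "B": 4}
    rows = []
    for r in records:
        rows.append(
            {
                "cnv_id": r.cnv_id,
                "dosage_type": r.dosage_type,
                "initial_labels": ",".join(sorted(r.initial_labels, key=order.get)),
                "final_labels": ",".join(sorted(r.final_labels, key=order.get)),
                "reasons": ",".join(sorted(r.reasons)) or MISSING,
                "forced_review": int(r.forced_review),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- reports


def write_report(results: Sequence[ScoreResult], path: PathLike) -> None:
    """Per-CNV scoring report: total shown to 2 decimals, assignments echoed."""
    rows = []
    for r in results:
        rows.append(
            {
                "cnv_id": r.cnv_id,
                "total_points": r.display_total,
                "classification": r.classification,
                "assignments": ";".join(
                    f"{a.category_code}:{a.points:g}" for a in r.assignments
                )
                or MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
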