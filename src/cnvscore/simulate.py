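"""Synthetic annotation sets, CNV panels, and multi-laboratory simulations.

Everything is generated from an explicit integer seed and is bit-identical
across reruns. Laboratory error modes are per-lab, per-CNV independent
Bernoulli events drawn from random streams split per ``(lab, cnv, mode)``, so
enabling one mode never shifts another mode's draws. Error-mode identifiers
reuse the discordance-reason vocabulary from :mod:`cnvscore.audit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .concordance import ClassificationMatrix
from .evidence import ReviewFlag, assign_all, assign_section3
from .genome import (
    AnnotationSet,
    CNVCall,
    GeneFeature,
    GenomicInterval,
    RegionRecord,
)
from .rubric import (
    EvidenceAssignment,
    Rubric,
    RubricConfigError,
    load_rubric,
    score_cnv,
)

__all__ = [
    "SimulationConfig",
    "TruthWorksheet",
    "ERROR_MODES",
    "generate_annotation",
    "generate_panel",
    "simulate_lab_classifications",
]

# supported error modes, in fixed stream order
ERROR_MODES = (
    "S1_CONTENT_MISAPPLIED",
    "S2_UNCURATED_SYNDROME",
    "S2_PHENOTYPE_2J_2K",
    "S3_GENE_FAMILY",
    "S4_WEIGHT_UP_DOWN",
    "S4_CASE_DATA_USE",
)

# default size-bin weights follow a realistic clinical panel mix
# (bins: <1 Mb, 1-5 Mb, 5-10 Mb, >10 Mb)
DEFAULT_SIZE_WEIGHTS = (77 / 234, 127 / 234, 22 / 234, 8 / 234)

SIZE_BIN_RANGES = (
    (50_000, 999_999),
    (1_000_000, 4_999_999),
    (5_000_000, 10_000_000),
    (10_000_001, 20_000_000),
)

# section-4 categories the truth sampler may draw (defaults applied)
S4_POOL = ("4A", "4B", "4C", "4D", "4E", "4L", "4M", "4N")

S4_STEP = 0.15  # one-step weight perturbation for S4_WEIGHT_UP_DOWN


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_cnvs: int = 234
    recurrent_fraction: float = 0.40
    size_distribution: tuple[float, float, float, float] = DEFAULT_SIZE_WEIGHTS
    n_labs: int = 9
    error_rates: dict[str, float] = field(default_factory=dict)
    n_genes: int = 300
    n_chromosomes: int = 4
    chrom_length: int = 60_000_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.recurrent_fraction <= 1:
            raise ValueError("recurrent_fraction must be in [0, 1]")
        if abs(sum(self.size_distribution) - 1.0) > 1e-9:
            raise ValueError("size_distribution weights must sum to 1")
        for mode, rate in self.error_rates.items():
            if mode not in ERROR_MODES:
                raise ValueError(f"unknown error mode {mode!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"error rate for {mode} must be in [0, 1]")
        if self.n_labs < 1 or self.n_cnvs < 1:
            raise ValueError("need at least one lab and one CNV")


@dataclass
class TruthWorksheet:
    """Ground-truth evidence for one CNV plus precomputed error-mode variants."""

    cnv_id: str
    assignments: list[EvidenceAssignment]
    flags: list[ReviewFlag]
    section3_collapsed: EvidenceAssignment
    uncurated_regions: list[str]


def generate_annotation(config: SimulationConfig, seed: Optional[int] = None) -> AnnotationSet:
    """Synthetic chromosomes with genes (some in families), curated HI/TS and
    benign regions, and uncurated syndrome reports. Deterministic per seed."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]
    genes: list[GeneFeature] = []

    n_family_groups = config.n_genes // 50
    n_singletons = config.n_genes - 5 * n_family_groups
    for i in range(max(0, n_singletons)):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(5_000, 200_001))
        start = int(rng.integers(1, config.chrom_length - length))
        biotype = rng.choice(
            ["protein_coding", "other_functional_element", "other"], p=[0.90, 0.05, 0.05]
        )
        genes.append(
            GeneFeature(
                symbol=f"G{i + 1:04d}",
                interval=GenomicInterval(chrom, start, start + length - 1),
                biotype=str(biotype),
            )
        )
    for f in range(n_family_groups):
        chrom = chroms[int(rng.integers(len(chroms)))]
        anchor = int(rng.integers(1, config.chrom_length - 2_000_000))
        for j in range(5):  # five tightly clustered paralogs per family
            start = anchor + j * 60_000
            genes.append(
                GeneFeature(
                    symbol=f"FAM{f + 1}G{j + 1}",
                    interval=GenomicInterval(chrom, start, start + 40_000),
                    biotype="protein_coding",
                    family_id=f"FAM{f + 1}",
                )
            )

    regions: list[RegionRecord] = []
    coding = [g for g in genes if g.biotype == "protein_coding" and g.family_id is None]
    if coding:
        picks = rng.choice(len(coding), size=min(16, len(coding)), replace=False)
        for k, idx in enumerate(picks):
            g = coding[int(idx)]
            role = "HI_gene" if k % 2 == 0 else "TS_gene"
            regions.append(RegionRecord(f"{role}_{g.symbol}", g.interval, role, curated=True))
    for role in ("HI_region", "TS_region"):
        for k in range(2):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(1_000_000, 3_000_001))
            start = int(rng.integers(1, config.chrom_length - length))
            regions.append(
                RegionRecord(
                    f"{role}_{k + 1}",
                    GenomicInterval(chrom, start, start + length - 1),
                    role,
                    curated=True,
                )
            )
    for k in range(4):  # curated benign regions
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(500_000, 2_000_001))
        start = int(rng.integers(1, config.chrom_length - length))
        regions.append(
            RegionRecord(
                f"benign_{k + 1}",
                GenomicInterval(chrom, start, start + length - 1),
                "benign_region",
                curated=True,
            )
        )
    for k in range(3):  # uncurated syndrome reports (flag-only, never points)
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1_000_000, 4_000_001))
        start = int(rng.integers(1, config.chrom_length - length))
        regions.append(
            RegionRecord(
                f"reported_syndrome_{k + 1}",
                GenomicInterval(chrom, start, start + length - 1),
                "HI_region",
                curated=False,
            )
        )
    return AnnotationSet(genes=genes, regions=regions)


def _sample_interval(rng: np.random.Generator, config: SimulationConfig) -> GenomicInterval:
    bin_idx = int(rng.choice(4, p=config.size_distribution))
    lo, hi = SIZE_BIN_RANGES[bin_idx]
    hi = min(hi, config.chrom_length - 1)
    length = int(rng.integers(lo, hi + 1))
    chrom = str(int(rng.integers(config.n_chromosomes)) + 1)
    start = int(rng.integers(1, config.chrom_length - length + 1))
    return GenomicInterval(chrom, start, start + length - 1)


def _sample_section4(
    rng: np.random.Generator, rubric: Rubric
) -> list[EvidenceAssignment]:
    k = int(rng.integers(0, 4))
    if k == 0:
        return []
    codes = rng.choice(len(S4_POOL), size=k, replace=False)
    out = []
    for idx in sorted(int(i) for i in codes):
        cat = rubric.get(S4_POOL[idx])
        out.append(
            EvidenceAssignment(cat.code, cat.default_points, "sampled case evidence", "manual")
        )
    return out


def generate_panel(
    config: SimulationConfig,
    ann: AnnotationSet,
    seed: Optional[int] = None,
) -> tuple[list[CNVCall], dict[str, TruthWorksheet]]:
    """Draw a CNV panel and its ground-truth evidence worksheets.

    Recurrent calls come in loss/gain pairs over the identical interval.
    Truth = deterministic section 1-3 evidence plus sampled section-4 points.
    """
    rng = np.random.default_rng([seed if seed is not None else config.seed, 1])
    rubrics = {dt: load_rubric(dt) for dt in ("loss", "gain")}
    calls: list[CNVCall] = []
    n_pairs = int(round(config.n_cnvs * config.recurrent_fraction / 2))
    for i in range(n_pairs):
        iv = _sample_interval(rng, config)
        calls.append(CNVCall(f"REC{i + 1:03d}_DEL", iv, "loss", recurrent=True))
        calls.append(CNVCall(f"REC{i + 1:03d}_DUP", iv, "gain", recurrent=True))
    for i in range(config.n_cnvs - 2 * n_pairs):
        iv = _sample_interval(rng, config)
        dt = "loss" if rng.random() < 0.5 else "gain"
        calls.append(CNVCall(f"NR{i + 1:04d}", iv, dt, recurrent=False))

    truth: dict[str, TruthWorksheet] = {}
    for cnv in calls:
        rubric = rubrics[cnv.dosage_type]
        assignments, flags = assign_all(cnv, ann, rubric, collapse_families=False)
        collapsed = assign_section3(cnv, ann, rubric, collapse_families=True)
        assignments = assignments + _sample_section4(rng, rubric)
        uncurated = sorted(
            {f.region_name for f in flags if f.code == "uncurated_region"}
        )
        truth[cnv.id] = TruthWorksheet(cnv.id, assignments, flags, collapsed, uncurated)
    return calls, truth


def _mode_streams_seed(base: int, lab: int, cnv: int, mode: str) -> np.random.Generator:
    return np.random.default_rng([base, 2, lab, cnv, ERROR_MODES.index(mode)])


def _check_modes_supported(error_rates: dict[str, float], rubrics: dict[str, Rubric]) -> None:
    needed = {
        "S1_CONTENT_MISAPPLIED": [("loss", "1A"), ("loss", "1B"), ("gain", "1A"), ("gain", "1B")],
        "S2_UNCURATED_SYNDROME": [("loss", "2A"), ("gain", "2A")],
        "S2_PHENOTYPE_2J_2K": [("gain", "2J"), ("gain", "2K")],
    }
    for mode, rate in error_rates.items():
        if rate > 0:
            for dt, code in needed.get(mode, []):
                if code not in rubrics[dt]:
                    raise RubricConfigError(
                        f"error mode {mode} requires category {code} in {dt} rubric"
                    )


def _apply_mode(
    mode: str,
    ws: dict[str, EvidenceAssignment],
    truth: TruthWorksheet,
    rubric: Rubric,
    rng: np.random.Generator,
) -> None:
    """Mutate a worksheet (keyed by category code) with one error mode."""
    if mode == "S1_CONTENT_MISAPPLIED":
        present = "1A" if "1A" in ws else ("1B" if "1B" in ws else None)
        if present:
            other = rubric.get("1B" if present == "1A" else "1A")
            del ws[present]
            ws[other.code] = EvidenceAssignment(
                other.code, other.default_points, "content category inverted", "manual"
            )
    elif mode == "S2_UNCURATED_SYNDROME":
        if truth.uncurated_regions and "2A" not in ws:
            cat = rubric.get("2A")
            ws["2A"] = EvidenceAssignment(
                cat.code,
                cat.default_points,
                f"uncurated report {truth.uncurated_regions[0]} applied as established",
                "manual",
            )
    elif mode == "S2_PHENOTYPE_2J_2K":
        present = "2K" if "2K" in ws else ("2J" if "2J" in ws else None)
        if present:
            other = rubric.get("2J" if present == "2K" else "2K")
            del ws[present]
            ws[other.code] = EvidenceAssignment(
                other.code, other.default_points, "phenotype read swapped", "manual"
            )
    elif mode == "S3_GENE_FAMILY":
        current = next(
            (c for c in ws if rubric.get(c).section == 3), None
        )
        if current is not None:
            del ws[current]
        alt = truth.section3_collapsed
        ws[alt.category_code] = replace(alt, provenance="manual")
    elif mode == "S4_WEIGHT_UP_DOWN":
        s4 = sorted(c for c in ws if rubric.get(c).section == 4)
        if s4:
            code = s4[int(rng.integers(len(s4)))]
            cat = rubric.get(code)
            delta = S4_STEP if rng.random() < 0.5 else -S4_STEP
            pts = min(cat.max_points, max(cat.min_points, ws[code].points + delta))
            ws[code] = replace(ws[code], points=pts, justification="weight perturbed")
    elif mode == "S4_CASE_DATA_USE":
        s4 = sorted(c for c in ws if rubric.get(c).section == 4)
        if s4:
            code = s4[int(rng.integers(len(s4)))]
            del ws[code]
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValueError(f"unknown error mode {mode!r}")


def simulate_lab_classifications(
    panel: Sequence[CNVCall],
    truth: dict[str, TruthWorksheet],
    config: SimulationConfig,
    seed: Optional[int] = None,
    rubrics: Optional[dict[str, Rubric]] = None,
) -> ClassificationMatrix:
    """Score the panel once per laboratory, applying enabled error modes.

    With all error rates at zero every laboratory reproduces the truth
    classification exactly.
    """
    missing = [c.id for c in panel if c.id not in truth]
    if missing:
        raise ValueError(f"truth worksheets missing for: {missing[:5]}")
    base = seed if seed is not None else config.seed
    rubrics = rubrics or {dt: load_rubric(dt) for dt in ("loss", "gain")}
    _check_modes_supported(config.error_rates, rubrics)
    lab_ids = [f"LAB{j + 1}" for j in range(config.n_labs)]
    cells: dict[tuple[str, str], str] = {}
    metadata: dict[str, dict] = {}
    for i, cnv in enumerate(panel):
        rubric = rubrics[cnv.dosage_type]
        metadata[cnv.id] = {
            "dosage_type": cnv.dosage_type,
            "recurrent": cnv.recurrent,
            "size_class": cnv.size_class,
            "panel": "simulated",
            "phase": "metric",
        }
        for j, lab in enumerate(lab_ids):
            ws = {a.category_code: a for a in truth[cnv.id].assignments}
            for mode in ERROR_MODES:
                rate = config.error_rates.get(mode, 0.0)
                if rate <= 0:
                    continue
                rng = _mode_streams_seed(base, j, i, mode)
                if rng.random() < rate:
                    _apply_mode(mode, ws, truth[cnv.id], rubric, rng)
            result = score_cnv(cnv, list(ws.values()), rubric)
            cells[(cnv.id, lab)] = result.classification
    return ClassificationMatrix(
        cnv_ids=[c.id for c in panel],
        lab_ids=lab_ids,
        cells=cells,
        metadata=metadata,
    )
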