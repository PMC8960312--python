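import pytest

from cnvscore.genome import (
    AnnotationSet,
    CNVCall,
    GeneFeature,
    GenomicInterval,
    RegionRecord,
)
from cnvscore.rubric import load_rubric


@pytest.fixture(scope="session")
def loss_rubric():
    return load_rubric("loss")


@pytest.fixture(scope="session")
def gain_rubric():
    return load_rubric("gain")


def iv(chrom, start, end):
    return GenomicInterval(str(chrom), start, end)


@pytest.fixture
def annotation():
    """Small hand-built annotation set on chromosomes 1 and 2.

    chr1: GENE_A (protein-coding, also curated HI gene) at 1_000_000-1_050_000;
    ELEM_B (other functional element) at 2_000_000-2_010_000; OTHER_C
    (biotype other) at 3_000_000-3_010_000; family genes FAM1_1..3 at
    4_000_000+; curated TS gene GENE_D at 5_000_000-5_040_000; curated benign
    region at 8_000_000-9_000_000; uncurated syndrome report at
    12_000_000-13_000_000.
    chr2: forty distinct protein-coding genes at 1 Mb spacing.
    """
    genes = [
        GeneFeature("GENE_A", iv(1, 1_000_000, 1_050_000)),
        GeneFeature("ELEM_B", iv(1, 2_000_000, 2_010_000), biotype="other_functional_element"),
        GeneFeature("OTHER_C", iv(1, 3_000_000, 3_010_000), biotype="other"),
        GeneFeature("FAM1_1", iv(1, 4_000_000, 4_020_000), family_id="FAM1"),
        GeneFeature("FAM1_2", iv(1, 4_050_000, 4_070_000), family_id="FAM1"),
        GeneFeature("FAM1_3", iv(1, 4_100_000, 4_120_000), family_id="FAM1"),
        GeneFeature("GENE_D", iv(1, 5_000_000, 5_040_000)),
    ]
    genes += [
        GeneFeature(f"CH2_{k:02d}", iv(2, k * 1_000_000, k * 1_000_000 + 10_000))
        for k in range(1, 41)
    ]
    regions = [
        RegionRecord("HI_GENE_A", iv(1, 1_000_000, 1_050_000), "HI_gene", curated=True),
        RegionRecord("TS_GENE_D", iv(1, 5_000_000, 5_040_000), "TS_gene", curated=True),
        RegionRecord("BENIGN_1", iv(1, 8_000_000, 9_000_000), "benign_region", curated=True),
        RegionRecord("REPORTED_SYN", iv(1, 12_000_000, 13_000_000), "HI_region", curated=False),
    ]
    return AnnotationSet(genes=genes, regions=regions)


def make_cnv(cnv_id, chrom, start, end, dosage_type, **kw):
    return CNVCall(cnv_id, iv(chrom, start, end), dosage_type, **kw)
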