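import numpy as np
import pytest

from cnvscore.evidence import assign_all, assign_section1, assign_section2, assign_section3
from cnvscore.genome import AnnotationSet, GenomicInterval, RegionRecord

from conftest import iv, make_cnv


class TestSection1:
    def test_protein_coding_gives_content(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 990_000, 1_010_000, "loss")
        a = assign_section1(cnv, annotation, loss_rubric)
        assert a.category_code == "1A"
        assert a.points == pytest.approx(0.0)
        assert a.provenance == "auto"

    def test_functional_element_gives_content(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 2_005_000, 2_006_000, "loss")
        assert assign_section1(cnv, annotation, loss_rubric).category_code == "1A"

    def test_empty_region_gives_no_content(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 40_000_000, 41_000_000, "loss")
        a = assign_section1(cnv, annotation, loss_rubric)
        assert a.category_code == "1B"
        assert a.points == pytest.approx(-0.60)

    def test_other_biotype_gives_no_content(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 3_000_000, 3_010_000, "loss")
        assert assign_section1(cnv, annotation, loss_rubric).category_code == "1B"

    def test_totality(self, annotation, loss_rubric, gain_rubric):
        rng = np.random.default_rng(7)
        for _ in range(50):
            start = int(rng.integers(1, 50_000_000))
            length = int(rng.integers(1_000, 5_000_000))
            dt = "loss" if rng.random() < 0.5 else "gain"
            rubric = loss_rubric if dt == "loss" else gain_rubric
            cnv = make_cnv("c", 1, start, start + length, dt)
            assert assign_section1(cnv, annotation, rubric).category_code in ("1A", "1B")


class TestSection2Loss:
    def test_full_hi_containment_scores_2a(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 900_000, 1_100_000, "loss")
        assignments, _ = assign_section2(cnv, annotation, loss_rubric)
        codes = {a.category_code: a for a in assignments}
        assert codes["2A"].points == pytest.approx(1.00)

    def test_benign_containment_scores_negative(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 8_200_000, 8_300_000, "loss")
        assignments, _ = assign_section2(cnv, annotation, loss_rubric)
        codes = {a.category_code: a for a in assignments}
        assert codes["2F"].points == pytest.approx(-1.00)

    def test_partial_hi_overlap_flags_without_points(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 1_020_000, 1_100_000, "loss")  # cuts into GENE_A
        assignments, flags = assign_section2(cnv, annotation, loss_rubric)
        assert not any(a.category_code == "2A" for a in assignments)
        assert any(f.code == "partial_dosage_overlap" and f.region_name == "HI_GENE_A" for f in flags)

    def test_uncurated_region_flag_only(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 12_100_000, 12_200_000, "loss")
        assignments, flags = assign_section2(cnv, annotation, loss_rubric)
        assert assignments == []
        assert any(f.code == "uncurated_region" and f.region_name == "REPORTED_SYN" for f in flags)

    def test_ts_region_ignored_for_loss(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 4_990_000, 5_050_000, "loss")
        assignments, _ = assign_section2(cnv, annotation, loss_rubric)
        assert assignments == []


class TestSection2Gain:
    def test_breakpoint_in_hi_gene_scores_2k(self, annotation, gain_rubric):
        # start breakpoint inside GENE_A (1_000_000-1_050_000)
        cnv = make_cnv("g", 1, 1_025_000, 3_000_000, "gain")
        assignments, _ = assign_section2(cnv, annotation, gain_rubric)
        codes = {a.category_code: a for a in assignments}
        assert codes["2K"].points == pytest.approx(0.45)
        assert "2J" not in codes

    def test_spanning_hi_gene_scores_2j(self, annotation, gain_rubric):
        cnv = make_cnv("g", 1, 900_000, 3_000_000, "gain")
        assignments, _ = assign_section2(cnv, annotation, gain_rubric)
        codes = {a.category_code: a for a in assignments}
        assert codes["2J"].points == pytest.approx(0.0)
        assert "2K" not in codes

    def test_ts_containment_scores_2a(self, annotation, gain_rubric):
        cnv = make_cnv("g", 1, 4_900_000, 5_100_000, "gain")
        assignments, _ = assign_section2(cnv, annotation, gain_rubric)
        assert any(a.category_code == "2A" for a in assignments)

    def test_2j_2k_never_both(self, annotation, gain_rubric):
        rng = np.random.default_rng(11)
        for _ in range(100):
            start = int(rng.integers(500_000, 2_000_000))
            end = start + int(rng.integers(10_000, 3_000_000))
            cnv = make_cnv("g", 1, start, end, "gain")
            assignments, _ = assign_section2(cnv, annotation, gain_rubric)
            codes = {a.category_code for a in assignments}
            assert not ({"2J", "2K"} <= codes)

    def test_boundary_breakpoint_counts_as_inside(self, annotation, gain_rubric):
        cnv = make_cnv("g", 1, 1_050_000, 3_000_000, "gain")  # start == gene end
        assignments, _ = assign_section2(cnv, annotation, gain_rubric)
        assert any(a.category_code == "2K" for a in assignments)


class TestSection2CurationGate:
    def test_uncurated_never_scores(self, loss_rubric, gain_rubric):
        rng = np.random.default_rng(3)
        for _ in range(30):
            regions = []
            for k in range(int(rng.integers(1, 6))):
                start = int(rng.integers(1, 10_000_000))
                length = int(rng.integers(10_000, 2_000_000))
                role = ["HI_gene", "HI_region", "TS_gene", "TS_region", "benign_region"][
                    int(rng.integers(5))
                ]
                regions.append(
                    RegionRecord(
                        f"R{k}",
                        GenomicInterval("1", start, start + length),
                        role,
                        curated=False,
                    )
                )
            ann = AnnotationSet(genes=[], regions=regions)
            for dt, rubric in (("loss", loss_rubric), ("gain", gain_rubric)):
                cnv = make_cnv("c", 1, 1, 12_000_000, dt)
                assignments, flags = assign_section2(cnv, ann, rubric)
                assert assignments == []
                assert all(f.code in ("uncurated_region",) for f in flags)


class TestSection3:
    def test_small_count_zero_points(self, annotation, loss_rubric):
        cnv = make_cnv("c", 2, 1, 11_000_000, "loss")  # ~10 genes
        a = assign_section3(cnv, annotation, loss_rubric)
        assert a.category_code == "3A"
        assert a.points == pytest.approx(0.0)

    def test_forty_genes_max_points_loss(self, annotation, loss_rubric):
        cnv = make_cnv("c", 2, 1, 41_000_000, "loss")  # 40 genes
        a = assign_section3(cnv, annotation, loss_rubric)
        assert a.category_code == "3C"
        assert a.points == pytest.approx(0.90)

    def test_forty_genes_gain_middle_bin(self, annotation, gain_rubric):
        cnv = make_cnv("c", 2, 1, 41_000_000, "gain")  # 40 genes, gain bins differ
        a = assign_section3(cnv, annotation, gain_rubric)
        assert a.category_code == "3B"
        assert a.points == pytest.approx(0.45)

    def test_family_collapse_changes_bin(self, loss_rubric):
        from cnvscore.genome import GeneFeature

        genes = [
            GeneFeature(f"F{k}", iv(1, 1_000_000 + k * 50_000, 1_000_000 + k * 50_000 + 10_000),
                        family_id="BIGFAM")
            for k in range(40)
        ]
        ann = AnnotationSet(genes=genes, regions=[])
        cnv = make_cnv("c", 1, 900_000, 3_500_000, "loss")
        full = assign_section3(cnv, ann, loss_rubric, collapse_families=False)
        collapsed = assign_section3(cnv, ann, loss_rubric, collapse_families=True)
        assert full.points == pytest.approx(0.90)
        assert collapsed.points == pytest.approx(0.0)
        assert "40" in full.justification and "1 " in collapsed.justification

    def test_monotone_in_gene_count(self, annotation, loss_rubric):
        points = []
        for end in range(1_500_000, 42_000_000, 2_000_000):
            cnv = make_cnv("c", 2, 1, end, "loss")
            points.append(assign_section3(cnv, annotation, loss_rubric).points)
        assert points == sorted(points)


class TestAssignAll:
    def test_deterministic(self, annotation, gain_rubric):
        cnv = make_cnv("g", 1, 1_025_000, 3_000_000, "gain")
        first = assign_all(cnv, annotation, gain_rubric)
        second = assign_all(cnv, annotation, gain_rubric)
        assert first == second

    def test_all_auto_provenance(self, annotation, loss_rubric):
        cnv = make_cnv("c", 1, 900_000, 1_100_000, "loss")
        assignments, _ = assign_all(cnv, annotation, loss_rubric)
        assert all(a.provenance == "auto" for a in assignments)
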