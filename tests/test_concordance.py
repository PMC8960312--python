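import itertools

import pytest
import scipy.stats
from hypothesis import given, strategies as st

from cnvscore.concordance import (
    CONFLICT_CLASSES,
    ClassificationMatrix,
    compare_rates,
    conflict_class,
    format_rate,
    partition_counts,
    percent,
    pool_counts,
    summarize,
)
from cnvscore.datasets import reference_review_panel
from cnvscore.rubric import CLASSES

# ---------------------------------------------------------------- oracle
# Independent pairwise-severity classifier: every unordered label pair has a
# hand-assigned severity; a set's class is the maximum severity over pairs.

_PAIR_SEVERITY = {
    frozenset({"P", "LP"}): "confidence_difference",
    frozenset({"P", "VUS"}): "management_impact",
    frozenset({"P", "LB"}): "management_impact",
    frozenset({"P", "B"}): "management_impact",
    frozenset({"LP", "VUS"}): "management_impact",
    frozenset({"LP", "LB"}): "management_impact",
    frozenset({"LP", "B"}): "management_impact",
    frozenset({"VUS", "LB"}): "ror_impact",
    frozenset({"VUS", "B"}): "ror_impact",
    frozenset({"LB", "B"}): "confidence_difference",
}
_SEVERITY_RANK = {"management_impact": 3, "ror_impact": 2, "confidence_difference": 1}


def oracle_conflict_class(labels):
    labels = set(labels)
    if len(labels) == 1:
        return "complete"
    pairs = [_PAIR_SEVERITY[frozenset(p)] for p in itertools.combinations(labels, 2)]
    return max(pairs, key=_SEVERITY_RANK.get)


class TestConflictClass:
    def test_identity(self):
        assert conflict_class(["P", "P", "P"]) == "complete"

    def test_confidence(self):
        assert conflict_class(["P", "LP"]) == "confidence_difference"
        assert conflict_class(["LB", "B"]) == "confidence_difference"

    def test_management_precedence(self):
        assert conflict_class(["P", "VUS", "LB"]) == "management_impact"

    def test_ror(self):
        assert conflict_class(["VUS", "LB"]) == "ror_impact"
        assert conflict_class(["VUS", "B", "LB"]) == "ror_impact"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conflict_class([])

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="Path"):
            conflict_class(["Path."])

    def test_oracle_equivalence_all_31_subsets(self):
        for r in range(1, 6):
            for subset in itertools.combinations(CLASSES, r):
                assert conflict_class(subset) == oracle_conflict_class(subset), subset

    @given(st.lists(st.sampled_from(CLASSES), min_size=1, max_size=9))
    def test_multiset_equals_set(self, labels):
        assert conflict_class(labels) == conflict_class(set(labels))


class TestPartitionCounts:
    def test_single_confidence_pattern(self):
        assert partition_counts([(("P", "LP"), 3)])["confidence_difference"] == 3

    def test_mixed_patterns(self):
        out = partition_counts([(("P", "VUS"), 10), (("LB", "VUS"), 3)])
        assert out["management_impact"] == 10
        assert out["ror_impact"] == 3

    def test_empty(self):
        assert partition_counts([]) == {c: 0 for c in CONFLICT_CLASSES}

    def test_reference_panel_initial_partition(self):
        records = reference_review_panel(include_forced=False)
        assert len(records) == 82
        out = partition_counts([(r.initial_labels, 1) for r in records])
        assert out["management_impact"] == 56
        assert out["ror_impact"] == 16
        assert out["confidence_difference"] == 10
        assert out["complete"] == 0


def _matrix(rows, lab_ids=None, metadata=None):
    lab_ids = lab_ids or [f"L{j}" for j in range(len(next(iter(rows.values()))))]
    cells = {
        (cnv, lab): label
        for cnv, labels in rows.items()
        for lab, label in zip(lab_ids, labels)
    }
    return ClassificationMatrix(list(rows), lab_ids, cells, metadata or {})


class TestSummarize:
    def test_all_concordant(self):
        m = _matrix({f"c{i}": ["VUS", "VUS"] for i in range(3)})
        s = summarize(m)
        assert s.complete_rate == 1
        assert s.complete_by_class["VUS"] == 3

    def test_one_of_each(self):
        m = _matrix({"a": ["P", "P"], "b": ["P", "LP"], "c": ["P", "VUS"]})
        s = summarize(m)
        assert s.counts == {
            "complete": 1,
            "confidence_difference": 1,
            "management_impact": 1,
            "ror_impact": 0,
        }

    def test_rates_sum_to_one(self):
        m = _matrix({"a": ["P", "B"], "b": ["VUS", "VUS"], "c": ["VUS", "LB"]})
        s = summarize(m)
        assert sum(s.rates.values()) == 1

    def test_clinically_meaningful_at_least_complete(self):
        m = _matrix({"a": ["P", "LP"], "b": ["VUS", "VUS"]})
        s = summarize(m)
        assert s.clinically_meaningful_rate >= s.complete_rate

    def test_lab_permutation_invariance(self):
        rows = {"a": ["P", "LP", "VUS"], "b": ["B", "B", "B"], "c": ["VUS", "LB", "B"]}
        s1 = summarize(_matrix(rows))
        permuted = {cnv: [labels[2], labels[0], labels[1]] for cnv, labels in rows.items()}
        s2 = summarize(_matrix(permuted))
        assert s1.counts == s2.counts
        assert s1.complete_by_class == s2.complete_by_class

    def test_missing_lab_dropped_from_row(self):
        cells = {("a", "L0"): "P", ("a", "L1"): "P", ("b", "L0"): "VUS"}
        m = ClassificationMatrix(["a", "b"], ["L0", "L1"], cells)
        s = summarize(m)
        assert s.counts["complete"] == 2

    def test_breakdowns(self):
        meta = {"a": {"dosage_type": "loss"}, "b": {"dosage_type": "gain"}}
        m = _matrix({"a": ["P", "P"], "b": ["P", "VUS"]}, metadata=meta)
        s = summarize(m, breakdown_keys=["dosage_type"])
        assert s.breakdowns["dosage_type=loss"].counts["complete"] == 1
        assert s.breakdowns["dosage_type=gain"].counts["management_impact"] == 1

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            summarize(ClassificationMatrix([], ["L0"], {}))


class TestPercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(177, 234, 76), (41, 234, 18), (35, 83, 42), (35, 306, 11), (260, 306, 85), (1, 8, 13)],
    )
    def test_round_half_up(self, k, n, expected):
        assert percent(k, n) == expected

    def test_half_up_exact(self):
        assert percent(1, 200) == 1  # 0.5% -> 1, not banker's 0

    def test_format(self):
        assert format_rate(177, 234) == "76% (177/234)"

    def test_pool(self):
        assert pool_counts([(43, 47), (47, 63), (34, 47), (53, 77)]) == (177, 234)


class TestCompareRates:
    def test_printed_comparison_significant(self):
        stat, p, sig = compare_rates(41, 234, 177, 234)
        assert sig and p < 0.05

    def test_identical_rates(self):
        stat, p, sig = compare_rates(50, 100, 50, 100)
        assert stat == pytest.approx(0.0)
        assert not sig

    @pytest.mark.parametrize(
        "k1,n1,k2,n2",
        [(41, 234, 177, 234), (43, 47, 34, 47), (25, 36, 22, 36), (47, 72, 177, 234)],
    )
    def test_against_scipy_contingency_oracle(self, k1, n1, k2, n2):
        stat, p, _ = compare_rates(k1, n1, k2, n2)
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        ref = scipy.stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_printed_nonsignificant_claims(self):
        # deletions vs duplications and distributed vs submitted panels
        _, p1, sig1 = compare_rates(43 + 53, 47 + 77, 34 + 47, 47 + 63)
        _, p2, sig2 = compare_rates(47, 72, 177, 234)
        assert not sig1 and not sig2

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            compare_rates(0, 10, 0, 10)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_rates(5, 4, 1, 10)
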