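import pytest
from hypothesis import given, settings, strategies as st

from srnakit.cleaning import (CleanParams, DEFAULT_ADAPTER_3P,
                              DEFAULT_ADAPTER_5P, LibrarySummary, categorize,
                              clean_reads_identity, common_specific,
                              find_adapter, length_distribution,
                              trim_and_filter)
from srnakit.tagio import ReadRecord, TagCount

PARAMS = CleanParams()
A3 = DEFAULT_ADAPTER_3P
A5 = DEFAULT_ADAPTER_5P


def make_read(seq, qual=None):
    qual = qual if qual is not None else tuple(40 for _ in seq)
    return ReadRecord("r", seq, qual)


INSERT21 = "TGCATGCATGCCTGACTGACT"  # 21 nt, mixed composition


class TestCategorize:
    def test_clean_read(self):
        cat, insert = categorize(make_read(INSERT21 + A3), PARAMS)
        assert cat == "clean"
        assert insert == INSERT21

    def test_insert_null(self):
        cat, insert = categorize(make_read(A3 + "TTTTTTTT"), PARAMS)
        assert cat == "insert_null"

    def test_polya(self):
        cat, _ = categorize(make_read("A" * 21 + A3), PARAMS)
        assert cat == "polyA"

    def test_polya_fraction_boundary(self):
        # 16/20 As = 0.8 >= threshold
        insert = "A" * 16 + "CGCG"
        cat, _ = categorize(make_read(insert + A3), PARAMS)
        assert cat == "polyA"

    def test_shorter_than_18(self):
        cat, _ = categorize(make_read("TGCATGCATGC" + A3), PARAMS)
        assert cat == "shorter_than_18"

    def test_adapter3_null(self):
        cat, _ = categorize(make_read("TGCA" * 12), PARAMS)
        assert cat == "adapter3_null"

    def test_adapter5_contaminant(self):
        cat, _ = categorize(make_read(A5 + INSERT21 + A3), PARAMS)
        assert cat == "adapter5_contaminant"

    def test_low_quality(self):
        read = make_read(INSERT21 + A3, tuple(2 for _ in INSERT21 + A3))
        cat, _ = categorize(read, PARAMS)
        assert cat == "low_quality"

    def test_long_insert_kept_clean(self):
        insert = "TGCATGCATGCCTGACTGACTTGCATGCATGCCTG"  # 35 nt > max_len
        cat, got = categorize(make_read(insert + A3), PARAMS)
        assert cat == "clean" and got == insert


class TestFindAdapter:
    def test_exact(self):
        assert find_adapter("CCCC" + A3, A3, 6, 1) == 4

    def test_one_mismatch_tolerated(self):
        mutated = "A" + A3[1:]
        assert find_adapter("CCCC" + mutated, A3, 6, 1) == 4

    def test_no_match(self):
        assert find_adapter("TGCA" * 10, A3, 6, 1) == -1

    def test_partial_suffix_overlap(self):
        assert find_adapter("CCCCCCCC" + A3[:8], A3, 6, 1) == 8


class TestTrimAndFilter:
    def test_table1_accounting_identity(self):
        # printed column: high-quality minus the five categories
        assert clean_reads_identity(5_964_851, 4_147, 1_228, 11_222,
                                    184_717, 28) == 5_763_509

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            CleanParams(adapter_3p="", adapter_5p=A5)

    def test_summary_identity_on_mixed_reads(self):
        reads = [
            make_read(INSERT21 + A3),
            make_read(A3 + "GGGG"),
            make_read("A" * 21 + A3),
            make_read("TGCA" * 12),
            make_read(A5 + INSERT21 + A3),
            make_read("TGCATGCATGC" + A3),
            make_read(INSERT21 + A3, tuple(2 for _ in INSERT21 + A3)),
        ]
        inserts, summary = trim_and_filter(reads, PARAMS)
        assert summary.check_identity()
        assert summary.high_quality == 6
        assert summary.low_quality == 1
        assert summary.clean_reads == 1
        assert inserts == [INSERT21]

    def test_percentages_sum(self):
        reads = [make_read(INSERT21 + A3), make_read(A3 + "GGGG")]
        _, summary = trim_and_filter(reads, PARAMS)
        assert sum(summary.percentages().values()) == pytest.approx(100.0)

    def test_simdata_summary_exact(self, small_corpus):
        config, _, reads, expected, _ = small_corpus
        params = config.clean_params()
        for lib in config.libraries:
            records = [ReadRecord(i, s, tuple(ord(c) - 33 for c in q))
                       for i, s, q in reads[lib]]
            _, observed = trim_and_filter(records, params)
            assert observed.as_dict() == expected[lib].as_dict()
            assert observed.check_identity()


class TestLengthDistribution:
    def test_single_tag(self):
        hist = length_distribution([TagCount("T" * 21, {"L1": 5})])
        assert hist[21] == 5
        assert sum(hist.values()) == 5

    def test_empty(self):
        hist = length_distribution([])
        assert set(hist) == set(range(18, 31))
        assert all(v == 0 for v in hist.values())

    def test_out_of_range_excluded(self):
        hist = length_distribution([TagCount("T" * 17, {"L1": 2}),
                                    TagCount("T" * 31, {"L1": 3})])
        assert sum(hist.values()) == 0


class TestCommonSpecific:
    def test_identical_sets(self):
        a = [TagCount("AA", {"L1": 2})]
        b = [TagCount("AA", {"L2": 3})]
        result = common_specific(a, b)
        assert result["A_specific_unique"] == result["B_specific_unique"] == 0

    def test_disjoint_sets(self):
        result = common_specific([TagCount("AA", {"L1": 1})],
                                 [TagCount("CC", {"L2": 1})])
        assert result["common_unique"] == 0 and result["common_total"] == 0

    def test_hand_enumeration(self):
        a = [TagCount("AA", {"L1": 2})]
        b = [TagCount("AA", {"L2": 3}), TagCount("AC", {"L2": 1})]
        result = common_specific(a, b)
        assert result["common_unique"] == 1
        assert result["common_total"] == 5
        assert result["B_specific_total"] == 1
        assert result["A_specific_total"] == 0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.sampled_from(["clean", "a3null", "polyA", "short", "a5"]),
                min_size=0, max_size=40))
def test_identity_fuzz(kinds):
    reads = []
    for kind in kinds:
        if kind == "clean":
            reads.append(make_read(INSERT21 + A3))
        elif kind == "a3null":
            reads.append(make_read("TGCA" * 12))
        elif kind == "polyA":
            reads.append(make_read("A" * 20 + A3))
        elif kind == "short":
            reads.append(make_read("TGCATGCAT" + A3))
        else:
            reads.append(make_read(A5 + INSERT21 + A3))
    _, summary = trim_and_filter(reads, PARAMS)
    assert summary.check_identity()
    assert summary.high_quality == len(reads)
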