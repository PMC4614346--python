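import pytest

from srnakit.fold import fold_mfe
from srnakit.hairpin import (HairpinCandidate, HairpinCriteria, Placement,
                             discover_novel, evaluate_hairpin,
                             extract_precursors, map_unannotated,
                             name_candidates, revcomp)
from srnakit.simulate import SimConfig, simulate_reference
from srnakit.tagio import TagCount

TAG = "TGCATGCCTGACTGACTGCAT"  # 21 nt


def make_genome(insert_at=500, n=2000, seed=5):
    import numpy as np
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return {"c1": seq[:insert_at] + TAG + seq[insert_at + len(TAG):]}


class TestMapUnannotated:
    def test_forward_single(self):
        genome = make_genome()
        placements = map_unannotated([TagCount(TAG, {"L1": 1})], genome)
        ours = [p for p in placements if p.strand == "+"]
        assert len(ours) == 1
        assert (ours[0].start, ours[0].end) == (500, 521)

    def test_reverse_complement(self):
        genome = {"c1": "T" * 30 + revcomp(TAG) + "T" * 30}
        placements = map_unannotated([TagCount(TAG, {"L1": 1})], genome)
        assert len(placements) == 1
        assert placements[0].strand == "-"
        assert (placements[0].start, placements[0].end) == (30, 51)

    def test_multi_locus(self):
        genome = {"c1": ("GC" * 20 + TAG) * 4 + "GC" * 20}
        placements = map_unannotated([TagCount(TAG, {"L1": 1})], genome)
        assert len([p for p in placements if p.strand == "+"]) == 4


class TestExtractPrecursors:
    def test_interior_two_windows_of_100(self):
        genome = make_genome()
        placement = Placement(TAG, "c1", "+", 500, 521)
        out = extract_precursors(placement, genome)
        assert len(out) == 2
        for seq, offset, g0, g1 in out:
            assert len(seq) == 100
            assert seq[offset:offset + len(TAG)] == TAG

    def test_contig_start_clipped(self):
        genome = {"c1": TAG + make_genome()["c1"][:300]}
        placement = Placement(TAG, "c1", "+", 0, 21)
        out = extract_precursors(placement, genome)
        assert out, "clipped candidate should survive"
        for seq, offset, g0, g1 in out:
            assert seq[offset:offset + len(TAG)] == TAG
            assert g0 == 0 or g1 <= len(genome["c1"])

    def test_too_short_contig_dropped(self):
        genome = {"c1": TAG + "ACGTACGT"}  # < 60 nt total
        placement = Placement(TAG, "c1", "+", 0, 21)
        assert extract_precursors(placement, genome) == []

    def test_planted_window_contains_precursor(self):
        config = SimConfig(seed=9, n_known_mirnas=4, n_novel_loci=2,
                           n_transcripts=4)
        reference = simulate_reference(config)
        locus = reference.truth.novel[0]
        placements = [p for p in map_unannotated(
            [TagCount(locus.mature, {"L1": 1})], reference.genome)
            if p.strand == "+"]
        assert placements
        windows = extract_precursors(placements[0], reference.genome)
        assert any(locus.precursor in seq or seq in locus.precursor
                   for seq, *_ in windows)


class TestEvaluate:
    def _planted(self, seed=9):
        config = SimConfig(seed=seed, n_known_mirnas=4, n_novel_loci=2,
                           n_transcripts=4)
        reference = simulate_reference(config)
        return reference.truth.novel[0]

    def test_planted_accepted_with_true_arm(self):
        locus = self._planted()
        offset = locus.precursor.find(locus.mature)
        fold = fold_mfe(locus.precursor)
        verdict, reason = evaluate_hairpin(locus.precursor, offset,
                                           len(locus.mature), fold)
        assert verdict is not None, reason
        assert verdict["arm"] == locus.arm

    def test_weak_mfe_rejected(self):
        locus = self._planted()
        offset = locus.precursor.find(locus.mature)
        fold = fold_mfe(locus.precursor)
        criteria = HairpinCriteria(max_mfe=fold.mfe - 1.0)
        verdict, reason = evaluate_hairpin(locus.precursor, offset,
                                           len(locus.mature), fold, criteria)
        assert verdict is None and reason == "mfe"

    def test_mature_length_19_rejected(self):
        locus = self._planted()
        offset = locus.precursor.find(locus.mature)
        fold = fold_mfe(locus.precursor)
        verdict, reason = evaluate_hairpin(locus.precursor, offset, 19, fold)
        assert verdict is None and reason == "length"

    def test_unstructured_rejected(self):
        seq = "A" * 80
        fold = fold_mfe(seq)
        criteria = HairpinCriteria(max_mfe=0.0)
        verdict, reason = evaluate_hairpin(seq, 10, 21, fold, criteria)
        assert verdict is None


class TestNaming:
    def _candidate(self, contig="c1", start=0, mature=TAG, arm="5p"):
        return HairpinCandidate(name="", mature=mature, star="", precursor="",
                                structure="", mfe=-20.0, arm=arm,
                                contig=contig, strand="+", start=start,
                                end=start + 80)

    def test_sequential_names(self):
        named = name_candidates([self._candidate(start=100, arm="5p"),
                                 self._candidate(start=300, arm="3p")])
        assert [c.name for c in named] == ["Ofu-m0001_5p", "Ofu-m0002_3p"]

    def test_same_sequence_different_loci_kept(self):
        named = name_candidates([self._candidate(start=s) for s in
                                 (0, 200, 400, 600)])
        assert len(named) == 4
        assert len({c.name for c in named}) == 4

    def test_exact_duplicates_dropped(self):
        named = name_candidates([self._candidate(), self._candidate()])
        assert len(named) == 1

    def test_empty(self):
        assert name_candidates([]) == []


class TestDiscovery:
    def test_planted_recovery(self):
        recovered = total = 0
        for seed in range(5):
            config = SimConfig(seed=seed, n_known_mirnas=6, n_novel_loci=3,
                               n_transcripts=4)
            reference = simulate_reference(config)
            tags = [TagCount(n.mature, {"L1": 10}) for n in reference.truth.novel]
            candidates = discover_novel(tags, reference.genome)
            found = {c.mature for c in candidates}
            total += len(reference.truth.novel)
            recovered += sum(1 for n in reference.truth.novel
                             if n.mature in found)
            # every emitted candidate satisfies the acceptance criteria
            for c in candidates:
                assert c.mfe <= -18.0
                assert 20 <= len(c.mature) <= 24
                assert c.mature in c.precursor or \
                    revcomp(c.mature) in c.precursor
                verdict, reason = evaluate_hairpin(
                    c.precursor, c.mature_offset, len(c.mature),
                    fold_mfe(c.precursor))
                assert verdict is not None, reason
        assert recovered / total >= 0.8

    def test_min_read_support(self):
        genome = make_genome()
        tags = [TagCount(TAG, {"L1": 2})]  # below default support of 3
        assert discover_novel(tags, genome) == []

    def test_empty_tags(self):
        assert discover_novel([], make_genome()) == []
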