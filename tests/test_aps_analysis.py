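"""AU statistics, APS classification, construct edits, ARE scan, alignment."""

import itertools

import numpy as np
import pytest

from apsscan import (
    ConstructSpec,
    Region,
    TranscriptError,
    TranscriptRecipe,
    apply_edits,
    au_fraction,
    au_profile,
    classify_aps,
    extract_utrs,
    find_conserved_blocks,
    gen_homolog_set,
    gen_transcript,
    global_align,
    scan_are,
)

from conftest import random_seq


def brute_force_au(seq: str) -> float:
    """Independent oracle: a character loop counting A and T."""
    n = 0
    for ch in seq:
        if ch in "AT":
            n += 1
    return n / len(seq)


class TestAuFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATATAT", 1.0), ("GCGCGC", 0.0), ("ATGC", 0.5), ("ATNNG", 0.4)],
    )
    def test_known_compositions(self, seq, expected):
        assert au_fraction(seq) == pytest.approx(expected)

    def test_empty_sequence_fatal(self):
        with pytest.raises(TranscriptError):
            au_fraction("")


class TestAuProfile:
    def test_block_composition_profile(self):
        prof = au_profile("AT" * 50 + "GC" * 50, window=100, step=100)
        assert [f for _, f in prof.points] == [pytest.approx(1.0), pytest.approx(0.0)]

    def test_windows_match_brute_force_recount(self, rng):
        seq = random_seq(rng, 500)
        prof = au_profile(seq, window=100, step=10)
        for start, frac in prof.points:
            assert frac == pytest.approx(brute_force_au(seq[start - 1 : start + 99]))
        assert prof.first100_au == pytest.approx(brute_force_au(seq[:100]))

    def test_partial_last_window_dropped(self):
        prof = au_profile("A" * 105, window=100, step=10)
        assert [s for s, _ in prof.points] == [1]

    def test_short_region_flagged(self):
        prof = au_profile("ATGC" * 10, window=5, step=5)
        assert prof.short_region_flag and prof.first100_au == pytest.approx(0.5)

    def test_bad_window_fatal(self):
        with pytest.raises(TranscriptError):
            au_profile("ACGT", window=0)


class TestClassifyAps:
    def test_positive_by_construction(self):
        head = "AT" * 30 + "GC" * 20  # 60 AU in first 100
        utr = head + "GC" * 150  # total 400
        call = classify_aps(utr)
        assert call.first100_au_percent == pytest.approx(60.0)
        assert call.is_aps_positive and call.au_ok and call.length_ok

    def test_length_boundary_is_inclusive(self):
        assert classify_aps("AT" * 150).is_aps_positive  # 300 nt, AU 100%
        call = classify_aps("AT" * 149 + "A")  # 299 nt
        assert not call.length_ok and not call.is_aps_positive

    def test_au_threshold_is_strict(self):
        head = "AT" * 25 + "GC" * 25  # exactly 50 AU in first 100
        call = classify_aps(head + "A" * 300)
        assert call.first100_au_percent == pytest.approx(50.0)
        assert not call.au_ok and not call.is_aps_positive

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            utr = random_seq(rng, int(rng.integers(50, 2001)))
            call = classify_aps(utr)
            expected = 100.0 * brute_force_au(utr[:100])
            assert call.first100_au_percent == pytest.approx(expected)
            assert call.is_aps_positive == (expected > 50.0 and len(utr) >= 300)

    def test_invariant_under_u_t_representation(self, rng):
        utr = random_seq(rng, 400)
        as_rna = utr.replace("T", "U")
        from apsscan.sequence_model import normalize_seq
        assert classify_aps(normalize_seq(as_rna)) == classify_aps(utr)

    def test_monotone_in_threshold_and_min_len(self, rng):
        utr = random_seq(rng, 600)
        grid = list(itertools.product([30, 50, 70], [100, 300, 700]))
        calls = {(th, ml): classify_aps(utr, threshold=th, min_len=ml).is_aps_positive
                 for th, ml in grid}
        for (th1, ml1), (th2, ml2) in itertools.product(grid, grid):
            if th2 >= th1 and ml2 >= ml1 and calls[(th2, ml2)]:
                assert calls[(th1, ml1)]


class TestApplyEdits:
    def _aps_positive_utr(self):
        # 400-nt UTR, AU-rich head: APS-positive by construction
        return "AT" * 50 + "GC" * 150

    def _low_au_donor(self):
        return "GC" * 45 + "G"  # 91 nt, AU content 0

    def test_head_insertion_flips_aps_call(self):
        utr = self._aps_positive_utr()
        assert classify_aps(utr).is_aps_positive
        spec = ConstructSpec("head_ins", {"utr": utr, "donor": self._low_au_donor()},
                             initial="utr", edits=[("insert_at", 0, "donor")])
        result = apply_edits(spec)
        assert result.seq[:91] == self._low_au_donor()
        assert result.seq[91:100] == utr[:9]
        assert not classify_aps(result).is_aps_positive

    def test_distal_insertion_leaves_aps_call_unchanged(self):
        utr = self._aps_positive_utr()
        spec = ConstructSpec("dis_ins", {"utr": utr, "donor": self._low_au_donor()},
                             initial="utr", edits=[("insert_at", 285, "donor")])
        result = apply_edits(spec)
        assert result.seq[:100] == utr[:100]
        assert classify_aps(result).is_aps_positive == classify_aps(utr).is_aps_positive

    def test_fuse_then_take_recovers_first_part(self, rng):
        a, b = random_seq(rng, 120), random_seq(rng, 80)
        spec = ConstructSpec("fusion", {"a": a, "b": b}, initial="a",
                             edits=[("fuse", "b"), ("take", 1, 120)])
        assert apply_edits(spec).seq == a

    def test_length_algebra_and_provenance(self, rng):
        base = random_seq(rng, 300)
        donor = random_seq(rng, 40)
        spec = ConstructSpec("algebra", {"base": base, "donor": donor}, initial="base",
                             edits=[("take", 11, 250), ("insert_at", 100, "donor"),
                                    ("delete", 5, 24)])
        result = apply_edits(spec)
        assert len(result) == 240 + 40 - 20
        assert len(spec.provenance_log) == 3
        # replaying yields the identical sequence
        assert apply_edits(spec).seq == result.seq

    def test_out_of_bounds_edits_fatal(self):
        spec = ConstructSpec("bad", {"base": "ACGT"}, initial="base",
                             edits=[("insert_at", 5, "base")])
        with pytest.raises(TranscriptError):
            apply_edits(spec)
        spec2 = ConstructSpec("bad2", {"base": "ACGT"}, initial="base",
                              edits=[("delete", 2, 9)])
        with pytest.raises(TranscriptError):
            apply_edits(spec2)


class TestScanAre:
    def test_single_hit(self):
        (hit,) = scan_are("ATTTA")
        assert (hit.start, hit.end) == (1, 5)

    def test_overlapping_hits_share_cluster(self):
        hits = scan_are("ATTTATTTA")
        assert [(h.start, h.cluster_id) for h in hits] == [(1, 0), (5, 0)]

    def test_distant_hits_split_clusters(self):
        hits = scan_are("ATTTA" + "G" * 20 + "ATTTA")
        assert [h.cluster_id for h in hits] == [0, 1]

    def test_no_hits(self):
        assert scan_are("GGGGGGG") == []


def enumerate_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Independent oracle: exhaustive recursion over all alignments (tiny inputs)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] else mismatch
    return max(
        sub + enumerate_alignment_score(a[1:], b[1:], match, mismatch, gap),
        gap + enumerate_alignment_score(a[1:], b, match, mismatch, gap),
        gap + enumerate_alignment_score(a, b[1:], match, mismatch, gap),
    )


class TestGlobalAlign:
    @pytest.mark.parametrize(
        "a,b,score",
        [
            ("ACGT", "ACGT", 4),
            ("ACGT", "AGT", 1),  # 3 matches, 1 gap
            ("A", "T", -1),  # mismatch beats two gaps
            ("ACGT", "A", -5),  # 1 match, 3 gaps
            ("GATTACA", "GATCA", 1),
        ],
    )
    def test_hand_filled_dp_scores(self, a, b, score):
        aligned_a, aligned_b, s = global_align(a, b)
        assert s == score == enumerate_alignment_score(a, b)
        assert aligned_a.replace("-", "") == a
        assert aligned_b.replace("-", "") == b
        assert len(aligned_a) == len(aligned_b)

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(2, 8)))
            b = random_seq(rng, int(rng.integers(2, 8)))
            assert global_align(a, b)[2] == enumerate_alignment_score(a, b)

    def test_matches_biopython_scores(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1, gap_score=-2)
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(10, 60)))
            b = random_seq(rng, int(rng.integers(10, 60)))
            assert global_align(a, b)[2] == int(aligner.score(a, b))

    def test_self_alignment_scores_length(self, rng):
        for _ in range(100):
            s = random_seq(rng, int(rng.integers(1, 80)))
            aligned_a, aligned_b, score = global_align(s, s)
            assert score == len(s) and aligned_a == aligned_b == s

    def test_score_beats_trivial_all_gap_alignment(self, rng):
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(1, 30)))
            b = random_seq(rng, int(rng.integers(1, 30)))
            assert global_align(a, b)[2] >= -2 * (len(a) + len(b))

    def test_empty_input_fatal(self):
        with pytest.raises(TranscriptError):
            global_align("ACGT", "")


class TestConservedBlocks:
    def test_identical_homologs_give_full_reference_block(self, rng):
        ref = random_seq(rng, 150)
        homs = gen_homolog_set(ref, n_species=4, substitution_rate=0.0, seed=7)
        (block,) = find_conserved_blocks(ref, homs)
        assert (block.start, block.end, block.length) == (1, 150, 150)
        assert block.per_column_identity == 1.0

    def test_embedded_block_recovered(self, rng):
        ref = random_seq(rng, 200)
        homs = gen_homolog_set(ref, n_species=8, substitution_rate=0.2,
                               conserved_block=(80, 37), seed=11)
        blocks = find_conserved_blocks(ref, homs)
        top = blocks[0]
        assert top.start <= 80 and top.end >= 116
        assert 35 <= top.length <= 41

    def test_unrelated_homologs_yield_no_long_block(self, rng):
        hits = 0
        for seed in range(30):
            ref = random_seq(rng, 120)
            homs = [Region(f"h{k}", "custom", 1, 120, random_seq(rng, 120))
                    for k in range(4)]
            blocks = find_conserved_blocks(ref, homs)
            if blocks and blocks[0].length >= 10:
                hits += 1
        assert hits <= 1

    def test_gap_counts_as_mismatch(self):
        # homolog missing 5 internal bases: the deleted columns break the run
        ref = "A" * 20 + "CGCGC" + "A" * 20
        hom = "A" * 20 + "A" * 20
        blocks = find_conserved_blocks(ref, [hom])
        assert blocks[0].length < len(ref)
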