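"""Banded dynamic programming, cluster extension, delta encoding and
coordinate translation."""

import pytest

from mumalign.align import (
    AlignmentOptions,
    banded_global_align,
    delta_decode,
    delta_encode,
    extend_and_join,
    reconstruct_transcript,
    translate_alignment,
)
from mumalign.cluster import ClusterOptions, cluster_matches
from mumalign.index import build_index
from mumalign.seeds import MatchMode, find_all_matches
from mumalign.seqio import SequenceRecord, concat_reference

from oracles import full_nw, random_dna, replay_alignment


class TestBandedGlobalAlign:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 50)
        transcript, score = banded_global_align(s, s, 5)
        assert transcript == "M" * 50 and score == 150

    def test_single_substitution(self):
        transcript, score = banded_global_align("ACGTT", "ACATT", 10)
        assert transcript == "MMXMM" and score == 4 * 3 - 3

    def test_pure_gap_cases(self):
        assert banded_global_align("AAA", "", 5) == ("DDD", -12)
        assert banded_global_align("", "AAA", 5) == ("III", -12)

    def test_wide_band_equals_full_dp(self, rng):
        for _ in range(60):
            la = int(rng.integers(1, 60))
            a = random_dna(rng, la)
            # edit-perturb a into b
            b = list(a)
            for _e in range(int(rng.integers(0, 8))):
                kind = rng.integers(0, 3)
                pos = int(rng.integers(0, max(1, len(b))))
                if kind == 0 and b:
                    b[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif kind == 1:
                    b.insert(pos, "ACGT"[int(rng.integers(0, 4))])
                elif b:
                    del b[pos]
            b = "".join(b) or "A"
            band = max(len(a), len(b))
            transcript, score = banded_global_align(a, b, band)
            exp_score, exp_errors = full_nw(a, b)
            assert score == exp_score
            assert sum(1 for o in transcript if o != "M") == exp_errors

    def test_transcript_consumes_both_strings_exactly(self, rng):
        a, b = random_dna(rng, 33), random_dna(rng, 29)
        transcript, _ = banded_global_align(a, b, 40)
        assert sum(1 for o in transcript if o in "MXD") == len(a)
        assert sum(1 for o in transcript if o in "MXI") == len(b)


class TestDeltaEncoding:
    @pytest.mark.parametrize(
        "transcript,expected",
        [
            ("MMMM", []),
            ("MMDM", [3]),
            ("MII", [-2, -1]),
            ("DMM", [1]),
            ("MMXMDMMIM", [5, -3]),
        ],
    )
    def test_encode_known(self, transcript, expected):
        assert delta_encode(transcript) == expected

    def test_decode_inverts_encode(self, rng):
        for _ in range(100):
            ops = "".join(
                rng.choice(list("MMMMMXID"), int(rng.integers(1, 40)))
            )
            offs = delta_encode(ops)
            ref_span = sum(1 for o in ops if o in "MXD")
            qry_span = sum(1 for o in ops if o in "MXI")
            skeleton = delta_decode(offs, ref_span, qry_span)
            # gap placement identical; M/X distinction is not stored
            assert skeleton.replace("M", ".") == (
                ops.replace("M", ".").replace("X", ".")
            )

    def test_inconsistent_offsets_rejected(self):
        with pytest.raises(ValueError):
            delta_decode([5], 3, 3)


def _single_cluster(ref_bases, qry_bases, min_len=10):
    ref = concat_reference([SequenceRecord("ref", ref_bases)])
    idx = build_index(ref.S)
    qrec = SequenceRecord("qry", qry_bases)
    ms = find_all_matches(idx, qrec, min_len, MatchMode.UNIQUE_IN_REFERENCE)
    clusters = cluster_matches(
        ms, ClusterOptions(min_cluster=20), ref=ref
    )
    return clusters, ref, qrec


class TestExtendAndJoin:
    def test_snp_between_seeds_single_alignment(self, rng):
        ref_bases = random_dna(rng, 400)
        qry_bases = ref_bases[:200] + (
            "A" if ref_bases[200] != "A" else "C"
        ) + ref_bases[201:]
        clusters, ref, qrec = _single_cluster(ref_bases, qry_bases)
        assert len(clusters) == 1
        (aln,) = extend_and_join(clusters[0], ref, qrec)
        assert (aln.ref_start, aln.ref_end) == (1, 400)
        assert aln.errors == 1 and aln.indels == []

    def test_identical_sequences_extend_to_both_ends(self, rng):
        bases = random_dna(rng, 300)
        clusters, ref, qrec = _single_cluster(bases, bases)
        (aln,) = extend_and_join(clusters[0], ref, qrec)
        assert (aln.ref_start, aln.ref_end) == (1, 300)
        assert (aln.qry_start, aln.qry_end) == (1, 300)
        assert aln.errors == 0

    def test_three_base_deletion_encoded_as_indel_run(self, rng):
        ref_bases = random_dna(rng, 400)
        qry_bases = ref_bases[:200] + ref_bases[203:]  # 3-base deletion
        clusters, ref, qrec = _single_cluster(ref_bases, qry_bases)
        (aln,) = extend_and_join(clusters[0], ref, qrec)
        assert aln.errors == 3
        # gap in the query = reference bases over gaps: positive offsets,
        # adjacent gap columns encoded as distance-1 follow-ups
        assert len(aln.indels) == 3
        assert aln.indels[0] > 1 and aln.indels[1:] == [1, 1]

    def test_replaying_indels_reproduces_error_count(self, rng):
        ref_bases = random_dna(rng, 500)
        qry = list(ref_bases)
        for pos in range(40, 460, 40):
            qry[pos] = "ACGT"[(("ACGT".index(qry[pos])) + 1) % 4]
        qry_bases = "".join(qry)
        clusters, ref, qrec = _single_cluster(ref_bases, qry_bases)
        for cluster in clusters:
            for aln in extend_and_join(cluster, ref, qrec):
                cols, errs = replay_alignment(
                    ref_bases[aln.ref_start - 1 : aln.ref_end],
                    qry_bases[aln.qry_start - 1 : aln.qry_end],
                    aln.indels,
                )
                assert errs == aln.errors
                # column-count consistency on both sides
                neg = sum(1 for x in aln.indels if x < 0)
                pos = sum(1 for x in aln.indels if x > 0)
                assert aln.ref_span + neg == aln.qry_span + pos == cols


class TestTranslateAlignment:
    def test_record_local_translation(self):
        ref = concat_reference(
            [SequenceRecord("r1", "ACGTA"), SequenceRecord("r2", "GGT")]
        )
        # S = "ACGTAxGGT": r2 occupies 1-based S positions 7-9
        assert translate_alignment(7, 8, ref) == ("r2", 1, 2)
        assert translate_alignment(9, 9, ref) == ("r2", 3, 3)

    def test_separator_crossing_rejected(self):
        ref = concat_reference(
            [SequenceRecord("r1", "ACGTA"), SequenceRecord("r2", "GGT")]
        )
        with pytest.raises(ValueError):
            translate_alignment(4, 8, ref)


class TestReconstructTranscript:
    def test_identity_and_classified_mismatch(self):
        from mumalign.align import Alignment

        aln = Alignment(
            ref_id="r", qry_id="q", ref_start=1, ref_end=4,
            qry_start=1, qry_end=4, errors=1, sim_errors=1,
            stop_codons=0, indels=[], ref_len=4, qry_len=4,
        )
        assert reconstruct_transcript(aln, "ACGT", "ACTT") == "MMXM"
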