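"""Delta serialisation round-trips and SAM emission, with pysam as the
independent validator for CIGAR/MD semantics."""

import io

import pysam
import pytest

from mumalign.align import Alignment
from mumalign.formats import (
    DeltaParseError,
    alignment_to_sam,
    parse_delta,
    write_delta,
    write_sam,
)
from mumalign.pipeline import RunOptions, align_records
from mumalign.seqio import SequenceRecord
from mumalign.synthetic import generate_mutated_pair

from oracles import random_dna


def aln(ref_id="r", qry_id="q", rs=1, re=9, qs=1, qe=9, errors=0,
        indels=(), ref_len=9, qry_len=9):
    return Alignment(
        ref_id=ref_id, qry_id=qry_id, ref_start=rs, ref_end=re,
        qry_start=qs, qry_end=qe, errors=errors, sim_errors=errors,
        stop_codons=0, indels=list(indels), ref_len=ref_len, qry_len=qry_len,
    )


class TestDelta:
    def test_exact_alignment_record_layout(self):
        buf = io.StringIO()
        write_delta([aln()], "ref.fa", "qry.fa", buf)
        assert buf.getvalue().splitlines() == [
            "ref.fa qry.fa",
            "NUCMER",
            ">r q 9 9",
            "1 9 1 9 0 0 0",
            "0",
        ]

    def test_indel_offsets_one_per_line(self):
        buf = io.StringIO()
        write_delta(
            [aln(re=9, qe=8, errors=1, indels=[3], qry_len=8)],
            "r", "q", buf,
        )
        assert buf.getvalue().splitlines()[-3:] == ["1 9 1 8 1 1 0", "3", "0"]

    def test_empty_set_writes_header_only(self):
        buf = io.StringIO()
        write_delta([], "a", "b", buf)
        assert buf.getvalue() == "a b\nNUCMER\n"

    def test_roundtrip_random_sets(self, rng):
        for _ in range(50):
            alns = []
            for k in range(int(rng.integers(1, 6))):
                span = int(rng.integers(1, 50))
                rs = int(rng.integers(1, 40))
                qs = int(rng.integers(1, 40))
                n_ind = int(rng.integers(0, 4))
                indels = [
                    int(rng.integers(1, 9)) * (1 if rng.random() < 0.5 else -1)
                    for _ in range(n_ind)
                ]
                pos = sum(1 for x in indels if x > 0)
                neg = len(indels) - pos
                rev = rng.random() < 0.5
                qspan = span + neg - pos
                if qspan < 1:
                    continue
                qe = qs + qspan - 1
                alns.append(
                    aln(
                        ref_id=f"r{k % 2}", qry_id="q",
                        rs=rs, re=rs + span - 1,
                        qs=qe if rev else qs, qe=qs if rev else qe,
                        errors=len(indels), indels=indels,
                        ref_len=200, qry_len=200,
                    )
                )
            # the writer takes records grouped by (ref, qry) pair
            alns.sort(key=lambda a: a.ref_id)
            buf = io.StringIO()
            write_delta(alns, "R", "Q", buf)
            rp, qp, back = parse_delta(io.StringIO(buf.getvalue()))
            assert (rp, qp) == ("R", "Q") and back == alns

    def test_reverse_strand_is_start_greater_than_end(self):
        buf = io.StringIO()
        write_delta([aln(qs=9, qe=1)], "R", "Q", buf)
        _, _, (back,) = parse_delta(io.StringIO(buf.getvalue()))
        assert back.strand == "-"

    def test_promer_dialect_rejected(self):
        with pytest.raises(DeltaParseError, match="PROMER"):
            parse_delta(io.StringIO("a b\nPROMER\n"))

    @pytest.mark.parametrize(
        "text,message",
        [
            ("a b\nNUCMER\n>r q 9 9\n1 9 1 9 0 0 0\n3\n", "unterminated"),
            ("a b\nNUCMER\n>r q 9 9\n1 9 1 9 0 0\n0\n", "7 integers"),
            ("a b\nNUCMER\n1 9 1 9 0 0 0\n0\n", "before '>'"),
        ],
    )
    def test_malformed_input_named_errors(self, text, message):
        with pytest.raises(DeltaParseError, match=message):
            parse_delta(io.StringIO(text))

    def test_out_of_range_coordinates_refused_on_write(self):
        with pytest.raises(ValueError):
            buf = io.StringIO()
            write_delta([aln(re=10, ref_len=9)], "R", "Q", buf)


class TestSamRecords:
    def test_exact_forward_alignment(self, rng):
        bases = random_dna(rng, 40)
        rec = alignment_to_sam(
            aln(re=40, qe=40, ref_len=40, qry_len=40),
            "short",
            SequenceRecord("q", bases),
        )
        assert rec.cigar == "40M" and rec.flag == 0
        assert "NM:i:0" in rec.tags and rec.seq == "*"

    def test_substitution_md(self):
        a = aln(re=4, qe=4, errors=1, ref_len=4, qry_len=4)
        a.transcript = "MMXM"
        rec = alignment_to_sam(
            a, "long", SequenceRecord("q", "ACTT"), ref_bases="ACGT"
        )
        assert rec.cigar == "4M"
        assert "MD:Z:2G1" in rec.tags and "NM:i:1" in rec.tags

    def test_reverse_strand_record(self):
        a = aln(qs=9, qe=1, ref_len=9, qry_len=9)
        a.transcript = "M" * 9
        rec = alignment_to_sam(
            a, "long", SequenceRecord("q", "ACGTACGTA")
        )
        assert rec.flag == 16
        assert rec.seq == "TACGTACGT"  # reverse complement of the query
        assert rec.pos == 1

    def test_soft_clips_for_partial_query(self):
        a = aln(rs=5, re=10, qs=3, qe=8, errors=0, ref_len=20, qry_len=12)
        a.transcript = "M" * 6
        rec = alignment_to_sam(a, "short", SequenceRecord("q", "A" * 12))
        assert rec.cigar == "2S6M4S"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            alignment_to_sam(aln(), "medium", SequenceRecord("q", "A" * 9))


@pytest.fixture(scope="module")
def pipeline_run():
    refs, qrys, _ = generate_mutated_pair(
        seed=31, length=12000, n_records=2,
        inversion_count=1, inversion_length=1500,
    )
    alns = align_records(refs, qrys, RunOptions(sorted_output=True))
    return refs, qrys, alns


class TestWriteSamPipeline:
    def test_headers_one_sq_per_reference(self, pipeline_run, tmp_path):
        refs, qrys, alns = pipeline_run
        path = tmp_path / "out.sam"
        write_sam(alns, refs, qrys, "short", path)
        lines = path.read_text().splitlines()
        sq = [ln for ln in lines if ln.startswith("@SQ")]
        assert len(sq) == 2
        for rec, ln in zip(refs, sq):
            assert f"SN:{rec.id}" in ln and f"LN:{len(rec)}" in ln

    def test_long_mode_md_reconstructs_reference(self, pipeline_run, tmp_path):
        refs, qrys, alns = pipeline_run
        rbases = {r.id: r.bases for r in refs}
        path = tmp_path / "out.sam"
        write_sam(alns, refs, qrys, "long", path)
        n = 0
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                qlen = sum(
                    l for op, l in rec.cigartuples if op in (0, 1, 4, 7, 8)
                )
                assert qlen == len(rec.query_sequence)
                rebuilt = rec.get_reference_sequence().upper()
                true = rbases[rec.reference_name][
                    rec.reference_start : rec.reference_start
                    + rec.reference_length
                ]
                assert rebuilt == true
                n += 1
        assert n == len(alns) > 0

    def test_one_primary_record_per_query(self, pipeline_run, tmp_path):
        refs, qrys, alns = pipeline_run
        path = tmp_path / "out.sam"
        write_sam(alns, refs, qrys, "short", path)
        primaries = {}
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if not rec.is_secondary:
                    primaries.setdefault(rec.query_name, 0)
                    primaries[rec.query_name] += 1
        assert all(v == 1 for v in primaries.values())

    def test_delta_and_sam_agree_on_coordinates(self, pipeline_run, tmp_path):
        refs, qrys, alns = pipeline_run
        dpath, spath = tmp_path / "o.delta", tmp_path / "o.sam"
        write_delta(alns, "R", "Q", dpath)
        write_sam(alns, refs, qrys, "short", spath)
        _, _, from_delta = parse_delta(dpath)
        delta_keys = sorted(
            (a.ref_id, a.ref_start, a.ref_end, a.errors) for a in from_delta
        )
        sam_keys = []
        with pysam.AlignmentFile(str(spath), "r") as fh:
            for rec in fh:
                sam_keys.append(
                    (
                        rec.reference_name,
                        rec.reference_start + 1,
                        rec.reference_start + rec.reference_length,
                        rec.get_tag("NM"),
                    )
                )
        assert sorted(sam_keys) == delta_keys
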