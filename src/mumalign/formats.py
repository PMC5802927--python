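"""Serialisation to the MUMmer delta dialect and to SAM.

Delta layout: line 1 holds the reference and query file paths, line 2 the
program tag ``NUCMER``; then, for every (reference record, query record)
pair with alignments, a ``>`` header with both ids and both lengths,
followed by one 7-integer line per alignment (ref_start ref_end qry_start
qry_end errors sim_errors stop_codons), its signed indel offsets one per
line, and a terminating ``0``.  Reverse-strand alignments are written with
``qry_start > qry_end``.

SAM output follows SAM v1: ``--sam-short`` emits name/flag/position/CIGAR
with ``*`` sequence; ``--sam-long`` additionally carries the (strand
oriented) sequence, qualities when the query had them, and the MD tag.
MAPQ is a fixed 30 (the pipeline computes no mapping-quality model); per
query the highest-scoring record is primary and the rest carry the
secondary flag.  Unaligned query ends are soft-clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .align import Alignment, reconstruct_transcript
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "write_delta",
    "parse_delta",
    "SamRecord",
    "alignment_to_sam",
    "write_sam",
]

MAPQ = 30
FLAG_REVERSE = 16
FLAG_SECONDARY = 256


class DeltaParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _as_text_handle(sink, mode="w"):
    if isinstance(sink, (str, Path)):
        return open(sink, mode), True
    return sink, False


def write_delta(
    alignments: Sequence[Alignment],
    ref_path: str,
    qry_path: str,
    sink: str | Path | IO[str],
) -> None:
    """Emit the delta dialect; groups appear in first-occurrence order."""
    handle, owned = _as_text_handle(sink)
    try:
        handle.write(f"{ref_path} {qry_path}\nNUCMER\n")
        groups: dict[tuple[str, str], list[Alignment]] = {}
        order: list[tuple[str, str]] = []
        for aln in alignments:
            key = (aln.ref_id, aln.qry_id)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(aln)
        for key in order:
            alns = groups[key]
            first = alns[0]
            for aln in alns:
                if not (
                    1 <= aln.ref_start <= aln.ref_end <= aln.ref_len
                    and 1 <= min(aln.qry_start, aln.qry_end)
                    and max(aln.qry_start, aln.qry_end) <= aln.qry_len
                ):
                    raise ValueError(
                        f"alignment coordinates outside declared lengths: "
                        f"{aln}"
                    )
            handle.write(
                f">{key[0]} {key[1]} {first.ref_len} {first.qry_len}\n"
            )
            for aln in alns:
                handle.write(
                    f"{aln.ref_start} {aln.ref_end} "
                    f"{aln.qry_start} {aln.qry_end} "
                    f"{aln.errors} {aln.sim_errors} {aln.stop_codons}\n"
                )
                for off in aln.indels:
                    handle.write(f"{off}\n")
                handle.write("0\n")
    finally:
        if owned:
            handle.close()


def parse_delta(
    source: str | Path | IO[str],
) -> tuple[str, str, list[Alignment]]:
    """Exact inverse of :func:`write_delta`.

    Returns (reference path, query path, alignments).  Rejects non-NUCMER
    dialects (PROMER is protein-space and unsupported).
    """
    handle, owned = _as_text_handle(source, "r")
    try:
        lines = [ln.rstrip("\n") for ln in handle]
    finally:
        if owned:
            handle.close()
    if len(lines) < 2:
        raise DeltaParseError("missing header", 1)
    parts = lines[0].split()
    if len(parts) != 2:
        raise DeltaParseError("header must hold reference and query paths", 1)
    ref_path, qry_path = parts
    tag = lines[1].strip()
    if tag != "NUCMER":
        raise DeltaParseError(f"unsupported dialect {tag!r}", 2)
    alignments: list[Alignment] = []
    ref_id = qry_id = None
    ref_len = qry_len = 0
    i = 2
    n = len(lines)
    while i < n:
        ln = lines[i]
        if not ln.strip():
            i += 1
            continue
        if ln.startswith(">"):
            fields = ln[1:].split()
            if len(fields) != 4:
                raise DeltaParseError("malformed '>' group header", i + 1)
            ref_id, qry_id = fields[0], fields[1]
            try:
                ref_len, qry_len = int(fields[2]), int(fields[3])
            except ValueError:
                raise DeltaParseError("non-integer record length", i + 1)
            i += 1
            continue
        if ref_id is None:
            raise DeltaParseError("alignment record before '>' header", i + 1)
        fields = ln.split()
        if len(fields) != 7:
            raise DeltaParseError(
                f"expected 7 integers, got {len(fields)}", i + 1
            )
        try:
            rs, re_, qs, qe, err, sim, stop = map(int, fields)
        except ValueError:
            raise DeltaParseError("non-integer alignment field", i + 1)
        i += 1
        indels: list[int] = []
        terminated = False
        while i < n:
            try:
                val = int(lines[i])
            except ValueError:
                raise DeltaParseError("non-integer indel offset", i + 1)
            i += 1
            if val == 0:
                terminated = True
                break
            indels.append(val)
        if not terminated:
            raise DeltaParseError("unterminated alignment record", i)
        alignments.append(
            Alignment(
                ref_id=ref_id,
                qry_id=qry_id,
                ref_start=rs,
                ref_end=re_,
                qry_start=qs,
                qry_end=qe,
                errors=err,
                sim_errors=sim,
                stop_codons=stop,
                indels=indels,
                ref_len=ref_len,
                qry_len=qry_len,
            )
        )
    return ref_path, qry_path, alignments


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    seq: str
    qual: str
    tags: list[str] = field(default_factory=list)

    def to_line(self) -> str:
        cols = [
            self.qname, str(self.flag), self.rname, str(self.pos),
            str(self.mapq), self.cigar, "*", "0", "0", self.seq, self.qual,
        ]
        return "\t".join(cols + self.tags)


def _cigar_from_transcript(transcript: str, lead: int, tail: int) -> str:
    ops: list[tuple[str, int]] = []
    if lead:
        ops.append(("S", lead))
    for op in transcript:
        sam_op = "M" if op in "MX" else ("I" if op == "I" else "D")
        if ops and ops[-1][0] == sam_op:
            ops[-1] = (sam_op, ops[-1][1] + 1)
        else:
            ops.append((sam_op, 1))
    if tail:
        ops.append(("S", tail))
    return "".join(f"{n}{o}" for o, n in ops)


def _md_from_transcript(transcript: str, ref_slice: str) -> str:
    out: list[str] = []
    run = 0
    i = 0
    k = 0
    while k < len(transcript):
        op = transcript[k]
        if op == "M":
            run += 1
            i += 1
            k += 1
        elif op == "X":
            out.append(str(run))
            out.append(ref_slice[i])
            run = 0
            i += 1
            k += 1
        elif op == "D":
            out.append(str(run))
            run = 0
            deleted = []
            while k < len(transcript) and transcript[k] == "D":
                deleted.append(ref_slice[i])
                i += 1
                k += 1
            out.append("^" + "".join(deleted))
        else:  # I: not represented in MD
            k += 1
    out.append(str(run))
    return "".join(out)


def alignment_to_sam(
    aln: Alignment,
    mode: str,
    query_record: SequenceRecord,
    ref_bases: str | None = None,
    secondary: bool = False,
) -> SamRecord:
    """One alignment -> one SAM record.

    ``mode`` is ``'short'`` or ``'long'``; long mode needs ``ref_bases``
    (the full owning reference record) to classify mismatches for MD.
    """
    if mode not in ("short", "long"):
        raise ValueError(f"unknown SAM mode {mode!r}")
    reverse = aln.strand != "+"
    qlen = aln.qry_len or len(query_record)
    if reverse:
        adj_start = qlen - aln.qry_start + 1
        adj_end = qlen - aln.qry_end + 1
    else:
        adj_start, adj_end = aln.qry_start, aln.qry_end
    lead, tail = adj_start - 1, qlen - adj_end
    transcript = aln.transcript
    if not transcript:
        if ref_bases is None:
            # skeleton only: mismatches cannot be classified without the
            # reference, which is fine for short mode CIGARs
            from .align import delta_decode

            transcript = delta_decode(aln.indels, aln.ref_span, aln.qry_span)
        else:
            transcript = reconstruct_transcript(
                aln, ref_bases, query_record.bases
            )
    flag = (FLAG_REVERSE if reverse else 0) | (FLAG_SECONDARY if secondary else 0)
    cigar = _cigar_from_transcript(transcript, lead, tail)
    tags = [f"NM:i:{aln.errors}"]
    seq = qual = "*"
    if mode == "long":
        seq = (
            reverse_complement(query_record.bases)
            if reverse
            else query_record.bases
        )
        if query_record.qualities is not None:
            q = query_record.qualities
            q = q[::-1] if reverse else q
            qual = "".join(chr(v + 33) for v in q)
        if ref_bases is not None:
            ref_slice = ref_bases[aln.ref_start - 1 : aln.ref_end]
            tags.append(f"MD:Z:{_md_from_transcript(transcript, ref_slice)}")
    return SamRecord(
        qname=aln.qry_id,
        flag=flag,
        rname=aln.ref_id,
        pos=aln.ref_start,
        mapq=MAPQ,
        cigar=cigar,
        seq=seq,
        qual=qual,
        tags=tags,
    )


def write_sam(
    alignments: Sequence[Alignment],
    ref_records: Sequence[SequenceRecord],
    qry_records: Sequence[SequenceRecord],
    mode: str,
    sink: str | Path | IO[str],
) -> None:
    """Emit a SAM file with @HD/@SQ headers for every reference record."""
    ref_by_id = {r.id: r for r in ref_records}
    qry_by_id = {r.id: r for r in qry_records}
    handle, owned = _as_text_handle(sink)
    try:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in ref_records:
            handle.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}\n")
        handle.write("@PG\tID:mumalign\tPN:mumalign\n")
        # primary = best score (longest query span as fallback) per query
        best: dict[str, Alignment] = {}
        for aln in alignments:
            key = aln.qry_id
            cur = best.get(key)
            rank = (aln.score, aln.qry_span, -aln.errors)
            if cur is None or rank > (cur.score, cur.qry_span, -cur.errors):
                best[key] = aln
        for aln in alignments:
            qrec = qry_by_id[aln.qry_id]
            ref_bases = ref_by_id[aln.ref_id].bases
            rec = alignment_to_sam(
                aln,
                mode,
                qrec,
                ref_bases=ref_bases,
                secondary=best[aln.qry_id] is not aln,
            )
            handle.write(rec.to_line() + "\n")
    finally:
        if owned:
            handle.close()
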