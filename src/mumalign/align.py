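"""Cluster extension and gapped alignment (the postnuc stage).

Each cluster's seed chain is turned into one or more gapped alignments:
the gaps between consecutive seeds are filled with banded global dynamic
programming, the two outer ends are extended outward until the running
score falls a break threshold below its maximum (then trimmed back to the
maximum), and adjacent colinear chains whose separating gaps are small are
joined into a single record.  Alignments are stored with MUMmer-style
signed indel offsets and an error count (mismatches plus indel bases).

Scoring is linear: match +3, mismatch -3, gap base -4 by default.  The
transcript alphabet is ``M`` (match), ``X`` (substitution), ``D`` (base in
reference aligned to a gap in the query, a positive delta offset) and ``I``
(gap in the reference, negative offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import Cluster
from .seeds import FORWARD, Match
from .seqio import ConcatenatedReference, SequenceRecord, reverse_complement

__all__ = [
    "AlignmentOptions",
    "Alignment",
    "banded_global_align",
    "extend_and_join",
    "align_clusters",
    "delta_encode",
    "delta_decode",
    "translate_alignment",
    "reconstruct_transcript",
]

NEG_INF = -(10**15)


@dataclass(frozen=True)
class AlignmentOptions:
    """postnuc parameters.

    ``break_len`` is the maximum distance an extension may continue past
    its best-scoring point without net improvement; once exceeded the
    extension stops and the alignment is trimmed back to that maximum.
    ``band_width`` is the extra half-width added to the diagonal span when
    filling inter-seed gaps.
    """

    break_len: int = 200
    band_width: int = 5
    match_score: int = 3
    mismatch_score: int = -3
    gap_score: int = -4
    #: clusters separated by gaps of at most this many bases on both sides
    #: are joined into one alignment record (0 disables joining)
    join_limit: int = 1000
    #: half-width of the adaptive band used for outward extension; wide
    #: enough to absorb indel drift over an extension span, narrow enough
    #: not to chase spurious matches in non-homologous sequence
    extension_band: int = 8

    @property
    def break_score(self) -> int:
        return self.break_len * abs(self.gap_score)


@dataclass
class Alignment:
    """A gapped pairwise alignment in record-local coordinates.

    Coordinates are 1-based inclusive; ``qry_start > qry_end`` marks a
    reverse-strand alignment (query coordinates on the forward strand).
    ``indels`` uses the MUMmer delta convention (see :func:`delta_encode`).
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    errors: int
    sim_errors: int
    stop_codons: int
    indels: list[int]
    ref_len: int = 0
    qry_len: int = 0
    score: int = field(default=0, compare=False)
    transcript: str = field(default="", compare=False, repr=False)

    @property
    def strand(self) -> str:
        return FORWARD if self.qry_start <= self.qry_end else "-"

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def qry_span(self) -> int:
        return abs(self.qry_end - self.qry_start) + 1


def _score_fn(opts: AlignmentOptions):
    m, x = opts.match_score, opts.mismatch_score
    return lambda a, b: m if a == b else x


def banded_global_align(
    ref_sub: str,
    qry_sub: str,
    band_width: int,
    opts: AlignmentOptions = AlignmentOptions(),
) -> tuple[str, int]:
    """Optimal global alignment restricted to a band around the
    corner-to-corner diagonal; the band auto-widens to at least the length
    difference so the corners always connect.  Returns (transcript, score).
    With a band at least as wide as both strings this equals unbanded
    Needleman-Wunsch."""
    la, lb = len(ref_sub), len(qry_sub)
    if la == 0:
        return "I" * lb, opts.gap_score * lb
    if lb == 0:
        return "D" * la, opts.gap_score * la
    w = max(band_width, abs(la - lb) + 1, 1)
    g = opts.gap_score
    a = np.frombuffer(ref_sub.encode(), dtype=np.uint8)
    b = np.frombuffer(qry_sub.encode(), dtype=np.uint8)

    def window(i: int) -> tuple[int, int]:
        c = round(i * lb / la)
        return max(0, c - w), min(lb, c + w)

    prev = np.arange(0, min(lb, w) + 1, dtype=np.int64) * g
    prev_lo = 0
    rows: list[tuple[int, np.ndarray]] = []
    for i in range(1, la + 1):
        lo, hi = window(i)
        js = np.arange(lo, hi + 1)

        def prev_at(j_arr):
            vals = np.full(len(j_arr), NEG_INF, dtype=np.int64)
            ok = (j_arr >= prev_lo) & (j_arr < prev_lo + len(prev))
            vals[ok] = prev[j_arr[ok] - prev_lo]
            return vals

        subs = np.where(
            b[np.maximum(js - 1, 0)] == a[i - 1],
            opts.match_score,
            opts.mismatch_score,
        )
        diag = prev_at(js - 1)
        diag = np.where(diag > NEG_INF, diag + subs, NEG_INF)
        up = prev_at(js)
        up = np.where(up > NEG_INF, up + g, NEG_INF)
        no_left = np.maximum(diag, up)
        # left-gap chains: cur[j] = max_k<j (no_left[k] + g*(j-k)),
        # computed with a running maximum of no_left[k] - g*k
        run = np.maximum.accumulate(no_left - g * js)
        left = np.concatenate(([NEG_INF], run[:-1] + g * js[1:]))
        cur = np.maximum(no_left, left)
        ptr = np.where(cur == diag, 0, np.where(cur == up, 1, 2)).astype(np.int8)
        rows.append((lo, ptr))
        prev, prev_lo = cur, lo
    # traceback from (la, lb)
    i, j = la, lb
    out: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            out.append("I")
            j -= 1
            continue
        lo, ptr = rows[i - 1]
        if j < lo:
            # outside the band at row i: only up-moves can have led here
            out.append("D")
            i -= 1
            continue
        p = ptr[j - lo] if j - lo < len(ptr) else 1
        if j == 0:
            p = 1
        if p == 0:
            out.append("M" if ref_sub[i - 1] == qry_sub[j - 1] else "X")
            i -= 1
            j -= 1
        elif p == 1:
            out.append("D")
            i -= 1
        else:
            out.append("I")
            j -= 1
    score = int(prev[lb - prev_lo])
    return "".join(reversed(out)), score


def transcript_score(transcript: str, opts: AlignmentOptions) -> int:
    return (
        transcript.count("M") * opts.match_score
        + transcript.count("X") * opts.mismatch_score
        + (transcript.count("I") + transcript.count("D")) * opts.gap_score
    )


def extend_outward(
    ref_tail: str,
    qry_tail: str,
    opts: AlignmentOptions,
) -> str:
    """Greedy outward extension from an alignment end into ``ref_tail`` /
    ``qry_tail`` (both read in the direction of extension).  A banded DP
    follows the best diagonal; extension stops once it has advanced more
    than ``break_len`` bases past the best-scoring cell without improving
    on it, then the transcript is trimmed back to that cell."""
    la, lb = len(ref_tail), len(qry_tail)
    if la == 0 or lb == 0:
        return ""
    w = opts.extension_band
    g = opts.gap_score
    m_sc, x_sc = opts.match_score, opts.mismatch_score
    a = ref_tail
    b = qry_tail
    best = (0, 0, 0)  # score, i, j
    prev = {0: 0}
    prev_best_j = 0
    rows: list[dict[int, int]] = []  # ptr per (i, j)
    # row 0 left-gaps are never useful (negative), so start from (0,0) only
    for i in range(1, la + 1):
        # band follows the best diagonal of the previous row
        lo = max(0, prev_best_j + 1 - w)
        hi = min(lb, prev_best_j + 1 + w)
        cur: dict[int, int] = {}
        ptrs: dict[int, int] = {}
        ai = a[i - 1]
        row_best = NEG_INF
        for j in range(lo, hi + 1):
            cand = NEG_INF
            p = -1
            if j - 1 in prev:
                s = prev[j - 1] + (m_sc if ai == b[j - 1] else x_sc)
                if s > cand:
                    cand, p = s, 0
            if j in prev:
                s = prev[j] + g
                if s > cand:
                    cand, p = s, 1
            if j - 1 in cur:
                s = cur[j - 1] + g
                if s > cand:
                    cand, p = s, 2
            if cand == NEG_INF:
                continue
            cur[j] = cand
            ptrs[j] = p
            if cand > row_best:
                row_best = cand
            if cand > best[0]:
                best = (cand, i, j)
        rows.append(ptrs)
        if not cur or i - best[1] > opts.break_len:
            break
        prev = cur
        prev_best_j = max(cur, key=lambda k: (cur[k], -k))
    # traceback from best cell
    score, bi, bj = best
    if bi == 0:
        return ""
    out: list[str] = []
    i, j = bi, bj
    while i > 0 or j > 0:
        if i == 0:
            out.append("I")
            j -= 1
            continue
        p = rows[i - 1].get(j, 1 if j == 0 else None)
        if p is None:
            p = 1
        if p == 0:
            out.append("M" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
        elif p == 1:
            out.append("D")
            i -= 1
        else:
            out.append("I")
            j -= 1
    return "".join(reversed(out))


def delta_encode(transcript: str) -> list[int]:
    """Transcript -> MUMmer signed indel offsets: each value's magnitude is
    the column distance from the previous indel (or alignment start) to
    this one, counted on the side that has a base; positive = reference
    base over a query gap, negative = reference gap."""
    out: list[int] = []
    count = 0
    for op in transcript:
        count += 1
        if op == "D":
            out.append(count)
            count = 0
        elif op == "I":
            out.append(-count)
            count = 0
    return out


def delta_decode(offsets: list[int], ref_span: int, qry_span: int) -> str:
    """Offsets -> transcript skeleton ('M' for every aligned pair; the
    mismatch positions are not recoverable from the delta encoding)."""
    ops: list[str] = []
    ref_used = qry_used = 0
    for off in offsets:
        if off == 0:
            raise ValueError("zero is a terminator, not an offset")
        run = abs(off) - 1
        ops.append("M" * run)
        ref_used += run
        qry_used += run
        if off > 0:
            ops.append("D")
            ref_used += 1
        else:
            ops.append("I")
            qry_used += 1
    rest_ref = ref_span - ref_used
    rest_qry = qry_span - qry_used
    if rest_ref != rest_qry or rest_ref < 0:
        raise ValueError(
            f"indel offsets inconsistent with spans {ref_span}/{qry_span}"
        )
    ops.append("M" * rest_ref)
    return "".join(ops)


def count_errors(transcript: str) -> int:
    return sum(1 for op in transcript if op != "M")


def _trim_overlap(chain: list[Match]) -> list[Match]:
    """Shorten each seed from the left so consecutive seeds never overlap
    in either coordinate (the chain is strictly increasing in both starts,
    but ends may reach past the next start)."""
    out: list[Match] = []
    for m in chain:
        if out:
            prevm = out[-1]
            t = max(
                prevm.ref_end - m.ref_start + 1,
                prevm.qry_end - m.qry_start + 1,
                0,
            )
            if t >= m.length:
                continue
            if t:
                m = Match(
                    m.ref_start + t, m.qry_start + t, m.length - t, m.strand
                )
        out.append(m)
    return out


@dataclass
class _Piece:
    """Accumulator for one alignment record in S-global / strand-adjusted
    query coordinates."""

    ref_start: int  # 1-based in S
    qry_start: int  # 1-based in strand-adjusted query
    transcript: list[str] = field(default_factory=list)

    def text(self) -> str:
        return "".join(self.transcript)


def _chains_to_pieces(
    chains: list[list[Match]],
    ref_text: str,
    qry_text: str,
    opts: AlignmentOptions,
) -> list[_Piece]:
    """Fill gaps inside (and between joined) chains; split where a gap
    alignment collapses below the break threshold."""
    pieces: list[_Piece] = []
    for chain in chains:
        chain = _trim_overlap(chain)
        if not chain:
            continue
        piece = _Piece(chain[0].ref_start, chain[0].qry_start)
        piece.transcript.append("M" * chain[0].length)
        for prevm, m in zip(chain, chain[1:]):
            gr = ref_text[prevm.ref_end : m.ref_start - 1]
            gq = qry_text[prevm.qry_end : m.qry_start - 1]
            band = abs(len(gr) - len(gq)) + opts.band_width + 10
            transcript, score = banded_global_align(gr, gq, band, opts)
            if score <= -opts.break_score and (gr or gq):
                pieces.append(piece)
                piece = _Piece(m.ref_start, m.qry_start)
            else:
                piece.transcript.append(transcript)
            piece.transcript.append("M" * m.length)
        pieces.append(piece)
    return pieces


def _extend_piece(
    piece: _Piece, ref_text: str, qry_text: str,
    ref_lo: int, ref_hi: int, opts: AlignmentOptions,
) -> _Piece:
    """Extend one piece outward in both directions.  ``ref_lo``/``ref_hi``
    are the 0-based bounds of the owning reference record inside S, so the
    extension never crosses a separator."""
    body = piece.text()
    ref_end = piece.ref_start - 1 + sum(1 for o in body if o in "MXD")
    qry_end = piece.qry_start - 1 + sum(1 for o in body if o in "MXI")
    left = extend_outward(
        ref_text[ref_lo : piece.ref_start - 1][::-1],
        qry_text[: piece.qry_start - 1][::-1],
        opts,
    )[::-1]
    right = extend_outward(
        ref_text[ref_end:ref_hi], qry_text[qry_end:], opts
    )
    new = _Piece(
        piece.ref_start - sum(1 for o in left if o in "MXD"),
        piece.qry_start - sum(1 for o in left if o in "MXI"),
        [left, body, right],
    )
    return new


def _piece_to_alignment(
    piece: _Piece,
    ref: ConcatenatedReference,
    qry: SequenceRecord,
    strand: str,
    opts: AlignmentOptions,
) -> Alignment:
    transcript = piece.text()
    ref_cols = sum(1 for o in transcript if o in "MXD")
    qry_cols = sum(1 for o in transcript if o in "MXI")
    s_start = piece.ref_start  # 1-based in S
    s_end = s_start + ref_cols - 1
    rid, local_start = ref.global_to_local(s_start - 1)
    local_end = local_start + ref_cols - 1
    qlen = len(qry)
    adj_start, adj_end = piece.qry_start, piece.qry_start + qry_cols - 1
    if strand == FORWARD:
        q_start, q_end = adj_start, adj_end
    else:
        q_start, q_end = qlen - adj_start + 1, qlen - adj_end + 1
    errors = count_errors(transcript)
    return Alignment(
        ref_id=rid,
        qry_id=qry.id,
        ref_start=local_start,
        ref_end=local_end,
        qry_start=q_start,
        qry_end=q_end,
        errors=errors,
        sim_errors=errors,
        stop_codons=0,
        indels=delta_encode(transcript),
        ref_len=ref.record_length(rid),
        qry_len=qlen,
        score=transcript_score(transcript, opts),
        transcript=transcript,
    )


def _joinable(a: list[Match], b: list[Match], opts: AlignmentOptions) -> bool:
    """Chains may be joined when the second makes progress in both
    coordinates, the separating gaps (possibly negative: overlap is trimmed
    later) are small, and the diagonals are consistent."""
    if b[-1].ref_end <= a[-1].ref_end or b[-1].qry_end <= a[-1].qry_end:
        return False
    gr = b[0].ref_start - a[-1].ref_end - 1
    gq = b[0].qry_start - a[-1].qry_end - 1
    if gr > opts.join_limit or gq > opts.join_limit:
        return False
    return abs(b[0].diagonal - a[-1].diagonal) <= opts.break_len


def align_clusters(
    clusters: list[Cluster],
    ref: ConcatenatedReference,
    qry: SequenceRecord,
    opts: AlignmentOptions = AlignmentOptions(),
) -> list[Alignment]:
    """Turn clusters for one query into alignment records: join adjacent
    colinear chains, fill seed gaps, extend the outer ends, emit."""
    out: list[Alignment] = []
    by_part: dict[tuple[str | None, str], list[Cluster]] = {}
    for c in clusters:
        by_part.setdefault((c.ref_record, c.strand), []).append(c)
    for (rid, strand), group in sorted(
        by_part.items(), key=lambda kv: (kv[0][0] or "", kv[0][1])
    ):
        qry_text = (
            qry.bases if strand == FORWARD else reverse_complement(qry.bases)
        )
        group = sorted(group, key=lambda c: (c.ref_start, c.qry_start))
        # greedily join colinear neighbours
        joined: list[list[list[Match]]] = []
        for c in group:
            if (
                joined
                and opts.join_limit > 0
                and _joinable(joined[-1][-1], c.matches, opts)
            ):
                joined[-1].append(c.matches)
            else:
                joined.append([c.matches])
        for run in joined:
            chain = sorted(
                (m for part in run for m in part),
                key=lambda m: (m.ref_start, m.qry_start),
            )
            pieces = _chains_to_pieces([chain], ref.S, qry_text, opts)
            rec0 = ref.record_index(chain[0].ref_start - 1)
            rrid, rlen, rstart = ref.boundaries[rec0]
            for piece in pieces:
                piece = _extend_piece(
                    piece, ref.S, qry_text, rstart, rstart + rlen, opts
                )
                out.append(_piece_to_alignment(piece, ref, qry, strand, opts))
    # shadow elimination: extension of parallel chains over one region can
    # produce a record contained (in both coordinates, same strand) within
    # another; keep only the best of each such nest
    ranked = sorted(
        out, key=lambda a: (-a.score, a.ref_id, a.ref_start, a.qry_start)
    )
    unique: list[Alignment] = []
    for aln in ranked:
        qlo, qhi = sorted((aln.qry_start, aln.qry_end))
        shadowed = False
        for keep in unique:
            if keep.ref_id != aln.ref_id or keep.strand != aln.strand:
                continue
            klo, khi = sorted((keep.qry_start, keep.qry_end))
            if (
                keep.ref_start <= aln.ref_start
                and aln.ref_end <= keep.ref_end
                and klo <= qlo
                and qhi <= khi
            ):
                shadowed = True
                break
        if not shadowed:
            unique.append(aln)
    unique.sort(key=lambda a: (a.ref_id, a.ref_start, a.ref_end,
                               a.qry_start, a.qry_end))
    return unique


def extend_and_join(
    cluster: Cluster,
    ref: ConcatenatedReference,
    qry: SequenceRecord,
    opts: AlignmentOptions = AlignmentOptions(),
) -> list[Alignment]:
    """Alignments from a single cluster (no cross-cluster joining)."""
    return align_clusters([cluster], ref, qry, opts)


def translate_alignment(
    s_start: int,
    s_end: int,
    ref: ConcatenatedReference,
) -> tuple[str, int, int]:
    """1-based inclusive S-global reference span -> (record id, 1-based
    local start, local end).  The span must not cross a separator."""
    rid, local_start = ref.global_to_local(s_start - 1)
    rid2, local_end = ref.global_to_local(s_end - 1)
    if rid != rid2:
        raise ValueError("alignment crosses a separator")
    return rid, local_start, local_end


def reconstruct_transcript(
    aln: Alignment, ref_bases: str, qry_bases: str
) -> str:
    """Rebuild the full transcript (with mismatches classified) from an
    alignment's coordinates and indel offsets plus the actual sequences."""
    skeleton = delta_decode(aln.indels, aln.ref_span, aln.qry_span)
    r = ref_bases[aln.ref_start - 1 : aln.ref_end]
    if aln.strand == FORWARD:
        q = qry_bases[aln.qry_start - 1 : aln.qry_end]
    else:
        q = reverse_complement(qry_bases[aln.qry_end - 1 : aln.qry_start])
    out: list[str] = []
    i = j = 0
    for op in skeleton:
        if op == "M":
            out.append("M" if r[i] == q[j] else "X")
            i += 1
            j += 1
        elif op == "D":
            out.append("D")
            i += 1
        else:
            out.append("I")
            j += 1
    return "".join(out)
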