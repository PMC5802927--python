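"""Synthetic (reference, mutated query, truth) triples for testing.

The generator draws a uniform-ACGT reference, then derives a query by an
independent per-base mutation process — substitutions at ``snp_rate``
(always to a different base), single-base insertions at ``ins_rate``,
single-base deletions at ``del_rate`` — plus a stated number of segmental
inversions (reverse complement of a contiguous slice).  The truth ledger
records every edit with reference coordinates, so end-to-end tests can
compare recovered alignments and error counts against what was planted.

Everything is driven by one integer seed; a fixed seed reproduces the pair
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, reverse_complement

__all__ = ["MutationTruth", "generate_mutated_pair"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MutationTruth:
    """Planted edits.  Coordinates are 1-based on the reference record
    named in each entry; edits are (kind, record, position, detail)."""

    edits: list[tuple[str, str, int, str]] = field(default_factory=list)
    inversions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def edit_count(self) -> int:
        """Planted single-base edits (substituted, inserted or deleted
        bases); inversions are structural and counted separately."""
        return len(self.edits)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _mutate_segment(
    rng: np.random.Generator,
    segment: str,
    rid: str,
    offset: int,
    snp_rate: float,
    ins_rate: float,
    del_rate: float,
    truth: MutationTruth,
) -> str:
    n = len(segment)
    draw = rng.random((3, n))
    dels = draw[0] < del_rate
    snps = (draw[1] < snp_rate) & ~dels
    ins = draw[2] < ins_rate
    snp_shift = rng.integers(1, 4, size=n)
    ins_base = rng.choice(_BASES, size=n)
    raw = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    out: list[str] = []
    lut = {ord(c): i for i, c in enumerate("ACGT")}
    for i in range(n):
        pos = offset + i + 1
        if dels[i]:
            truth.edits.append(("del", rid, pos, segment[i]))
        else:
            c = segment[i]
            if snps[i]:
                new = "ACGT"[(lut[raw[i]] + snp_shift[i]) % 4]
                truth.edits.append(("snp", rid, pos, f"{c}>{new}"))
                c = new
            out.append(c)
        if ins[i]:
            b = chr(ins_base[i])
            truth.edits.append(("ins", rid, pos, b))
            out.append(b)
    return "".join(out)


def generate_mutated_pair(
    seed: int,
    length: int = 200_000,
    n_records: int = 1,
    snp_rate: float = 0.02,
    ins_rate: float = 0.002,
    del_rate: float = 0.002,
    inversion_count: int = 0,
    inversion_length: int = 5000,
    edge_margin: int = 2000,
) -> tuple[list[SequenceRecord], list[SequenceRecord], MutationTruth]:
    """Build (reference records, query records, truth ledger).

    ``length`` is the per-record reference length.  Inversions are placed
    disjointly, at least ``edge_margin`` bases from record ends so both
    flanks can anchor alignments.  All rates must lie in [0, 1).
    """
    for r in (snp_rate, ins_rate, del_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must lie in [0, 1)")
    if length < 1 or n_records < 1:
        raise ValueError("length and n_records must be >= 1")
    rng = np.random.default_rng(seed)
    truth = MutationTruth()
    refs: list[SequenceRecord] = []
    qrys: list[SequenceRecord] = []
    inversions_left = inversion_count
    for rec_i in range(n_records):
        rid = f"ref_{rec_i + 1}"
        bases = _random_bases(rng, length)
        refs.append(SequenceRecord(rid, bases))
        # place disjoint inversions for this record, away from the edges
        spans: list[tuple[int, int]] = []
        usable = length - 2 * edge_margin - inversion_length
        while inversions_left > 0 and usable >= 0:
            placed = False
            for _attempt in range(100):
                start = int(rng.integers(edge_margin, edge_margin + usable + 1))
                span = (start, start + inversion_length)
                if all(span[1] < s or span[0] > e for s, e in spans):
                    spans.append(span)
                    inversions_left -= 1
                    placed = True
                    break
            if not placed:
                break
        spans.sort()
        pieces: list[str] = []
        cursor = 0
        for s, e in spans:
            pieces.append(
                _mutate_segment(
                    rng, bases[cursor:s], rid, cursor,
                    snp_rate, ins_rate, del_rate, truth,
                )
            )
            inv = _mutate_segment(
                rng, bases[s:e], rid, s, snp_rate, ins_rate, del_rate, truth
            )
            pieces.append(reverse_complement(inv))
            truth.inversions.append((rid, s + 1, e))
            cursor = e
        pieces.append(
            _mutate_segment(
                rng, bases[cursor:], rid, cursor,
                snp_rate, ins_rate, del_rate, truth,
            )
        )
        qrys.append(SequenceRecord(f"qry_{rec_i + 1}", "".join(pieces)))
    if inversions_left > 0:
        raise ValueError(
            f"could not place {inversions_left} of {inversion_count} "
            f"inversions: records too short for the requested length/margin"
        )
    return refs, qrys, truth
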