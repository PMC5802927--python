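"""Sequence input/output and the concatenated reference string.

The aligner indexes the reference as a single string ``S`` obtained by
joining every reference record with a separator character (lowercase
``'x'``) that cannot occur in the uppercased sequence alphabet.  All seed
matching happens in ``S``-global coordinates; this module owns the
bidirectional map between global offsets and per-record 1-based positions.
"""

from __future__ import annotations

import io as _io
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "SequenceRecord",
    "ConcatenatedReference",
    "read_sequences",
    "write_fasta",
    "reverse_complement",
    "concat_reference",
    "MAX_REFERENCE_LENGTH",
    "SEPARATOR",
]

#: Hard capacity bound on the concatenated reference string (48-bit index).
MAX_REFERENCE_LENGTH = 2**47 - 1

#: Separator joining reference records inside S.  Record bases are
#: uppercased on input, so a lowercase letter can never collide.
SEPARATOR = "x"

_IUPAC = set("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CapacityError(ValueError):
    """Input exceeds the 2^47 - 1 reference-length contract."""


@dataclass
class SequenceRecord:
    """One named sequence with optional per-base Phred qualities.

    Record ids may be arbitrarily long (no 128-character truncation) and
    must contain no whitespace; everything after the first whitespace in a
    header is the description.
    """

    id: str
    bases: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if len(self.bases) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(bases: str) -> str:
    """Watson-Crick complement, reversed.  ``N`` maps to ``N``."""
    for c in set(bases.upper()):
        if c not in _IUPAC:
            raise ValueError(f"non-IUPAC character {c!r}")
    return bases.translate(_COMPLEMENT)[::-1]


def _open(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="ascii"), True
    if isinstance(source, (bytes, bytearray)):
        return _io.StringIO(source.decode("ascii")), True
    return source, False


def read_sequences(
    source: str | Path | IO[str],
    format: str = "auto",
) -> Iterator[SequenceRecord]:
    """Stream records from FASTA or FASTQ (Phred+33).

    ``format='auto'`` sniffs the first non-blank character: ``>`` means
    FASTA, ``@`` means FASTQ.  Bases are uppercased; qualities are kept only
    for FASTQ.  Multi-line FASTA and CRLF endings are accepted.  An empty
    source yields nothing.
    """
    handle, owned = _open(source)
    try:
        lines = enumerate((ln.rstrip("\r\n") for ln in handle), start=1)
        first = None
        for lineno, ln in lines:
            if ln.strip():
                first = (lineno, ln)
                break
        if first is None:
            return
        if format == "auto":
            format = "fasta" if first[1][0] == ">" else "fastq"
        if format == "fasta":
            yield from _read_fasta(first, lines)
        elif format == "fastq":
            yield from _read_fastq(first, lines)
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if owned:
            handle.close()


def _split_header(header: str, lineno: int, tag: str) -> tuple[str, str]:
    if not header.startswith(tag):
        raise ParseError(f"expected {tag!r} header, got {header[:20]!r}", lineno)
    body = header[1:].strip()
    if not body:
        raise ParseError("empty sequence header", lineno)
    parts = body.split(None, 1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def _read_fasta(first, lines) -> Iterator[SequenceRecord]:
    lineno, header = first
    rid, desc = _split_header(header, lineno, ">")
    chunks: list[str] = []
    head_line = lineno
    for lineno, ln in lines:
        if ln.startswith(">"):
            if not chunks:
                raise ParseError(f"record {rid!r} has no sequence", head_line)
            yield SequenceRecord(rid, "".join(chunks).upper(), desc)
            rid, desc = _split_header(ln, lineno, ">")
            chunks = []
            head_line = lineno
        elif ln.strip():
            chunks.append(ln.strip())
    if not chunks:
        raise ParseError(f"record {rid!r} has no sequence", head_line)
    yield SequenceRecord(rid, "".join(chunks).upper(), desc)


def _read_fastq(first, lines) -> Iterator[SequenceRecord]:
    pending = first
    while pending is not None:
        lineno, header = pending
        rid, desc = _split_header(header, lineno, "@")
        try:
            _, seq = next(lines)
            plus_no, plus = next(lines)
            qual_no, qual = next(lines)
        except StopIteration:
            raise ParseError(f"truncated FASTQ record {rid!r}", lineno) from None
        if not plus.startswith("+"):
            raise ParseError("missing '+' separator line", plus_no)
        if len(qual) != len(seq):
            raise ParseError(
                f"record {rid!r}: {len(qual)} quality values for "
                f"{len(seq)} bases",
                qual_no,
            )
        yield SequenceRecord(
            rid, seq.upper(), desc, [ord(c) - 33 for c in qual]
        )
        pending = next(lines, None)
        if pending is not None and not pending[1].strip():
            pending = next(lines, None)


def write_fasta(records: Iterable[SequenceRecord], sink: str | Path | IO[str],
                width: int = 70) -> None:
    handle, owned = (open(sink, "w"), True) if isinstance(sink, (str, Path)) \
        else (sink, False)
    try:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            handle.write(head + "\n")
            for i in range(0, len(rec.bases), width):
                handle.write(rec.bases[i:i + width] + "\n")
    finally:
        if owned:
            handle.close()


@dataclass
class ConcatenatedReference:
    """The separator-joined reference string plus its coordinate map."""

    S: str
    #: (record id, record length, 0-based global start) in input order.
    boundaries: list[tuple[str, int, int]]
    separator: str = SEPARATOR
    _starts: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._starts:
            self._starts = [b[2] for b in self.boundaries]

    def record_ids(self) -> list[str]:
        return [b[0] for b in self.boundaries]

    def record_length(self, rid: str) -> int:
        for b in self.boundaries:
            if b[0] == rid:
                return b[1]
        raise KeyError(rid)

    def record_index(self, global_pos: int) -> int:
        """Index of the record owning ``global_pos`` (0-based, no separator)."""
        if not 0 <= global_pos < len(self.S):
            raise IndexError(f"global position {global_pos} out of range")
        i = bisect_right(self._starts, global_pos) - 1
        rid, length, start = self.boundaries[i]
        if global_pos >= start + length:
            raise ValueError(
                f"global position {global_pos} addresses a separator"
            )
        return i

    def global_to_local(self, global_pos: int) -> tuple[str, int]:
        """0-based global offset -> (record id, 1-based local position)."""
        i = self.record_index(global_pos)
        rid, _, start = self.boundaries[i]
        return rid, global_pos - start + 1

    def local_to_global(self, rid: str, local_pos: int) -> int:
        """(record id, 1-based local) -> 0-based global offset."""
        for brid, length, start in self.boundaries:
            if brid == rid:
                if not 1 <= local_pos <= length:
                    raise IndexError(f"{rid}:{local_pos} out of range")
                return start + local_pos - 1
        raise KeyError(rid)


def check_capacity(total_bases: int, n_records: int) -> None:
    total = total_bases + max(n_records - 1, 0)
    if total > MAX_REFERENCE_LENGTH:
        raise CapacityError(
            f"concatenated reference of {total} characters exceeds the "
            f"2^47 - 1 limit"
        )


def concat_reference(
    records: Sequence[SequenceRecord],
    separator: str = SEPARATOR,
) -> ConcatenatedReference:
    """Join records into ``S`` with one separator between each pair.

    The separator must be a single character outside the (uppercased)
    sequence alphabet so that no exact seed can span it.
    """
    if not records:
        raise ValueError("cannot concatenate zero records")
    if len(separator) != 1 or separator.upper() in _IUPAC:
        raise ValueError(f"invalid separator {separator!r}")
    check_capacity(sum(len(r) for r in records), len(records))
    boundaries = []
    offset = 0
    parts = []
    for rec in records:
        boundaries.append((rec.id, len(rec), offset))
        parts.append(rec.bases)
        offset += len(rec) + 1
    return ConcatenatedReference(separator.join(parts), boundaries, separator)


def global_to_local(ref: ConcatenatedReference, global_pos: int) -> tuple[str, int]:
    """Functional alias for :meth:`ConcatenatedReference.global_to_local`."""
    return ref.global_to_local(global_pos)
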