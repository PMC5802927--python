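"""Suffix-array index over the concatenated reference.

The index holds three arrays over the text ``S``: the suffix array ``sa``
(suffix start offsets in lexicographic order), its inverse ``isa``
(``isa[sa[i]] = i``), and the LCP array (``lcp[i]`` = length of the longest
common prefix of the suffixes at ranks ``i-1`` and ``i``; ``lcp[0] = 0``).

Construction uses prefix doubling over numpy sorts: O(n log n) passes of
``lexsort``, deterministic for a fixed text, with no sentinel appended —
a rank of -1 past the end makes a shorter suffix sort before any extension,
matching plain string comparison.

The index can be saved to a small versioned binary file together with a
digest of the text, so a stale index is detected on load.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .seqio import ConcatenatedReference, SequenceRecord, concat_reference

__all__ = [
    "SuffixIndex",
    "ReferenceBatch",
    "build_index",
    "save_index",
    "load_index",
    "batch_reference",
    "suffix_array",
    "lcp_array",
]

_MAGIC = b"MUMALIGN"
_VERSION = 1


class IndexFormatError(ValueError):
    """Unreadable or wrong-version index file."""


class StaleIndexError(ValueError):
    """Index digest does not match the supplied reference text."""


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling."""
    n = len(codes)
    if n == 0:
        raise ValueError("cannot index an empty text")
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        sorted_rank = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = sorted_rank
        if sorted_rank[-1] == n - 1:
            return sa
        k *= 2


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP of lexicographically adjacent suffixes, computed by vectorised
    simultaneous extension of all adjacent pairs (work O(n + sum of LCPs))."""
    n = len(sa)
    lcp = np.zeros(n, dtype=np.int64)
    if n < 2:
        return lcp
    a = sa[:-1].copy()
    b = sa[1:].copy()
    slot = np.arange(1, n)
    off = 0
    while len(slot):
        ai = a + off
        bi = b + off
        ok = (ai < n) & (bi < n)
        ok[ok] = codes[ai[ok]] == codes[bi[ok]]
        lcp[slot[ok]] += 1
        a, b, slot = a[ok], b[ok], slot[ok]
        off += 1
    return lcp


def encode_text(text: str) -> np.ndarray:
    """Text -> int64 codes preserving character order (plain ordinals)."""
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)


def encode_seed_alphabet(text: str, special_base: int = 5) -> np.ndarray:
    """Encode for seed matching: A,C,G,T -> 1..4; every other character
    (N, ambiguity codes, separators) gets a unique code so it equals
    nothing, not even itself at another position.  Exact matches over this
    encoding therefore never contain N or cross a separator."""
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(len(raw), dtype=np.int64)
    for i, ch in enumerate(b"ACGT"):
        codes[raw == ch] = i + 1
    other = codes == 0
    codes[other] = special_base + np.arange(int(other.sum()), dtype=np.int64)
    return codes


@dataclass
class SuffixIndex:
    """sa / isa / lcp triple over a text, with persistence metadata."""

    text: str
    sa: np.ndarray
    isa: np.ndarray
    lcp: np.ndarray
    digest: str = ""
    version: int = _VERSION

    def __post_init__(self) -> None:
        if not self.digest:
            self.digest = text_digest(self.text)

    @property
    def n(self) -> int:
        return len(self.sa)

    def unique_span(self, pos: int, length: int) -> bool:
        """True iff the length-``length`` substring starting at text offset
        ``pos`` occurs exactly once in the text.  O(1): the substring
        repeats iff a lexicographic neighbour shares a prefix >= length."""
        r = int(self.isa[pos])
        if r > 0 and self.lcp[r] >= length:
            return False
        if r + 1 < self.n and self.lcp[r + 1] >= length:
            return False
        return True


def text_digest(text: str) -> str:
    return hashlib.sha256(text.encode("ascii")).hexdigest()


def build_index(S: str) -> SuffixIndex:
    """Build the full suffix index of ``S`` (deterministic)."""
    if not S:
        raise ValueError("cannot index an empty reference")
    codes = encode_text(S)
    sa = suffix_array(codes)
    isa = np.empty_like(sa)
    isa[sa] = np.arange(len(sa), dtype=np.int64)
    lcp = lcp_array(codes, sa)
    return SuffixIndex(S, sa, isa, lcp)


def save_index(index: SuffixIndex, sink: str | Path | IO[bytes]) -> None:
    """Serialise header (magic, version, n, digest) + the three arrays."""
    handle, owned = (open(sink, "wb"), True) if isinstance(sink, (str, Path)) \
        else (sink, False)
    try:
        digest = bytes.fromhex(index.digest)
        handle.write(_MAGIC)
        handle.write(struct.pack("<IQ", index.version, index.n))
        handle.write(struct.pack("<I", len(digest)))
        handle.write(digest)
        for arr in (index.sa, index.isa, index.lcp):
            handle.write(np.ascontiguousarray(arr, dtype=np.int64).tobytes())
        handle.write(index.text.encode("ascii"))
    finally:
        if owned:
            handle.close()


def load_index(
    source: str | Path | IO[bytes],
    reference_text: str | None = None,
) -> SuffixIndex:
    """Load a saved index; verify the digest against ``reference_text`` if
    one is supplied (stale-index protection)."""
    handle, owned = (open(source, "rb"), True) if isinstance(source, (str, Path)) \
        else (source, False)
    try:
        magic = handle.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexFormatError("not a mumalign index file")
        header = handle.read(12)
        if len(header) < 12:
            raise IndexFormatError("truncated index header")
        version, n = struct.unpack("<IQ", header)
        if version != _VERSION:
            raise IndexFormatError(f"unsupported index version {version}")
        (dlen,) = struct.unpack("<I", handle.read(4))
        digest = handle.read(dlen).hex()
        arrays = []
        for name in ("sa", "isa", "lcp"):
            raw = handle.read(8 * n)
            if len(raw) < 8 * n:
                raise IndexFormatError(f"truncated {name} array")
            arrays.append(np.frombuffer(raw, dtype=np.int64).copy())
        text = handle.read(n).decode("ascii")
        if len(text) < n:
            raise IndexFormatError("truncated reference text")
    finally:
        if owned:
            handle.close()
    if reference_text is not None and text_digest(reference_text) != digest:
        raise StaleIndexError(
            "index was built for a different reference (digest mismatch)"
        )
    return SuffixIndex(text, *arrays, digest=digest, version=version)


@dataclass
class ReferenceBatch:
    """A contiguous slab of whole reference records."""

    records: list[SequenceRecord]
    batch_index: int
    concatenated: ConcatenatedReference = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.concatenated is None:
            self.concatenated = concat_reference(self.records)


def batch_reference(
    records: Sequence[SequenceRecord],
    X: int | None,
) -> list[ReferenceBatch]:
    """Greedy whole-record packing into slabs of at most ``X`` bases.

    Records are never split: a single record longer than ``X`` forms its own
    batch, so batched and unbatched runs see the same per-record text and
    produce the same alignments.  ``X=None`` means one batch.
    """
    if not records:
        raise ValueError("no reference records")
    if X is None:
        return [ReferenceBatch(list(records), 0)]
    if X < 1:
        raise ValueError("batch size must be >= 1")
    batches: list[ReferenceBatch] = []
    current: list[SequenceRecord] = []
    total = 0
    for rec in records:
        if current and total + len(rec) > X:
            batches.append(ReferenceBatch(current, len(batches)))
            current, total = [], 0
        current.append(rec)
        total += len(rec)
    batches.append(ReferenceBatch(current, len(batches)))
    return batches
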