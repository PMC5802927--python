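"""Maximal exact match (MEM/MUM) seeding against the indexed reference.

A seed is an exact match between the reference string ``S`` and the query
that cannot be extended by one base in either direction, of length at least
``min_len``.  Three uniqueness modes mirror the classic mummer options:

* ``unique_in_reference`` (default): the matched reference substring occurs
  exactly once in ``S`` (a MUM in the reference sense);
* ``unique_in_both``: additionally occurs exactly once in the query;
* ``all_mems``: every maximal exact match, regardless of multiplicity.

Enumeration builds a generalised suffix array over ``reference # query``
(prefix doubling) and walks runs of adjacent suffixes sharing at least
``min_len``: within such a run every reference/query pair shares a prefix
equal to the minimum LCP between their ranks, which is exactly the longest
common extension, so taking that full length gives right-maximality for
free; left-maximality is a single character comparison.  Non-ACGT
characters (N, IUPAC ambiguity codes, separators) are encoded as pairwise
distinct symbols, so no seed ever contains them or spans a record boundary.

Reference uniqueness is an O(1) test on the persisted reference index: a
substring repeats in ``S`` iff one of its lexicographic neighbours shares a
prefix at least as long.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

from .index import SuffixIndex, encode_seed_alphabet, lcp_array, suffix_array
from .seqio import SequenceRecord, reverse_complement

__all__ = ["Match", "MatchMode", "find_seeds", "find_all_matches"]

FORWARD = "+"
REVERSE = "-"


class MatchMode(Enum):
    """Seed uniqueness requirement."""

    UNIQUE_IN_REFERENCE = "unique_in_reference"
    UNIQUE_IN_BOTH = "unique_in_both"
    ALL_MEMS = "all_mems"


@dataclass(frozen=True, order=True)
class Match:
    """An exact seed.  ``ref_start`` is 1-based in ``S``; ``qry_start`` is
    1-based in the strand-adjusted query (the reverse complement for
    reverse-strand seeds)."""

    ref_start: int
    qry_start: int
    length: int
    strand: str = FORWARD

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length - 1

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.qry_start


class _QueryUniqueness:
    """Adjacent-LCP uniqueness test over one query string, built lazily."""

    def __init__(self, codes: np.ndarray):
        self.sa = suffix_array(codes)
        self.lcp = lcp_array(codes, self.sa)
        self.isa = np.empty_like(self.sa)
        self.isa[self.sa] = np.arange(len(self.sa))

    def unique(self, pos: int, length: int) -> bool:
        r = int(self.isa[pos])
        if r > 0 and self.lcp[r] >= length:
            return False
        if r + 1 < len(self.sa) and self.lcp[r + 1] >= length:
            return False
        return True


def _seed_codes(index: SuffixIndex) -> np.ndarray:
    # cached on the index: the ACGT/unique-special encoding of S
    cached = getattr(index, "_seed_codes", None)
    if cached is None:
        cached = encode_seed_alphabet(index.text)
        index._seed_codes = cached  # type: ignore[attr-defined]
    return cached


def find_seeds(
    index: SuffixIndex,
    query: str,
    min_len: int,
    mode: MatchMode = MatchMode.UNIQUE_IN_REFERENCE,
) -> list[Match]:
    """All forward-strand maximal exact matches of length >= ``min_len``
    between the indexed reference and ``query``, filtered by ``mode``."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not query:
        raise ValueError("empty query")
    query = query.upper()
    ref_codes = _seed_codes(index)
    n_ref = len(ref_codes)
    hi = int(ref_codes.max()) + 1 if n_ref else 5
    qry_codes = encode_seed_alphabet(query, special_base=hi + 1)
    combined = np.concatenate(
        (ref_codes, np.array([hi], dtype=np.int64), qry_codes)
    )
    sa = suffix_array(combined)
    lcp = lcp_array(combined, sa)

    qry_unique = None
    if mode is MatchMode.UNIQUE_IN_BOTH:
        qry_unique = _QueryUniqueness(qry_codes)

    q_off = n_ref + 1
    n = len(sa)
    matches: list[Match] = []
    sa_l = sa.tolist()
    lcp_l = lcp.tolist()
    comb_l = combined.tolist()
    # Runs of ranks with pairwise LCP >= min_len; enumerate cross pairs.
    start = 0
    while start < n:
        end = start
        while end + 1 < n and lcp_l[end + 1] >= min_len:
            end += 1
        if end > start:
            for i in range(start, end):
                lce = None
                for j in range(i + 1, end + 1):
                    lj = lcp_l[j]
                    lce = lj if lce is None else min(lce, lj)
                    if lce < min_len:
                        break
                    p, q = sa_l[i], sa_l[j]
                    if p > q:
                        p, q = q, p
                    if p >= n_ref or q < q_off:
                        continue  # both reference-side or both query-side
                    qpos = q - q_off
                    # left-maximality: preceding characters differ or edge
                    if p > 0 and qpos > 0 and comb_l[p - 1] == comb_l[q - 1]:
                        continue
                    if mode is not MatchMode.ALL_MEMS:
                        if not index.unique_span(p, lce):
                            continue
                        if qry_unique is not None and not qry_unique.unique(
                            qpos, lce
                        ):
                            continue
                    matches.append(Match(p + 1, qpos + 1, lce))
        start = end + 1
    matches.sort()
    return matches


def find_all_matches(
    index: SuffixIndex,
    query: SequenceRecord | str,
    min_len: int = 20,
    mode: MatchMode = MatchMode.UNIQUE_IN_REFERENCE,
) -> list[Match]:
    """Seeds on both strands.  Reverse-strand seeds carry coordinates on the
    reverse-complemented query; downstream output flips them to the
    start-greater-than-end convention on the forward query."""
    bases = query.bases if isinstance(query, SequenceRecord) else query
    out = find_seeds(index, bases, min_len, mode)
    rc = reverse_complement(bases)
    out += [
        Match(m.ref_start, m.qry_start, m.length, REVERSE)
        for m in find_seeds(index, rc, min_len, mode)
    ]
    return out
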