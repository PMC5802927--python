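"""Clustering of exact seeds into colinear chains (the mgaps stage).

Seeds are first partitioned by strand (and by owning reference record when
the coordinate map is supplied), overlapping same-diagonal seeds are merged,
and the remainder grouped into connected components under a proximity
relation: two seeds may be neighbours when both the reference gap and the
query gap between them are at most ``max_gap`` and their diagonals differ by
at most ``diag_frac`` times the larger gap.  Within each component a single
maximum-score strictly colinear chain is selected by weighted
longest-increasing-subsequence dynamic programming (weight = seed length),
and chains scoring below ``min_cluster`` matched bases are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .seeds import Match
from .seqio import ConcatenatedReference

__all__ = ["ClusterOptions", "Cluster", "cluster_matches", "diagonal"]


@dataclass(frozen=True)
class ClusterOptions:
    """mgaps parameters: defaults follow the classic nucmer settings
    (-g 90 -c 65 -d 0.12); the long-read preset lowers -c to 31."""

    max_gap: int = 90
    min_cluster: int = 65
    diag_frac: float = 0.12

    def __post_init__(self) -> None:
        if self.max_gap < 0 or self.min_cluster < 1:
            raise ValueError("invalid cluster options")
        if not 0 <= self.diag_frac <= 1:
            raise ValueError("diag_frac must lie in [0, 1]")


@dataclass
class Cluster:
    matches: list[Match]
    strand: str
    score: int
    ref_record: str | None = None

    @property
    def ref_start(self) -> int:
        return self.matches[0].ref_start

    @property
    def ref_end(self) -> int:
        return self.matches[-1].ref_end

    @property
    def qry_start(self) -> int:
        return self.matches[0].qry_start

    @property
    def qry_end(self) -> int:
        return self.matches[-1].qry_end


def diagonal(match: Match) -> int:
    """ref_start - qry_start in strand-adjusted coordinates."""
    return match.ref_start - match.qry_start


def _gaps(a: Match, b: Match) -> tuple[int, int]:
    return (b.ref_start - a.ref_end - 1, b.qry_start - a.qry_end - 1)


def _neighbours(a: Match, b: Match, opts: ClusterOptions) -> bool:
    """Proximity relation; ``a`` is the earlier seed by (ref, qry) order."""
    gr, gq = _gaps(a, b)
    if gr > opts.max_gap or gq > opts.max_gap:
        return False
    return abs(diagonal(b) - diagonal(a)) <= opts.diag_frac * max(gr, gq, 1)


def _merge_same_diagonal(matches: list[Match]) -> list[Match]:
    """Merge seeds that overlap or abut on a shared diagonal so each base
    contributes to the chain score exactly once."""
    matches = sorted(matches, key=lambda m: (diagonal(m), m.ref_start))
    out: list[Match] = []
    for m in matches:
        if (
            out
            and diagonal(out[-1]) == diagonal(m)
            and m.ref_start <= out[-1].ref_end + 1
        ):
            prev = out[-1]
            new_end = max(prev.ref_end, m.ref_end)
            out[-1] = replace(prev, length=new_end - prev.ref_start + 1)
        else:
            out.append(m)
    return out


def _components(matches: list[Match], opts: ClusterOptions) -> list[list[Match]]:
    ms = sorted(matches)
    n = len(ms)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    max_len = max((m.length for m in ms), default=0)
    window = opts.max_gap + max_len + 1
    for i in range(n):
        for j in range(i + 1, n):
            if ms[j].ref_start - ms[i].ref_start > window:
                break
            a, b = (ms[i], ms[j])
            if (b.ref_start, b.qry_start) < (a.ref_start, a.qry_start):
                a, b = b, a
            if _neighbours(a, b, opts):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[Match]] = {}
    for i, m in enumerate(ms):
        groups.setdefault(find(i), []).append(m)
    return [groups[k] for k in sorted(groups)]


def _best_chain(members: list[Match], opts: ClusterOptions) -> tuple[list[Match], int]:
    """Maximum-weight strictly colinear chain by LIS dynamic programming.
    Ties broken deterministically: higher score, then smaller total gap,
    then the earliest predecessor in (ref, qry) sort order."""
    ms = sorted(members, key=lambda m: (m.ref_start, m.qry_start, m.length))
    n = len(ms)
    score = [m.length for m in ms]
    gap_tot = [0] * n
    prev = [-1] * n
    max_len = max(m.length for m in ms)
    window = opts.max_gap + max_len + 1
    for i in range(n):
        mi = ms[i]
        # base case: chain of just mi; any extension has score > mi.length
        best_key = (mi.length, 0, 0)
        for j in range(i - 1, -1, -1):
            mj = ms[j]
            if mi.ref_start - mj.ref_start > window:
                break
            if mj.ref_start >= mi.ref_start or mj.qry_start >= mi.qry_start:
                continue
            if not _neighbours(mj, mi, opts):
                continue
            gr, gq = _gaps(mj, mi)
            key = (
                score[j] + mi.length,
                -(gap_tot[j] + max(gr, 0) + max(gq, 0)),
                -j,
            )
            if key > best_key:
                best_key = key
                score[i] = key[0]
                gap_tot[i] = -key[1]
                prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -gap_tot[i], -i))
    chain: list[Match] = []
    i = best
    while i != -1:
        chain.append(ms[i])
        i = prev[i]
    chain.reverse()
    return chain, score[best]


def cluster_matches(
    matches: Sequence[Match],
    opts: ClusterOptions = ClusterOptions(),
    ref: ConcatenatedReference | None = None,
) -> list[Cluster]:
    """Group seeds into clusters and keep each component's best chain.

    When ``ref`` is given, seeds are additionally partitioned by the
    reference record that owns them (seeds never span separators, so each
    seed has exactly one owner) and clusters carry the record id.
    """
    parts: dict[tuple[str, str | None], list[Match]] = {}
    for m in matches:
        rid = None
        if ref is not None:
            rid = ref.global_to_local(m.ref_start - 1)[0]
        parts.setdefault((m.strand, rid), []).append(m)

    clusters: list[Cluster] = []
    for (strand, rid), ms in sorted(
        parts.items(), key=lambda kv: (kv[0][1] or "", kv[0][0])
    ):
        merged = _merge_same_diagonal(ms)
        for comp in _components(merged, opts):
            chain, chain_score = _best_chain(comp, opts)
            if chain_score >= opts.min_cluster:
                clusters.append(Cluster(chain, strand, chain_score, rid))
    clusters.sort(key=lambda c: (c.ref_record or "", c.ref_start, c.qry_start))
    return clusters
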