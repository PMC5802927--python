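"""Pipeline orchestration: index -> seed -> cluster -> extend -> emit.

The unit of work is one query record against one reference batch; workers
process query records independently (no cross-query state), so the multiset
of emitted alignment records is invariant under worker count and — because
reference records are never split across batches — under batch size.
Output order is canonicalised on request (``sorted_output``).
"""

from __future__ import annotations

import multiprocessing as mp
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .align import Alignment, AlignmentOptions, align_clusters
from .cluster import ClusterOptions, cluster_matches
from .index import (
    SuffixIndex,
    ReferenceBatch,
    batch_reference,
    build_index,
    load_index,
    save_index,
)
from .seeds import MatchMode, find_all_matches
from .seqio import SequenceRecord, read_sequences

__all__ = ["RunOptions", "RunSummary", "run_pipeline", "align_records"]


@dataclass(frozen=True)
class RunOptions:
    """Everything the pipeline needs; defaults mirror classic nucmer
    behaviour (reference-unique 20-base seeds, -g 90 -c 65 -d 0.12 -b 200)."""

    mode: MatchMode = MatchMode.UNIQUE_IN_REFERENCE
    min_len: int = 20
    cluster: ClusterOptions = field(default_factory=ClusterOptions)
    align: AlignmentOptions = field(default_factory=AlignmentOptions)
    batch_size: int | None = None
    workers: int = 1
    sorted_output: bool = False

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.workers < 1:
            raise ValueError("min_len and workers must be >= 1")


@dataclass
class RunSummary:
    n_queries: int = 0
    n_aligned_queries: int = 0
    n_alignments: int = 0
    aligned_ref_bases: int = 0
    elapsed_s: float = 0.0

    def report(self) -> str:
        return (
            f"queries={self.n_queries} aligned_queries="
            f"{self.n_aligned_queries} alignments={self.n_alignments} "
            f"aligned_ref_bases={self.aligned_ref_bases} "
            f"elapsed={self.elapsed_s:.1f}s"
        )


def canonical_sort_key(aln: Alignment):
    return (
        aln.ref_id,
        aln.ref_start,
        aln.ref_end,
        aln.qry_id,
        min(aln.qry_start, aln.qry_end),
        max(aln.qry_start, aln.qry_end),
        aln.strand,
        aln.errors,
        tuple(aln.indels),
    )


# worker context, installed before forking so children inherit it
_CTX: dict = {}


def _align_one(args) -> list[Alignment]:
    batch, index, qrec, opts = args
    matches = find_all_matches(index, qrec, opts.min_len, opts.mode)
    clusters = cluster_matches(matches, opts.cluster, ref=batch.concatenated)
    return align_clusters(clusters, batch.concatenated, qrec, opts.align)


def _align_by_index(qi: int) -> list[Alignment]:
    batch, index, queries, opts = (
        _CTX["batch"], _CTX["index"], _CTX["queries"], _CTX["opts"]
    )
    return _align_one((batch, index, queries[qi], opts))


def align_records(
    ref_records: Sequence[SequenceRecord],
    qry_records: Sequence[SequenceRecord],
    opts: RunOptions = RunOptions(),
    prebuilt_index: SuffixIndex | None = None,
) -> list[Alignment]:
    """Align every query against every reference batch; returns all
    alignment records (canonically sorted when ``opts.sorted_output``)."""
    batches = batch_reference(ref_records, opts.batch_size)
    out: list[Alignment] = []
    for batch in batches:
        if prebuilt_index is not None and len(batches) == 1:
            index = prebuilt_index
        else:
            index = build_index(batch.concatenated.S)
        if opts.workers > 1 and len(qry_records) > 1:
            _CTX.update(
                batch=batch, index=index, queries=list(qry_records), opts=opts
            )
            try:
                ctx = mp.get_context("fork")
                with ctx.Pool(opts.workers) as pool:
                    for alns in pool.map(
                        _align_by_index, range(len(qry_records))
                    ):
                        out.extend(alns)
            finally:
                _CTX.clear()
        else:
            for qrec in qry_records:
                out.extend(_align_one((batch, index, qrec, opts)))
    if opts.sorted_output:
        out.sort(key=canonical_sort_key)
    return out


def run_pipeline(
    ref_source: str | Path,
    qry_source: str | Path,
    opts: RunOptions = RunOptions(),
    delta_path: str | Path | None = None,
    sam_short_path: str | Path | None = None,
    sam_long_path: str | Path | None = None,
    save_index_path: str | Path | None = None,
    load_index_path: str | Path | None = None,
    log=None,
) -> tuple[list[Alignment], RunSummary]:
    """File-level entry point: read inputs once, align, write outputs."""
    from .formats import write_delta, write_sam

    t0 = time.monotonic()
    ref_records = list(read_sequences(ref_source))
    qry_records = list(read_sequences(qry_source))
    prebuilt = None
    if load_index_path is not None:
        batches = batch_reference(ref_records, opts.batch_size)
        if len(batches) != 1:
            raise ValueError("a saved index cannot be combined with batching")
        prebuilt = load_index(load_index_path, batches[0].concatenated.S)
    alignments = align_records(ref_records, qry_records, opts, prebuilt)
    if save_index_path is not None:
        batches = batch_reference(ref_records, opts.batch_size)
        if len(batches) != 1:
            raise ValueError("cannot save a batched index")
        index = prebuilt or build_index(batches[0].concatenated.S)
        save_index(index, save_index_path)
    if delta_path is not None:
        write_delta(alignments, str(ref_source), str(qry_source), delta_path)
    if sam_short_path is not None:
        write_sam(alignments, ref_records, qry_records, "short", sam_short_path)
    if sam_long_path is not None:
        write_sam(alignments, ref_records, qry_records, "long", sam_long_path)
    summary = RunSummary(
        n_queries=len(qry_records),
        n_aligned_queries=len({a.qry_id for a in alignments}),
        n_alignments=len(alignments),
        aligned_ref_bases=sum(a.ref_span for a in alignments),
        elapsed_s=time.monotonic() - t0,
    )
    if log is not None:
        print(summary.report(), file=log)
    return alignments, summary
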