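# mumalign

Pairwise nucleotide genome alignment by the classic seed–cluster–extend
recipe: index a reference with a suffix array, seed alignments with maximal
exact matches, chain nearby seeds into colinear clusters, and fill and
extend the clusters with banded dynamic programming.  Output is the MUMmer
delta dialect or SAM.  It is aimed at the usual whole-genome comparison
tasks — assembly vs. assembly, draft vs. reference, reads vs. genome — at
a scale where a pure-Python implementation is comfortable, and at people
who want every stage of such a pipeline inspectable and testable.

## The method

The reference records are joined into a single string *S* with a separator
character (`x`) that cannot occur in the uppercased sequence alphabet, so
no exact match can span a record boundary.  Over *S* the package builds a
suffix array (prefix doubling), its inverse, and the LCP array; the triple
can be saved to disk and reloaded, guarded by a digest of *S*.

For each query, seeds are **maximal exact matches**: substrings shared by
reference and query that cannot be extended on either side, of length at
least *l* (default 20).  Three uniqueness modes mirror the mummer
tradition — matches whose reference substring is unique in *S* (default,
the MUM-style behaviour), matches unique in both sequences (`--mum`), and
all maximal exact matches regardless of multiplicity (`--maxmatch`).
Uniqueness is a constant-time test: a substring of length *k* repeats in
*S* iff a lexicographic neighbour of its suffix shares a prefix ≥ *k*.
Both strands are searched; reverse-strand seeds live in reverse-complement
query coordinates until output.

Seeds are clustered by proximity (reference gap and query gap ≤ `-g`,
diagonal drift ≤ `-d` × gap), and within each cluster a maximum-weight
strictly colinear chain is selected by weighted
longest-increasing-subsequence dynamic programming; chains under `-c`
matched bases are discarded.  Gaps between consecutive seeds are closed
with banded global alignment (match +3, mismatch −3, gap −4), adjacent
colinear chains separated by small gaps are joined, and the outer ends are
extended until the extension has gone `-b` bases past its best-scoring
point without improvement, then trimmed back to that point.  Each
alignment record carries its coordinates, an error count
(mismatches + indel bases), and the indel positions in the delta offset
encoding.

## Worked example

Generate a 50 kb synthetic pair (2% SNPs, 0.2% insertions and deletions,
one 3 kb inversion) and align it:

```python
from mumalign import generate_mutated_pair, write_fasta

refs, qrys, truth = generate_mutated_pair(
    seed=11, length=50_000, snp_rate=0.02, ins_rate=0.002,
    del_rate=0.002, inversion_count=1, inversion_length=3000)
write_fasta(refs, "ref.fa"); write_fasta(qrys, "qry.fa")
print("planted edits:", truth.edit_count, "inversion:", truth.inversions)
```

    planted edits: 1175 inversion: [('ref_1', 6257, 9256)]

```
$ mumalign align ref.fa qry.fa --delta out.delta --sam-long out.sam --sorted --verbose
queries=1 aligned_queries=1 alignments=3 aligned_ref_bases=50129 elapsed=0.8s
```

The run found three alignments: the two forward segments flanking the
inversion and the inverted segment itself on the reverse strand, together
covering the whole reference.  The delta file starts:

```
ref.fa qry.fa
NUCMER
>ref_1 qry_1 50000 50026
1 6285 1 6290 174 174 0
79
8
-2
...
```

Line 4 is the first alignment: reference 1–6285 against query 1–6290 with
174 errors; the signed integers that follow are indel positions (positive
= reference base over a query gap, negative = the reverse), terminated by
a `0` line.  A reverse-strand alignment is written with query start >
query end.  The same records in `out.sam` carry CIGAR, NM and MD tags;
the highest-scoring record per query is primary and the rest are flagged
secondary.

The same pipeline is available in the library as
`mumalign.align_records(ref_records, qry_records, RunOptions(...))`, and
the `mumalign index` / `mumalign match` subcommands expose the index and
seed stages separately.

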