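# Methods

This note records how mumalign's pipeline is defined, which knobs matter,
what the synthetic data emulates, and where the open design choices were
settled.

## Pipeline model

The aligner follows the four-stage seed-and-extend design used by the
nucmer family of whole-genome aligners:

1. **Concatenation.**  Reference records are uppercased and joined into
   one string *S* with a lowercase `x` between records.  Because the
   separator is outside the sequence alphabet, no exact match can cross a
   record boundary; all later stages work in *S*-global coordinates and
   translate back to 1-based record-local coordinates at output.  *S* is
   read and parsed exactly once per run.  Input length is validated
   against the 48-bit contract (2^47 − 1 characters).

2. **Seeding.**  A maximal exact match (MEM) is a shared substring
   extendable in neither direction.  Enumeration builds a generalised
   suffix array over `reference ⧺ sentinel ⧺ query` by prefix doubling
   and scans runs of lexicographically adjacent suffixes whose pairwise
   LCP is at least the minimum seed length: within a run, the longest
   common extension of a reference/query pair is the minimum LCP between
   their ranks, which makes every reported pair right-maximal by
   construction; left-maximality is one character comparison.  Non-ACGT
   characters (N, ambiguity codes, separators) are encoded as pairwise
   distinct symbols so they match nothing — seeds therefore never contain
   N, and N never equals N.  Uniqueness filtering uses the persisted
   reference index: a substring occurs more than once in *S* iff an
   adjacent suffix in the suffix array shares a prefix at least as long,
   an O(1) test via the LCP and inverse arrays.  Query-side uniqueness
   (strict MUM mode) applies the same test on a per-strand suffix array
   of the query.  Occurrences are counted on the text as written (forward
   strand only), and per reference batch when batching is active.

3. **Clustering.**  Seeds are partitioned by strand and owning reference
   record, merged when they overlap on a shared diagonal (so score counts
   each base once), and grouped into connected components under the
   proximity relation: reference gap ≤ `max_gap`, query gap ≤ `max_gap`,
   and diagonal difference ≤ `diag_frac` × max(gap, 1).  Within each
   component one maximum-weight strictly colinear chain is selected by
   weighted LIS dynamic programming (weight = seed length); ties prefer
   smaller total gap, then the earliest predecessor in (ref, qry) sort
   order, which makes the output independent of input order.  Chains
   scoring under `min_cluster` are dropped.

4. **Extension.**  Consecutive chains on one strand whose separating gaps
   are at most `join_limit` on both sides (overlaps allowed; they are
   trimmed) and whose diagonals agree within `break_len` are joined into
   one record.  Inter-seed gaps are filled by banded global alignment;
   should a gap alignment collapse below −`break_len`·|gap cost| the
   record is split there instead.  The two outer ends are extended with a
   banded DP whose band follows the best diagonal of the previous row;
   extension stops once it has advanced `break_len` reference bases past
   the best-scoring cell without improving on it and the transcript is
   trimmed back to that cell, so alignments end at their score maximum.
   Records contained in both coordinates within a better record of the
   same strand (shadows of parallel chains over one region) are removed.

## Parameters

| knob | default | meaning |
|---|---|---|
| `-l` min seed length | 20 bases | shorter seeds find more, slower and noisier; 15 with `-c 31` is the long-read preset |
| `-g` max gap | 90 bases | cluster proximity bound in both coordinates |
| `-c` min cluster | 65 matched bases | minimum chain weight emitted |
| `-d` diagonal fraction | 0.12 | allowed diagonal drift per unit gap |
| `-b` break length | 200 bases | distance an extension may trail its best point |
| match / mismatch / gap | +3 / −3 / −4 | linear scoring, no affine opening |
| join limit | 1000 bases (5·`-b`) | largest inter-chain gap closed by DP when joining |
| extension band half-width | 8 columns | wide enough for indel drift across an extension span, narrow enough not to chase chance matches in non-homologous sequence |
| band width (gap fill) | diagonal span + 5 + 10 | always connects the two anchoring seeds |

Scoring is deliberately linear: it keeps the banded aligner exactly
checkable against a plain unbanded dynamic program, which the test suite
exploits.  MAPQ in SAM output is a fixed 30 — the pipeline has no mapping
quality model and pretending otherwise would be misleading.

## Numerical and convention choices

* Suffix arrays are built by numpy prefix doubling (O(n log n) sorts); no
  sentinel is appended — a past-the-end rank of −1 makes a shorter suffix
  sort first, matching plain string comparison.  LCPs are computed by
  vectorised simultaneous extension of all adjacent pairs (work
  proportional to n plus the LCP sum).  Construction is deterministic, so
  two saves of the same text are byte-identical.
* Coordinates are 1-based inclusive everywhere in output; a
  reverse-strand alignment reports query start > query end on the forward
  strand.  Internally reverse-strand work uses reverse-complement query
  coordinates throughout and flips once at record construction.
* Delta offsets follow the MUMmer convention: magnitude = columns since
  the previous indel (counted on the side that has the base), sign
  positive when the reference base sits over a query gap.  The invariant
  enforced end-to-end is ref_span + #negative = qry_span + #positive =
  aligned columns, and replaying (coordinates, offsets) against the
  sequences must reproduce the stored error count exactly.
* DP move preference is diagonal > up (reference-consuming) > left, fixed
  for determinism.  The banded global aligner auto-widens its band to at
  least the length difference plus one so the corners always connect, and
  equals unbanded alignment whenever the band covers both strings.
* Empty query extension, pure-gap gap fills (one side empty) and
  single-record references (no separator) are all exercised explicitly in
  the tests.

## Worker and batch contracts

Work is distributed per query record; no state is shared across queries,
so the multiset of emitted records is identical for any worker count
(processes are forked with the index already built).  The reference is
batched by greedy whole-record packing — a record is never split, so a
record longer than the slab forms its own batch — which makes batched and
unbatched runs see identical per-record text.  One caveat is semantic:
seed uniqueness is evaluated against the current batch's text, so a
substring duplicated *across* batches is unique within each; on random
sequence at the tested scales this is vanishingly rare, but on highly
repetitive references `--batch` can admit seeds a whole-reference run
would reject.  A `--sorted` flag canonically orders output for diffing.

## What the synthetic data does and does not emulate

`generate_mutated_pair` draws a uniform ACGT reference and mutates it with
independent per-base substitutions (never silent), single-base insertions
and deletions, plus disjoint segmental inversions placed away from record
edges, recording every event with reference coordinates.  The defaults of
the end-to-end tests — 200 kb, 2% SNPs, 0.2% insertions and deletions,
one 5 kb inversion — represent a diverged-genome comparison at roughly
the divergence where the default seed length still anchors densely.  The
200 kb problem size (and 4 × 50 kb for the batching variant) was chosen so
the full property suite runs in minutes on one CPU.

Real genomes differ in ways this generator does not model: repeat
families and segmental duplications (which stress the uniqueness modes
and would make `--maxmatch` output explode), multi-base indels and
structural events other than inversion, composition bias, and N runs from
assembly gaps.  Passing the end-to-end tests therefore demonstrates that
the machinery recovers planted variation faithfully on repeat-poor
sequence; it does not certify sensitivity or precision on repetitive real
genomes.  The oracle-equivalence tests (seed sets, suffix arrays, DP
scores, chain weights) are exact and scale-free statements about
correctness of each stage in isolation.

## Known limitations

* Nucleotide mode only; the delta fields `sim_errors` and `stop_codons`
  are kept for dialect compatibility (equal to `errors` and 0).
* Linear gap costs; no affine opening penalty, no X-drop beyond the
  break-length rule.
* Alignment error totals slightly overshoot planted edit counts (a few
  percent) because extensions trimmed at their score maximum can retain a
  short chance-match excursion into non-homologous sequence at breakpoint
  ends; the effect is bounded by the break length.
* The full suffix array is kept in memory (no sparse sampling or
  compressed index), and uniqueness under batching is per-batch as noted
  above.
* MAPQ is uninformative by design; downstream filtering should use NM,
  alignment length or the delta error counts.
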