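# Methods

## Model and data structures

The mapper treats the reference as one concatenated string over Σ = {A,C,G,T}
with per-record boundary metadata. Three structures form the hybrid index:

* **Packed sequence** — two bits per base, first base of each byte in the most
  significant bit pair. The working in-memory form is one code byte per base
  so that Python `bytes` comparison (lexicographic, C speed) doubles as suffix
  comparison; the 4-bases-per-byte packing is used on disk. Non-ACGT symbols
  (N, IUPAC codes) are replaced by uniformly random bases from a generator
  whose seed is stored in the `.seqInfo` file, so a rebuild is bit-identical.
* **Suffix array** — starting positions of the N − q + 1 suffixes that carry a
  full q-gram, in lexicographic order. Suffixes shorter than q are not
  indexed, which avoids sentinel symbols; a suffix that ends inside a
  comparison sorts as smaller (ordinary prefix convention).
* **Hash table** — 4^q + 1 offsets; the SA range of q-gram x is
  [HT[x], HT[x+1] − 1], empty when HT[x] = HT[x+1].

Construction counts q-grams (exclusive prefix sums give the offsets), drops
positions into their ranges in position order, and sorts each range by keying
on length-w blocks of trailing bases, recursing on ties. The contract is only
that the result equals a full comparison sort, which the tests check against a
naive all-suffix sort; buckets are independent, so the serial loop could be
parallelized without changing the output.

Integer width on disk is 4 bytes while all values fit below 2^31 and 8 bytes
otherwise, recorded in each binary header together with magic bytes, a format
version and an endianness marker. `save_index` exposes the threshold as a
private parameter so the wide path is testable without a 2-Gb genome.

## Seeding

For read length m and error rate ε (default 0.02, a typical Illumina
substitution rate), λ = εm and k = ⌈1.5λ⌉. A read within k differences of the
reference must share a substring of length ≥ m/(k+1) (pigeonhole), so the seed
length is ⌊m/(k+1)⌋ clamped to [q_ht, m]; with ε = 0 the whole read is one
exact seed. The ceiling is computed as ⌈1.5λ − 10⁻⁹⌉ because products like
0.02·100 land just above the exact value in binary floating point and would
otherwise flip the result. `poisson_cdf` is an incremental term accumulation
(term_{i+1} = term_i · λ/(i+1)), accurate to ~10⁻¹⁵ for λ ≤ 20; for λ ≥ 6 the
mass within k = ⌈1.5λ⌉ errors stays above 0.9, which is the coverage argument
behind the 1.5 factor.

Hits are collected at every read offset (stride 1 by default, matching the
worked example that samples all q-grams); a q-gram whose SA range exceeds
`freq_cap` (default 500) contributes nothing — the frequency-weighting idea is
realized as a hard cap, the simplest faithful reading, and is configurable.
Hits whose span would cross a record boundary are dropped.

Matching regions are maximal runs of hits with one diagonal and consecutive
offsets; a run of c hits has length (c−1)·stride + q_seed. Chaining scans
regions in reference order and appends a region to the open chain when it
advances the read, its diagonal differs from the chain tail's by at most
`adjacency_limit` (default 10 — the permitted net indel size) and the
reference gap is at most `merge_window` (default 2× the limit). The matched
count subtracts, per consecutive pair, max(read overlap, reference overlap),
which reproduces the worked example's value of 5 for the chain GC + CATG (2 +
4 with one reference base covered twice). Ranking is by matched bases
descending with ties broken by leftmost reference position, then input order;
determinism is the governing contract because the source material's own
ranking printout is internally inconsistent. Up to `max_cars` (default 30)
candidates go on to alignment.

## Alignment

Only unmatched regions are aligned. Between two chained regions, with read gap
g_r and reference gap g_s (negatives are overlaps), the split cause is:
(1,1) → Mismatch; (g_r>0, 0) → Insertion 1; (g_r≥0, g_s<0) → Insertion 2;
(both<0, g_r>g_s) → Insertion 3; (0, g_s>0) → Deletion 1; (g_r<0, g_s≥0) →
Deletion 2; (both<0, g_s>g_r) → Deletion 3; anything else Mixed. For every
non-Mixed cause the edit length equals |g_s − g_r| = |Δdv|. Assembly
normalizes overlaps first (read overlap trims the next region; reference
overlap converts leading region bases into insertions — exactly what Insertion
2/3 prescribe), then emits the implied operations; Needleman–Wunsch runs only
on Mixed gaps, which after normalization always have both gaps positive.

Flanks (left of the first region, right of the last) are compared against a
reference window extended by the adjacency limit, clipped at record
boundaries. Candidate pure causes — a contiguous mismatch block adjacent to
the region, n inserted flank bases, or n deleted reference bases — are scored
by their loss under the default scheme (4n, 5n, 3n respectively) and the
cheapest wins, so the fast path never chooses an explanation dynamic
programming would beat; anything else is Mixed and gets semi-global DP (free
outer window end, anchored at the region). A flank is soft-clipped only when
no reference window remains at all; a flank that still faces reference bases
is aligned even if it overhangs the record end, which is what reproduces the
textbook 4M1I1M for the read's final base in the worked example (the stricter
always-soft-clip rule would produce 5M1S instead).

Scoring is match +2, mismatch −2, gap −3, linear. These values are this
package's choice — the method itself prescribes only the algorithm — and
linear gaps keep the Mixed-region DP simple; the co-optimal pair
4M1I1M / 5M1I in the worked example is resolved by the deterministic traceback
preference diagonal > deletion > insertion. Score, edit distance (NM) and
matched-base count are recomputed by walking the final CIGAR against the
reference, so they are consistent by construction.

## Mapping, pairing, fallback

`map_read` seeds and aligns the read and its reverse complement (strand search
is this package's addition: the evaluation contract requires strand
correctness, so both orientations must be tried; a `strands="forward"` knob
exists for pipeline introspection) and keeps placements whose matched bases
reach 40% of the read length (configurable acceptance floor). If nothing
passes, one extended pass runs with seed length halved (never below the
hash-table q), frequency cap ×10 and CAR budget ×4 — the qualitative recipe
"shorter seeds, frequent q-grams admitted, more candidates" made concrete.
The best placement is reported; mapping quality is 60 when no second distinct
placement exists, else max(0, min(60, 2·(best − second score))), so ties get 0.

Pairing maps each mate independently (top 10 candidates each) and flags as
properly paired the forward–reverse combination on one record whose insert
lies in [insert_min, insert_max] (defaults 100/1000) with maximal summed
score; TLEN is signed from the leftmost mate. Batch mapping is serial and
emits records in input order; a `threads` option is accepted for interface
compatibility and does not affect the output.

## Simulator and what passing tests mean

`simulate_reads` draws positions uniformly (records weighted by length),
strands fairly, and walks the reference emitting substitutions at `error_rate`
per base and single-base insertions/deletions at `indel_rate` (half each);
paired mode draws a fragment length from a normal distribution (default mean
375, sd 25, the classic short-insert library shape) and emits
forward–reverse mates. Default study conditions used by the recovery tests:
a 100-kb uniform-random genome, 1000 reads of 100 bp, ε = 0 and ε = 0.02 with
indel rate 0.002 — scaled-down but structurally faithful stand-ins for
genome-scale benchmarks. Everything is driven by one integer seed; identical
seeds give byte-identical FASTQ.

The simulator does *not* model base-quality-dependent error profiles,
position-dependent error ramps, repeats/duplications, GC bias or adapter
artifacts. A uniform-random genome has almost no repeat structure, so
uniqueness results here say nothing about mappability in repetitive genomes;
what the tests do establish is correctness of the index, the seeding
combinatorics, the split-cause algebra and the coordinate bookkeeping.

## Numerical and degenerate-input choices

* Binary search decodes the packed sequence lazily; no suffix is materialized.
* Queries overhanging the concatenated sequence end simply fail (no wrap).
* Empty SA ranges are encoded lo > hi; `locate` returns sorted positions.
* Reads shorter than the hash-table q raise an error (reported per read, not
  fatal, in batch mode).
* An alignment candidate that fails internal consistency (a matching region
  whose claimed bases do not match the reference) raises a corrupt-CAR error.
* `evaluate_accuracy` percentages are over all primary records; "unique" is
  MAPQ ≥ 1, "Q10" is MAPQ ≥ 10, and correctness requires same record, same
  strand and leftmost position within 50 bp (the standard tolerance).

## Known limitations

* Bucket sorting is O(bucket² · w) in the worst case (e.g. a single-letter
  genome); adequate for the intended scales, no divsufsort-class performance.
* One best placement per read; no secondary/supplementary records, no mate
  rescue, no affine gaps, no base-quality-aware scoring.
* The extended pass runs at most once; reads whose every seed-length window
  contains an error stay unmapped rather than triggering progressively
  shorter seeds.
* MAPQ is a score-gap heuristic, not a calibrated error probability.
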