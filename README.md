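# hybridmap

A short/long-read genome mapper built on a **hybrid index**: a q-gram hash
table laid over a suffix array. It is written for people who want a compact,
fully inspectable seed-and-extend mapper — every intermediate (suffix-array
ranges, diagonal hits, matching regions, candidate regions, split causes) is a
plain Python object that can be examined and unit-tested.

## The method

**Index.** The reference (multi-record FASTA, concatenated) is packed two bits
per base (A=0, C=1, G=2, T=3; non-ACGT symbols are replaced by seeded-random
bases). A suffix array SA holds the starting positions of all suffixes that
carry a full q-gram, in lexicographic order, so |SA| = N − q + 1. A hash table
HT with 4^q + 1 entries maps each q-gram value x to its contiguous SA range

    R(x) = [HT[x], HT[x+1] − 1],

which is empty iff the q-gram is absent. Construction counts q-grams, places
positions into their ranges, and sorts each range by comparing length-w blocks
of the following bases, refining ties. Looking up a query Q is two steps: one
hash jump for its length-q prefix, then binary search over the (small) range
for Q[q:], comparing the packed sequence on the fly.

**Seeding.** For a read of length m and expected error rate ε, let λ = εm and
k = ⌈1.5λ⌉; by the pigeonhole argument a read with at most k differences
shares a substring of length at least m/(k+1) with the reference, so the seed
q-gram length is ⌊m/(k+1)⌋ (clamped to [q, m]); the Poisson CDF
P(X ≤ k) = Σ_{i≤k} e^{−λ} λ^i / i! quantifies how many reads that covers.
Every occurrence of a read q-gram at read offset `ro` and reference position
`sp` is a hit on diagonal `dv = sp − ro`. Same-diagonal runs of consecutive
offsets collapse into **matching regions** ⟨dv, ro, L⟩ (maximal exact
matches); regions close on the reference whose diagonals differ by at most the
adjacency limit chain into **candidate alignment regions** (CARs), ranked by
matched bases. Overly frequent q-grams (SA range above a cap) are skipped.

**Alignment.** Within a CAR only the unmatched regions are aligned. Each gap
between regions is classified from its read-gap/reference-gap pair into
Mismatch, Insertion (3 subtypes), Deletion (3 subtypes) — which translate
directly into CIGAR operations — or Mixed, the only case where
Needleman–Wunsch (match 2, mismatch −2, gap −3, deterministic traceback) runs.
Flanks left/right of the outermost regions are classified the same way, with
semi-global DP for Mixed flanks. Both strands are searched; reads that fail an
acceptance floor are retried once with shorter seeds, a relaxed frequency cap
and more CARs ("extended" pass). Mapping quality is 60 for a unique placement,
otherwise scaled by the best-vs-second score gap.

## Worked example

```python
import hybridmap as hm

index = hm.build_hybrid_index([("seq", "TATAGGCATGAGCCAC")],
                              hm.IndexBuildConfig(q=1, w=4))
read = "GCCATG"
hits = hm.collect_hits(index, read, q_seed=2, freq_cap=500)
mrs  = hm.group_hits_to_mrs(hits)
cars = hm.rank_cars(hm.merge_mrs_to_cars(mrs, adjacency_limit=10), 30)
res  = hm.align_car(read, cars[0], index)
print([(m.gram, m.dv, m.ro, m.L) for m in mrs])
print(cars[0].matched, cars[0].adjacency_list, res.ref_pos, res.cigar)
```

prints

```
[('AT', -2, 3, 2), ('CATG', 4, 2, 4), ('GC', 5, 0, 2), ('GCCA', 11, 0, 4)]
5 [1] 5 [(2, 'M'), (1, 'I'), (3, 'M')]
```

i.e. four maximal exact matches; the best candidate chains GC (diagonal 5)
with CATG (diagonal 4) for 5 matched bases and adjacency 1 (one net inserted
base), and the final alignment places the read at reference position 5
(0-based) with CIGAR `2M1I3M` — read = GC, inserted C, ATG. The scripts in
`examples/` walk through indexing/lookup, seeding/alignment, and a full
simulate→map→evaluate loop.

## Command line

```bash
hybridmap index    --ref ref.fa --out idx --q 14 --w 8 --seed 1
hybridmap map      --index idx --fq1 r1.fq [--fq2 r2.fq] --out out.sam
hybridmap locate   --index idx --query ACGTACGT
hybridmap simulate --ref ref.fa --n 1000 --len 100 --error 0.02 --out reads
hybridmap evaluate --sam out.sam --truth reads.truth.tsv --tolerance 50
```

`index` writes four files (`.seq` packed sequence, `.idx` hash table, `.sa`
suffix array, `.seqInfo` record table); `map` writes SAM plus a text/JSON
summary; `evaluate` scores placements against simulator truth (same strand,
leftmost position within the tolerance).

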