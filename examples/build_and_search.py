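"""Build a hybrid index of a tiny reference and look substrings up.

The index couples a hash table (one slot per possible q-gram, pointing into
the suffix array) with the suffix array itself, so a lookup is one hash jump
for the length-q prefix plus a binary search for the remainder.
"""

import hybridmap as hm

index = hm.build_hybrid_index(
    [("seq", "TATAGGCATGAGCCAC")], hm.IndexBuildConfig(q=1, w=4, rng_seed=1)
)

print("reference           :", index.sequence.decode())
print("hash-table offsets  :", index.ht.offsets.tolist())
print("suffix array        :", index.sa.positions.tolist())
# offsets [0, 5, 9, 13, 16] say: suffixes starting with A occupy SA slots 0-4,
# C slots 5-8, G slots 9-12, T slots 13-15.

for query in ["GC", "CAT", "GT"]:
    rng = hm.sa_find(index, query)
    where = hm.locate(index, query)
    print(f"query {query!r:6}: SA range [{rng.lo}, {rng.hi}] -> positions {where}")
# GC occupies SA slots 10-11 and occurs at reference positions 5 and 11;
# GT does not occur, so its range is empty and no position is returned.
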