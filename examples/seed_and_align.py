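"""Seed a short read against a tiny reference and align the best candidate.

Every q-gram shared by read and reference is a hit on diagonal dv = sp - ro;
same-diagonal runs collapse into matching regions (exact common substrings),
nearby regions chain into candidate alignment regions (CARs), and only the
unmatched gaps of the best CAR are aligned — dynamic programming runs solely
on gaps whose split cause is "Mixed".
"""

import hybridmap as hm

index = hm.build_hybrid_index(
    [("seq", "TATAGGCATGAGCCAC")], hm.IndexBuildConfig(q=1, w=4, rng_seed=1)
)
read = "GCCATG"

hits = hm.collect_hits(index, read, q_seed=2, freq_cap=500)
print("hits (gram, dv, ro):", [(h.gram, h.dv, h.ro) for h in hits])

mrs = hm.group_hits_to_mrs(hits)
print("matching regions   :", [(m.gram, m.dv, m.ro, m.L) for m in mrs])

cars = hm.rank_cars(hm.merge_mrs_to_cars(mrs, adjacency_limit=10), max_cars=30)
for i, car in enumerate(cars):
    print(f"CAR {i}: regions={[m.gram for m in car.mrs]} matched={car.matched} "
          f"adjacency={car.adjacency_list}")
# The top CAR chains GC (diagonal 5) and CATG (diagonal 4): 5 matched bases
# with adjacency 1, i.e. one net inserted base between the two regions.

result = hm.align_car(read, cars[0], index)
cigar = "".join(f"{n}{op}" for n, op in result.cigar)
print(f"alignment: position {result.ref_pos} (0-based), CIGAR {cigar}, "
      f"score {result.score}, edit distance {result.nm}")
# Expected: position 5, CIGAR 2M1I3M — the read is GC + inserted C + ATG.
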