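"""Seed discovery: q-gram hits, matching regions (MRs), candidate regions (CARs).

A read of length m is scanned for q-grams; every reference occurrence of a
q-gram at read offset ``ro`` and reference position ``sp`` defines a hit on
diagonal ``dv = sp - ro``. Runs of hits on one diagonal with consecutive
offsets collapse into a matching region (an exact common substring), and
nearby matching regions chain into candidate alignment regions, ranked by
their matched-base count.

Three heuristics keep the search small:

1. The seed length is chosen from the read length and error rate: with
   lambda = eps*m expected errors and k = ceil(1.5*lambda), a read with at
   most k differences from the reference is guaranteed a common substring of
   length at least m/(k+1), and the Poisson CDF puts the mass of reads within
   k errors near or above 0.9.
2. q-grams occurring in more than ``freq_cap`` reference positions are
   uninformative (inverse-document-frequency idea) and contribute no hits.
3. Only the ``max_cars`` candidate regions with the most matched bases are
   passed on to alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .index_core import HybridIndex, PackedSequence, _CODE_OF
from .search import sa_find


def poisson_cdf(k: int, lam: float) -> float:
    """P(X <= k) for X ~ Poisson(lam), by incremental term accumulation."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    term = math.exp(-lam)
    total = term
    for i in range(1, k + 1):
        term *= lam / i
        total += term
    return min(total, 1.0)


def choose_seed_length(m: int, error_rate: float, q_ht: int) -> int:
    """Seed length floor(m / (k+1)) with k = ceil(1.5 * eps * m), clamped to [q_ht, m].

    The small epsilon guards against binary round-up (e.g. 0.02*100 evaluating
    just above 2.0), which would otherwise shorten the seed by a full step.
    """
    lam = error_rate * m
    k = math.ceil(1.5 * lam - 1e-9) if lam > 0 else 0
    return max(q_ht, min(m, m // (k + 1)))


@dataclass(frozen=True)
class QGramHit:
    """One q-gram occurrence: read offset ro, reference start sp, diagonal dv = sp - ro."""

    gram: str
    dv: int
    ro: int
    sp: int


@dataclass
class MatchingRegion:
    """Maximal same-diagonal run of q-gram hits: an exact common substring."""

    dv: int
    ro: int
    L: int
    gram: str | None = None

    @property
    def sp(self) -> int:
        return self.dv + self.ro

    @property
    def ro_end(self) -> int:
        return self.ro + self.L

    @property
    def sp_end(self) -> int:
        return self.sp + self.L


@dataclass
class CandidateAlignmentRegion:
    """Chain of nearby matching regions, ordered by read offset."""

    mrs: list[MatchingRegion]
    matched: int
    adjacency_list: list[int] = field(default_factory=list)

    @property
    def first_sp(self) -> int:
        return self.mrs[0].sp


@dataclass
class SeedingConfig:
    """Knobs for seed discovery.

    ``error_rate`` feeds the seed-length heuristic; ``q_seed`` overrides it
    when set. ``freq_cap`` is the largest SA-range size a q-gram may have and
    still produce hits. ``adjacency_limit`` bounds |delta dv| between chained
    matching regions (the permitted net indel size), and ``merge_window``
    (default 2x adjacency_limit) bounds the reference gap between them.
    ``stride`` samples every stride-th read offset.
    """

    error_rate: float = 0.02
    q_seed: int | None = None
    freq_cap: int = 500
    adjacency_limit: int = 10
    max_cars: int = 30
    stride: int = 1
    merge_window: int | None = None

    def __post_init__(self) -> None:
        if self.freq_cap < 1 or self.adjacency_limit < 0 or self.max_cars < 1:
            raise ValueError("seeding parameters must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def window(self) -> int:
        return self.merge_window if self.merge_window is not None else 2 * self.adjacency_limit


def collect_hits(
    index: HybridIndex,
    read: str,
    q_seed: int,
    freq_cap: int = 500,
    stride: int = 1,
) -> list[QGramHit]:
    """All (gram, dv, ro, sp) hits of the read's sampled q-grams.

    q-grams with SA ranges larger than ``freq_cap`` are skipped, as are hits
    whose implied span would cross a record boundary of the concatenated
    reference. q-grams containing non-ACGT symbols yield no hits.
    """
    read = read.upper()
    m = len(read)
    seq = index.sequence
    hits: list[QGramHit] = []
    for ro in range(0, m - q_seed + 1, stride):
        gram = read[ro : ro + q_seed]
        if any(_CODE_OF[ord(c)] == 255 for c in gram):
            continue
        rng = sa_find(index, gram)
        if rng.is_empty or len(rng) > freq_cap:
            continue
        for sp in sorted(int(p) for p in index.sa.positions[rng.lo : rng.hi + 1]):
            span = seq.record_of(sp)
            if sp + q_seed > span.end:
                continue
            hits.append(QGramHit(gram=gram, dv=sp - ro, ro=ro, sp=sp))
    return hits


def group_hits_to_mrs(hits: list[QGramHit], stride: int = 1) -> list[MatchingRegion]:
    """Sort hits by (dv, ro) and collapse same-diagonal consecutive-offset runs.

    A run of c hits with seed length q becomes one matching region of length
    (c-1)*stride + q, so an exact match of length L absorbs L-q+1 hits when
    stride is 1.
    """
    if not hits:
        return []
    q = len(hits[0].gram)
    ordered = sorted(hits, key=lambda h: (h.dv, h.ro))
    mrs: list[MatchingRegion] = []
    run_start = 0
    for i in range(1, len(ordered) + 1):
        if (
            i < len(ordered)
            and ordered[i].dv == ordered[i - 1].dv
            and ordered[i].ro == ordered[i - 1].ro + stride
        ):
            continue
        run = ordered[run_start:i]
        length = (len(run) - 1) * stride + q
        gram = None
        if stride == 1:
            gram = run[0].gram + "".join(h.gram[-1] for h in run[1:])
        mrs.append(MatchingRegion(dv=run[0].dv, ro=run[0].ro, L=length, gram=gram))
        run_start = i
    return mrs


def _pair_overlap_correction(prev: MatchingRegion, nxt: MatchingRegion) -> int:
    read_ov = max(0, prev.ro_end - nxt.ro)
    ref_ov = max(0, prev.sp_end - nxt.sp)
    return max(read_ov, ref_ov)


def merge_mrs_to_cars(
    mrs: list[MatchingRegion],
    adjacency_limit: int = 10,
    merge_window: int | None = None,
    sequence: PackedSequence | None = None,
) -> list[CandidateAlignmentRegion]:
    """Chain matching regions that are close on the reference into CARs.

    Regions are scanned in reference order; a region joins the open chain when
    it advances the read (ro and ro_end both beyond the chain tail), its
    diagonal differs from the tail's by at most ``adjacency_limit`` and the
    reference gap is at most ``merge_window`` (default 2x the limit). When a
    ``sequence`` is given, chains never span two reference records. The
    matched count is the sum of region lengths minus, for each consecutive
    pair, the larger of the read and reference overlaps.
    """
    if not mrs:
        return []
    window = merge_window if merge_window is not None else 2 * adjacency_limit
    ordered = sorted(mrs, key=lambda r: (r.sp, r.ro))
    cars: list[CandidateAlignmentRegion] = []
    chain: list[MatchingRegion] = [ordered[0]]

    def record_id(mr: MatchingRegion) -> int:
        return sequence.record_of(mr.sp).start if sequence is not None else 0

    def close() -> None:
        matched = sum(r.L for r in chain) - sum(
            _pair_overlap_correction(a, b) for a, b in zip(chain, chain[1:])
        )
        adjacency = [abs(b.dv - a.dv) for a, b in zip(chain, chain[1:])]
        cars.append(
            CandidateAlignmentRegion(mrs=list(chain), matched=matched, adjacency_list=adjacency)
        )

    for nxt in ordered[1:]:
        last = chain[-1]
        chainable = (
            nxt.ro >= last.ro
            and nxt.ro_end > last.ro_end
            and abs(nxt.dv - last.dv) <= adjacency_limit
            and nxt.sp - last.sp_end <= window
            and record_id(nxt) == record_id(last)
        )
        if chainable:
            chain.append(nxt)
        else:
            close()
            chain = [nxt]
    close()
    return cars


def rank_cars(
    cars: list[CandidateAlignmentRegion], max_cars: int = 30
) -> list[CandidateAlignmentRegion]:
    """Order by matched bases descending, break ties by leftmost reference
    position then input order (stable), and keep the top ``max_cars``."""
    indexed = sorted(
        enumerate(cars), key=lambda t: (-t[1].matched, t[1].first_sp, t[0])
    )
    return [car for _, car in indexed[:max_cars]]


def find_cars(
    index: HybridIndex, read: str, config: SeedingConfig | None = None
) -> list[CandidateAlignmentRegion]:
    """Full seeding pipeline: hits -> matching regions -> ranked CARs."""
    config = config or SeedingConfig()
    m = len(read)
    q_seed = config.q_seed or choose_seed_length(m, config.error_rate, index.q)
    q_seed = max(q_seed, index.q)
    if q_seed > m:
        return []
    hits = collect_hits(index, read, q_seed, config.freq_cap, config.stride)
    mrs = group_hits_to_mrs(hits, stride=config.stride)
    cars = merge_mrs_to_cars(
        mrs, config.adjacency_limit, config.merge_window, sequence=index.sequence
    )
    return rank_cars(cars, config.max_cars)
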