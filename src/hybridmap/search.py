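"""Two-step substring lookup: hash-table range jump plus suffix-array binary search.

The hash table resolves the length-q prefix of a query to a contiguous
suffix-array range in O(1); two binary searches over that range then narrow it
to the suffixes that start with the whole query, comparing only from offset q
onward and decoding the packed sequence on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidAlphabetError, InvalidQGramError, QueryTooShortError
from .index_core import HashTable, HybridIndex, _CODE_OF, encode_qgram


@dataclass(frozen=True)
class SARange:
    """Inclusive suffix-array index range; empty when lo > hi."""

    lo: int
    hi: int

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    def __len__(self) -> int:
        return 0 if self.is_empty else self.hi - self.lo + 1


def qgram_range(ht: HashTable, x: int) -> SARange:
    """SA range of the q-gram with encoded value ``x``: [HT[x], HT[x+1]-1]."""
    if not (0 <= x < 4**ht.q):
        raise InvalidQGramError(f"q-gram value {x} outside [0, 4^{ht.q})")
    return SARange(int(ht.offsets[x]), int(ht.offsets[x + 1]) - 1)


def _query_codes(query: str) -> bytes:
    out = bytearray()
    for ch in query.upper():
        code = _CODE_OF[ord(ch)] if ord(ch) < 256 else 255
        if code == 255:
            raise InvalidAlphabetError(f"non-ACGT symbol {ch!r} in query")
        out.append(code)
    return bytes(out)


def sa_find(index: HybridIndex, query: str) -> SARange:
    """Maximal SA range whose suffixes start with ``query``.

    The length-q prefix is resolved through the hash table; lower and upper
    bounds for the remainder are found by binary search comparing suffix bases
    from offset q onward. A suffix that ends inside the query (reference
    overhang) compares as smaller, so it falls below the returned range.
    """
    q = index.q
    if len(query) < q:
        raise QueryTooShortError(
            f"query length {len(query)} < hash-table q-gram length {q}"
        )
    qc = _query_codes(query)
    rng = qgram_range(index.ht, encode_qgram(query[:q]))
    if rng.is_empty or len(query) == q:
        return rng

    rem = qc[q:]
    codes = index.sequence.codes
    sa = index.sa.positions

    def cmp(sa_i: int) -> int:
        """-1/0/+1 of suffix[sa[i]+q:] vs rem, where 0 means starts-with."""
        p = int(sa[sa_i]) + q
        s = codes[p : p + len(rem)]
        if s == rem:
            return 0
        return -1 if s < rem else 1

    # lower bound: first i with cmp(i) >= 0
    lo, hi = rng.lo, rng.hi + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cmp(mid) < 0:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    # upper bound: first i with cmp(i) > 0
    lo, hi = first, rng.hi + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cmp(mid) <= 0:
            lo = mid + 1
        else:
            hi = mid
    return SARange(first, lo - 1)


def locate(index: HybridIndex, query: str) -> list[int]:
    """Sorted reference positions where ``query`` occurs."""
    rng = sa_find(index, query)
    if rng.is_empty:
        return []
    return sorted(int(p) for p in index.sa.positions[rng.lo : rng.hi + 1])
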