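"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import hybridmap as hm

EXAMPLE_SEQ = "TATAGGCATGAGCCAC"
EXAMPLE_READ = "GCCATG"


@pytest.fixture(scope="session")
def example_index() -> hm.HybridIndex:
    """Hybrid index of the 16-base worked-example sequence, q=1."""
    return hm.build_hybrid_index(
        [("seq", EXAMPLE_SEQ)], hm.IndexBuildConfig(q=1, w=4, rng_seed=1)
    )


@pytest.fixture(scope="session")
def small_genome() -> str:
    """20-kb uniform-random genome used by mid-sized mapping tests."""
    rng = np.random.default_rng(20240401)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])


@pytest.fixture(scope="session")
def small_genome_index(small_genome) -> hm.HybridIndex:
    return hm.build_hybrid_index(
        [("chr1", small_genome)], hm.IndexBuildConfig(q=9, w=8, rng_seed=1)
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def naive_suffix_array(s: str, q: int) -> list[int]:
    """Brute-force sort of all suffixes starting at positions 0..N-q."""
    return sorted(range(len(s) - q + 1), key=lambda i: s[i:])


def naive_locate(s: str, pattern: str) -> list[int]:
    """Naive substring scan."""
    out, start = [], 0
    while True:
        i = s.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def nw_score_oracle(a: str, b: str, match: int = 2, mismatch: int = -2, gap: int = -3) -> int:
    """Best global alignment score via memoized recursion over suffixes.

    Independent of the implementation's iterative matrix + traceback; explores
    every alignment path (with sharing).
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == len(a):
            return (len(b) - j) * gap
        if j == len(b):
            return (len(a) - i) * gap
        sub = match if a[i] == b[j] else mismatch
        return max(best(i + 1, j + 1) + sub, best(i + 1, j) + gap, best(i, j + 1) + gap)

    return best(0, 0)


def nw_score_enumerated(a: str, b: str, match: int = 2, mismatch: int = -2, gap: int = -3) -> int:
    """Plain exhaustive enumeration of all alignments (no sharing); tiny inputs only."""

    def go(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(go(i + 1, j + 1) + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            cands.append(go(i + 1, j) + gap)
        if j < len(b):
            cands.append(go(i, j + 1) + gap)
        return max(cands)

    return go(0, 0)
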