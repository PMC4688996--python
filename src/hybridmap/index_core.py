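"""Hybrid index construction: packed reference, q-gram hash table, suffix array.

The index couples three structures built from one concatenated reference:

* a 2-bit-per-base packed sequence (A=0, C=1, G=2, T=3),
* a hash table ``HT`` of ``4**q + 1`` offsets into the suffix array, so that the
  suffix-array range of q-gram ``x`` is ``[HT[x], HT[x+1] - 1]``,
* a suffix array over the ``N - q + 1`` positions that carry a full q-gram,
  bucket-sorted per q-gram by comparing length-``w`` blocks of following bases.

Lookup of a query then needs one hash-table jump for its length-``q`` prefix and
a binary search over the (small) bucket for the remainder.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyReferenceError,
    IndexFormatError,
    IndexVersionError,
    InvalidAlphabetError,
    SequenceTooShortError,
)

FORMAT_VERSION = 1
_ENDIAN_MARK = 0x0102

# byte value -> 2-bit code; 255 marks "not ACGT"
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE_OF[_b] = _i

_BASES = "ACGT"
_DECODE_TABLE = bytes.maketrans(bytes(range(4)), b"ACGT")


def encode_qgram(s: str) -> int:
    """Encode an ACGT string as an unsigned integer, two bits per base.

    The first base occupies the most significant bit pair, so the encoding
    orders q-grams of equal length lexicographically.
    """
    x = 0
    for ch in s.upper():
        code = _CODE_OF[ord(ch)] if ord(ch) < 256 else 255
        if code == 255:
            raise InvalidAlphabetError(f"non-ACGT symbol {ch!r} in q-gram {s!r}")
        x = (x << 2) | int(code)
    return x


def decode_qgram(x: int, q: int) -> str:
    """Inverse of :func:`encode_qgram` for a fixed length ``q``."""
    out = []
    for shift in range(2 * (q - 1), -1, -2):
        out.append(_BASES[(x >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class RecordSpan:
    """Placement of one FASTA record inside the concatenated reference."""

    name: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


class PackedSequence:
    """Concatenated reference in 2-bit encoding with per-record boundaries.

    ``codes`` holds one byte per base with values in {0,1,2,3}; this is the
    working representation used for all comparisons (Python ``bytes``
    comparison is lexicographic, which matches suffix order). ``data`` is the
    4-bases-per-byte packing used on disk, first base in the most significant
    bit pair of each byte.
    """

    def __init__(self, codes: bytes, boundaries: Sequence[RecordSpan], n_seed: int):
        if len(codes) == 0:
            raise EmptyReferenceError("empty reference sequence")
        self.codes = codes
        self.length = len(codes)
        self.boundaries = tuple(boundaries)
        self.n_seed = int(n_seed)
        if sum(b.length for b in self.boundaries) != self.length:
            raise ValueError("record boundaries do not cover the sequence")
        self._starts = np.array([b.start for b in self.boundaries], dtype=np.int64)

    @property
    def data(self) -> np.ndarray:
        """Bit-packed codes, 4 bases per byte (zero-padded at the tail)."""
        c = np.frombuffer(self.codes, dtype=np.uint8)
        pad = (-len(c)) % 4
        if pad:
            c = np.concatenate([c, np.zeros(pad, dtype=np.uint8)])
        c = c.reshape(-1, 4)
        return (
            (c[:, 0] << 6) | (c[:, 1] << 4) | (c[:, 2] << 2) | c[:, 3]
        ).astype(np.uint8)

    @classmethod
    def from_packed(
        cls,
        packed: np.ndarray,
        length: int,
        boundaries: Sequence[RecordSpan],
        n_seed: int,
    ) -> "PackedSequence":
        p = np.asarray(packed, dtype=np.uint8)
        codes = np.empty((len(p), 4), dtype=np.uint8)
        codes[:, 0] = (p >> 6) & 3
        codes[:, 1] = (p >> 4) & 3
        codes[:, 2] = (p >> 2) & 3
        codes[:, 3] = p & 3
        return cls(codes.reshape(-1)[:length].tobytes(), boundaries, n_seed)

    def fetch(self, start: int, end: int) -> str:
        """Decode bases in the half-open concatenated interval [start, end)."""
        return self.codes[start:end].translate(_DECODE_TABLE).decode()

    def decode(self) -> str:
        return self.fetch(0, self.length)

    def record_of(self, pos: int) -> RecordSpan:
        """Record span containing concatenated position ``pos``."""
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        span = self.boundaries[i]
        if not (span.start <= pos < span.end):
            raise IndexError(f"position {pos} outside the reference")
        return span

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PackedSequence)
            and self.codes == other.codes
            and self.boundaries == other.boundaries
            and self.n_seed == other.n_seed
        )


@dataclass
class HashTable:
    """q-gram hash table: ``offsets[x]`` is the first SA slot of q-gram ``x``."""

    q: int
    offsets: np.ndarray  # 4**q + 1 non-decreasing integers

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HashTable)
            and self.q == other.q
            and np.array_equal(self.offsets, other.offsets)
        )


@dataclass
class SuffixArray:
    """Starting positions of the indexable suffixes in lexicographic order."""

    positions: np.ndarray
    width: int = 4  # byte width used on disk

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SuffixArray)
            and np.array_equal(self.positions, other.positions)
        )


@dataclass
class HybridIndex:
    """Packed sequence + hash table + suffix array built with one q."""

    sequence: PackedSequence
    ht: HashTable
    sa: SuffixArray

    @property
    def q(self) -> int:
        return self.ht.q

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HybridIndex)
            and self.sequence == other.sequence
            and self.ht == other.ht
            and self.sa == other.sa
        )


@dataclass
class IndexBuildConfig:
    """Construction parameters.

    ``q`` is the hash-table q-gram length (the genome-scale default is 14; small
    references want much smaller q). ``w`` is the prefix-block width, in bases,
    used as the integer sort key when ordering suffixes inside one q-gram
    bucket; 0 falls back to an internal default block. ``rng_seed`` drives the
    replacement of non-ACGT symbols.
    """

    q: int = 14
    w: int = 8
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.q <= 16):
            raise ValueError("q must be in [1, 16]")
        if not (0 <= self.w <= 16):
            raise ValueError("w must be in [0, 16]")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file into (name, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _normalize_records(records: Iterable) -> list[tuple[str, str]]:
    out = []
    for rec in records:
        if isinstance(rec, (tuple, list)):
            name, seq = rec
        else:  # Bio.SeqRecord duck-typing
            name, seq = rec.id, str(rec.seq)
        out.append((str(name), str(seq)))
    return out


def pack_reference(records: Iterable, rng_seed: int = 1) -> PackedSequence:
    """Concatenate FASTA records into a 2-bit packed sequence.

    Symbols outside {A,C,G,T} (case-insensitive), including IUPAC ambiguity
    codes and N, are replaced by a base drawn uniformly from a generator
    seeded with ``rng_seed`` so repeated builds are identical.
    """
    pairs = _normalize_records(records)
    if not pairs or any(len(s) == 0 for _, s in pairs):
        raise EmptyReferenceError("reference must contain at least one non-empty record")

    rng = np.random.default_rng(rng_seed)
    boundaries: list[RecordSpan] = []
    chunks: list[np.ndarray] = []
    offset = 0
    for name, seq in pairs:
        raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
        codes = _CODE_OF[raw]
        bad = codes == 255
        n_bad = int(bad.sum())
        if n_bad:
            codes = codes.copy()
            codes[bad] = rng.integers(0, 4, size=n_bad, dtype=np.uint8)
        chunks.append(codes)
        boundaries.append(RecordSpan(name, offset, len(seq)))
        offset += len(seq)
    return PackedSequence(np.concatenate(chunks).tobytes(), boundaries, rng_seed)


def _qgram_values(seq: PackedSequence, q: int) -> np.ndarray:
    """Integer value of the q-gram starting at every position 0..N-q."""
    codes = np.frombuffer(seq.codes, dtype=np.uint8)
    n = seq.length - q + 1
    vals = np.zeros(n, dtype=np.int64)
    for j in range(q):
        vals = (vals << 2) | codes[j : j + n]
    return vals


def build_hash_table(seq: PackedSequence, q: int) -> HashTable:
    """Count q-grams and store exclusive prefix sums as SA offsets."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if seq.length < q:
        raise SequenceTooShortError(
            f"reference length {seq.length} is shorter than q={q}"
        )
    vals = _qgram_values(seq, q)
    counts = np.bincount(vals, minlength=4**q)
    offsets = np.zeros(4**q + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    return HashTable(q=q, offsets=offsets)


def _sort_bucket(codes: bytes, positions: list[int], depth: int, w: int, n: int) -> list[int]:
    """Sort suffix start positions by their suffixes from ``depth`` onward.

    Positions are keyed on the length-``w`` block of bases at offset ``depth``;
    groups still tied after the block (which then necessarily all have at least
    ``w`` bases left) are refined recursively. A suffix that ends inside the
    block yields a shorter key, and bytes comparison puts the shorter key
    first, matching the shorter-suffix-sorts-first convention.
    """
    if len(positions) <= 1:
        return positions
    keyed = sorted(positions, key=lambda p: codes[p + depth : p + depth + w])
    out: list[int] = []
    i = 0
    while i < len(keyed):
        j = i + 1
        ki = codes[keyed[i] + depth : keyed[i] + depth + w]
        while j < len(keyed) and codes[keyed[j] + depth : keyed[j] + depth + w] == ki:
            j += 1
        group = keyed[i:j]
        if len(group) > 1 and depth + w < n:
            group = _sort_bucket(codes, group, depth + w, w, n)
        out.extend(group)
        i = j
    return out


def build_suffix_array(seq: PackedSequence, ht: HashTable, w: int = 8) -> SuffixArray:
    """Place each q-gram's positions into its SA range and sort each range.

    The result equals a full comparison sort of all suffixes starting at
    positions 0..N-q (suffixes shorter than q are not indexed).
    """
    q = ht.q
    w_eff = w if w >= 1 else 8
    vals = _qgram_values(seq, q)
    # stable argsort groups positions by q-gram, ascending position within each
    order = np.argsort(vals, kind="stable").astype(np.int64)
    offsets = ht.offsets
    counts = np.diff(offsets)
    multi = np.nonzero(counts > 1)[0]
    codes = seq.codes
    n = seq.length
    positions = order.copy()
    for x in multi:
        lo, hi = int(offsets[x]), int(offsets[x + 1])
        bucket = positions[lo:hi].tolist()
        positions[lo:hi] = _sort_bucket(codes, bucket, q, w_eff, n)
    width = 4 if len(positions) < 2**31 else 8
    return SuffixArray(positions=positions, width=width)


def build_hybrid_index(records: Iterable, config: IndexBuildConfig | None = None) -> HybridIndex:
    """Pack the reference, build HT and SA, and bundle them."""
    config = config or IndexBuildConfig()
    seq = pack_reference(records, rng_seed=config.rng_seed)
    ht = build_hash_table(seq, config.q)
    sa = build_suffix_array(seq, ht, w=config.w)
    return HybridIndex(sequence=seq, ht=ht, sa=sa)


# ---------------------------------------------------------------------------
# serialization: basename.seq / .idx / .sa / .seqInfo
# ---------------------------------------------------------------------------

_MAGIC_SEQ = b"HMSQ"
_MAGIC_HT = b"HMHT"
_MAGIC_SA = b"HMSA"


def _write_header(fh, magic: bytes) -> None:
    fh.write(magic)
    fh.write(struct.pack("<HH", FORMAT_VERSION, _ENDIAN_MARK))


def _read_header(fh, magic: bytes, path: Path) -> None:
    got = fh.read(8)
    if len(got) != 8 or got[:4] != magic:
        raise IndexFormatError(f"{path}: bad or missing magic bytes")
    version, endian = struct.unpack("<HH", got[4:])
    if endian != _ENDIAN_MARK:
        raise IndexFormatError(f"{path}: endianness marker mismatch")
    if version != FORMAT_VERSION:
        raise IndexVersionError(
            f"{path}: format version {version}, expected {FORMAT_VERSION}"
        )


def _int_dtype(width: int) -> np.dtype:
    return np.dtype("<u4") if width == 4 else np.dtype("<u8")


def save_index(index: HybridIndex, basename: str | Path, _width_threshold: int = 2**31) -> None:
    """Write the four index files ``basename.{seq,idx,sa,seqInfo}``.

    Integer arrays use 4-byte entries while all values fit below
    ``_width_threshold`` and 8-byte entries otherwise; the chosen width is
    recorded in each binary header.
    """
    base = Path(basename)
    seq, ht, sa = index.sequence, index.ht, index.sa
    width = 4 if len(sa.positions) < _width_threshold else 8

    with open(base.with_suffix(base.suffix + ".seq"), "wb") as fh:
        _write_header(fh, _MAGIC_SEQ)
        fh.write(struct.pack("<Q", seq.length))
        fh.write(seq.data.tobytes())

    with open(base.with_suffix(base.suffix + ".idx"), "wb") as fh:
        _write_header(fh, _MAGIC_HT)
        fh.write(struct.pack("<HBQ", ht.q, width, len(ht.offsets)))
        fh.write(ht.offsets.astype(_int_dtype(width)).tobytes())

    with open(base.with_suffix(base.suffix + ".sa"), "wb") as fh:
        _write_header(fh, _MAGIC_SA)
        fh.write(struct.pack("<BQ", width, len(sa.positions)))
        fh.write(sa.positions.astype(_int_dtype(width)).tobytes())

    with open(base.with_suffix(base.suffix + ".seqInfo"), "w") as fh:
        fh.write(f"#format_version\t{FORMAT_VERSION}\n")
        fh.write(f"#q\t{ht.q}\n")
        fh.write(f"#N\t{seq.length}\n")
        fh.write(f"#rng_seed\t{seq.n_seed}\n")
        for span in seq.boundaries:
            fh.write(f"{span.name}\t{span.start}\t{span.length}\n")


def _read_exact(fh, nbytes: int, path: Path) -> bytes:
    buf = fh.read(nbytes)
    if len(buf) != nbytes:
        raise IndexFormatError(f"{path}: truncated file")
    return buf


def load_index(basename: str | Path) -> HybridIndex:
    """Load an index written by :func:`save_index`; inverse field-for-field."""
    base = Path(basename)
    paths = {
        ext: base.with_suffix(base.suffix + "." + ext)
        for ext in ("seq", "idx", "sa", "seqInfo")
    }
    for p in paths.values():
        if not p.exists():
            raise IndexFormatError(f"{p}: missing index file")

    meta: dict[str, int] = {}
    boundaries: list[RecordSpan] = []
    with open(paths["seqInfo"]) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                meta[key] = int(val)
            else:
                name, off, length = line.split("\t")
                boundaries.append(RecordSpan(name, int(off), int(length)))
    if meta.get("format_version") != FORMAT_VERSION:
        raise IndexVersionError(f"{paths['seqInfo']}: unsupported format version")
    if not boundaries:
        raise IndexFormatError(f"{paths['seqInfo']}: no record boundaries")

    with open(paths["seq"], "rb") as fh:
        _read_header(fh, _MAGIC_SEQ, paths["seq"])
        (n,) = struct.unpack("<Q", _read_exact(fh, 8, paths["seq"]))
        if n != meta["N"]:
            raise IndexFormatError(f"{paths['seq']}: N disagrees with seqInfo")
        packed = np.frombuffer(
            _read_exact(fh, (n + 3) // 4, paths["seq"]), dtype=np.uint8
        )
    seq = PackedSequence.from_packed(packed, n, boundaries, meta["rng_seed"])

    with open(paths["idx"], "rb") as fh:
        _read_header(fh, _MAGIC_HT, paths["idx"])
        q, width, n_off = struct.unpack("<HBQ", _read_exact(fh, 11, paths["idx"]))
        if q != meta["q"] or n_off != 4**q + 1:
            raise IndexFormatError(f"{paths['idx']}: inconsistent header")
        offsets = np.frombuffer(
            _read_exact(fh, n_off * width, paths["idx"]), dtype=_int_dtype(width)
        ).astype(np.int64)
    ht = HashTable(q=q, offsets=offsets)

    with open(paths["sa"], "rb") as fh:
        _read_header(fh, _MAGIC_SA, paths["sa"])
        width, n_pos = struct.unpack("<BQ", _read_exact(fh, 9, paths["sa"]))
        if n_pos != n - q + 1 or n_pos != offsets[-1]:
            raise IndexFormatError(f"{paths['sa']}: size disagrees with HT/seqInfo")
        positions = np.frombuffer(
            _read_exact(fh, n_pos * width, paths["sa"]), dtype=_int_dtype(width)
        ).astype(np.int64)
    sa = SuffixArray(positions=positions, width=width)

    return HybridIndex(sequence=seq, ht=ht, sa=sa)
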