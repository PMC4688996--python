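"""End-to-end read mapping: strands, extended fallback, pairing, I/O, evaluation.

``map_read`` runs the seeding + CAR-alignment pipeline on a read and its
reverse complement and reports the best placement, with mapping quality from
the best/second-best score gap. Reads that fail the acceptance floor are
retried once with extended parameters (shorter seeds, relaxed frequency cap,
more candidate regions) before being declared unmapped. A seeded read
simulator and a position-tolerance evaluator close the loop for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .car_align import (
    AlignmentResult,
    PairInfo,
    ScoringScheme,
    align_car,
    compute_mapq,
)
from .errors import EvaluationError, ReadTooShortError
from .index_core import HybridIndex, PackedSequence
from .seeding import SeedingConfig, choose_seed_length, find_cars

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read; ``mate_index`` is 0/1 for paired data, None otherwise."""

    name: str
    sequence: str
    qualities: Optional[str] = None
    mate_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.name}: quality string length mismatch")


@dataclass
class TruthRecord:
    """Where a simulated read really came from (0-based leftmost position)."""

    name: str
    record: str
    pos: int
    strand: str


@dataclass
class MapperConfig:
    """Everything map_read / map_pair need.

    The extended fallback halves the seed length (never below the hash-table
    q), multiplies the frequency cap by ``extended_freq_factor`` and the CAR
    budget by ``extended_cars_factor``. An alignment is accepted when its
    matched bases reach ``min_matched_frac`` of the read length. ``strands``
    may be "both" or "forward" (the latter pins the worked-example pipeline).
    ``threads`` is accepted for interface compatibility; execution is serial
    and the output is independent of it.
    """

    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    extended_enabled: bool = True
    extended_q_factor: int = 2
    extended_freq_factor: int = 10
    extended_cars_factor: int = 4
    min_matched_frac: float = 0.4
    strands: str = "both"
    insert_min: int = 100
    insert_max: int = 1000
    mapq_scale: int = 2
    threads: int = 1


def _candidates(
    index: HybridIndex, read: str, config: MapperConfig, extended: bool
) -> list[AlignmentResult]:
    """Accepted alignments of one read on the requested strands, best first."""
    m = len(read)
    seed_cfg = config.seeding
    q_seed = seed_cfg.q_seed or choose_seed_length(m, seed_cfg.error_rate, index.q)
    if extended:
        seed_cfg = replace(
            seed_cfg,
            q_seed=max(index.q, q_seed // config.extended_q_factor),
            freq_cap=seed_cfg.freq_cap * config.extended_freq_factor,
            max_cars=seed_cfg.max_cars * config.extended_cars_factor,
        )
    else:
        seed_cfg = replace(seed_cfg, q_seed=q_seed)

    floor = config.min_matched_frac * m
    out: list[AlignmentResult] = []
    strands = ["+", "-"] if config.strands == "both" else ["+"]
    for strand in strands:
        seq = read if strand == "+" else reverse_complement(read)
        for car in find_cars(index, seq, seed_cfg):
            try:
                result = align_car(
                    seq,
                    car,
                    index,
                    scoring=config.scoring,
                    flank_allowance=seed_cfg.adjacency_limit,
                )
            except Exception:
                continue
            if result.matches >= floor:
                result.strand = strand
                out.append(result)
    out.sort(key=lambda r: (-r.score, r.ref_record, r.ref_pos, r.strand))
    # drop duplicate placements (same record, position, strand)
    seen: set[tuple[str, int, str]] = set()
    uniq = []
    for r in out:
        key = (r.ref_record, r.ref_pos, r.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(r)
    return uniq


def _candidates_with_fallback(
    index: HybridIndex, read: str, config: MapperConfig
) -> list[AlignmentResult]:
    cands = _candidates(index, read, config, extended=False)
    if not cands and config.extended_enabled:
        cands = _candidates(index, read, config, extended=True)
    return cands


def map_read(
    index: HybridIndex, read: ReadRecord | str, config: MapperConfig | None = None
) -> list[AlignmentResult]:
    """Best placement of a read (empty list when unmapped)."""
    config = config or MapperConfig()
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < index.q:
        raise ReadTooShortError(
            f"read length {len(seq)} < hash-table q-gram length {index.q}"
        )
    cands = _candidates_with_fallback(index, seq, config)
    if not cands:
        return []
    best = cands[0]
    second = cands[1] if len(cands) > 1 else None
    best.mapq = compute_mapq(best, second, scale=config.mapq_scale)
    return [best]


def map_pair(
    index: HybridIndex,
    r1: ReadRecord,
    r2: ReadRecord,
    config: MapperConfig | None = None,
) -> list[Optional[AlignmentResult]]:
    """Map both mates; flag the best FR pair within the insert window as proper.

    Returns [result1, result2] with None for an unmapped mate. Each mate's
    MAPQ comes from its own candidate ranking; the pair choice maximizes the
    summed score among placements satisfying forward-reverse orientation on
    one record with insert size inside [insert_min, insert_max].
    """
    config = config or MapperConfig()
    cands = [
        _candidates_with_fallback(index, r.sequence, config)[:10] for r in (r1, r2)
    ]
    results: list[Optional[AlignmentResult]] = [None, None]
    for k in (0, 1):
        if cands[k]:
            best = cands[k][0]
            second = cands[k][1] if len(cands[k]) > 1 else None
            best.mapq = compute_mapq(best, second, scale=config.mapq_scale)
            results[k] = best

    best_pair: tuple[int, AlignmentResult, AlignmentResult] | None = None
    for a in cands[0]:
        for b in cands[1]:
            if a.ref_record != b.ref_record or a.strand == b.strand:
                continue
            fwd, rev = (a, b) if a.strand == "+" else (b, a)
            tlen = rev.ref_end - fwd.ref_pos
            if fwd.ref_pos <= rev.ref_pos and config.insert_min <= tlen <= config.insert_max:
                if best_pair is None or a.score + b.score > best_pair[0]:
                    best_pair = (a.score + b.score, a, b)
    proper = False
    if best_pair is not None:
        _, a, b = best_pair
        for k, r in ((0, a), (1, b)):
            if results[k] is not r:
                r.mapq = results[k].mapq if results[k] is not None else 0
                results[k] = r
        proper = True

    for k in (0, 1):
        mate = results[1 - k]
        info = PairInfo(
            mate_index=k,
            proper=proper,
            mate_unmapped=mate is None,
            mate_record=mate.ref_record if mate else None,
            mate_pos=mate.ref_pos if mate else 0,
            mate_reverse=(mate.strand == "-") if mate else False,
        )
        if results[k] is not None:
            results[k].pair = info
        else:
            # keep mate info for the unmapped record via a placeholder on the read
            pass
    if proper and results[0] and results[1]:
        fwd, rev = (
            (results[0], results[1]) if results[0].strand == "+" else (results[1], results[0])
        )
        tlen = rev.ref_end - fwd.ref_pos
        fwd.pair.tlen = tlen
        rev.pair.tlen = -tlen
    return results


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _mutate_segment(
    rec_seq: str, start: int, m: int, error_rate: float, indel_rate: float, rng
) -> str:
    """Walk the reference from ``start`` emitting m read bases with errors."""
    bases = "ACGT"
    out: list[str] = []
    i = start
    L = len(rec_seq)
    while len(out) < m:
        if i >= L:  # ran off the record end (rare, deletion-heavy walk)
            out.append(bases[rng.integers(0, 4)])
            continue
        r = rng.random()
        if r < indel_rate / 2:
            out.append(bases[rng.integers(0, 4)])  # insertion
        elif r < indel_rate:
            i += 1  # deletion
        else:
            b = rec_seq[i]
            if error_rate > 0 and rng.random() < error_rate:
                b = bases[(bases.index(b) + int(rng.integers(1, 4))) % 4]
            out.append(b)
            i += 1
    return "".join(out)


def simulate_reads(
    reference: Sequence[tuple[str, str]] | str | Path,
    n: int,
    m: int,
    error_rate: float = 0.0,
    indel_rate: float = 0.0,
    insert: Optional[tuple[float, float]] = None,
    seed: int = 1,
    out_prefix: str | Path | None = None,
) -> tuple[list, list[TruthRecord]]:
    """Draw n reads of length m from the reference with seeded errors.

    Substitutions occur per base at ``error_rate`` and 1-base indels at
    ``indel_rate``; strands are sampled uniformly. With ``insert``
    (mean, sd of the fragment length), forward-reverse pairs are produced and
    the result is a list of (mate1, mate2) tuples plus one truth record per
    mate. With ``out_prefix`` set, FASTQ file(s) and a truth TSV are written
    (``prefix.fq`` or ``prefix_1.fq``/``prefix_2.fq``, plus ``prefix.truth.tsv``).
    Identical seeds give byte-identical output.
    """
    if isinstance(reference, (str, Path)):
        from .index_core import read_fasta

        reference = read_fasta(reference)
    records = [(name, seq.upper()) for name, seq in reference]
    rng = np.random.default_rng(seed)

    frag_needed = m if insert is None else int(m + (insert[0] + 6 * insert[1]))
    usable = [(name, seq) for name, seq in records if len(seq) >= frag_needed]
    if not usable:
        raise ValueError(f"no reference record is long enough for read length {m}")
    weights = np.array([len(s) for _, s in usable], dtype=float)
    weights /= weights.sum()

    reads: list = []
    truth: list[TruthRecord] = []
    for i in range(n):
        ridx = int(rng.choice(len(usable), p=weights))
        name, seq = usable[ridx]
        if insert is None:
            pos = int(rng.integers(0, len(seq) - m + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            bases = _mutate_segment(seq, pos, m, error_rate, indel_rate, rng)
            if strand == "-":
                bases = reverse_complement(bases)
            qual = "".join(chr(33 + int(q)) for q in rng.integers(30, 41, size=m))
            rname = f"sim_{i}"
            reads.append(ReadRecord(rname, bases, qual))
            truth.append(TruthRecord(rname, name, pos, strand))
        else:
            mean, sd = insert
            frag = max(m, int(round(rng.normal(mean, sd))))
            frag = min(frag, len(seq))
            pos = int(rng.integers(0, len(seq) - frag + 1))
            p1, p2 = pos, pos + frag - m
            b1 = _mutate_segment(seq, p1, m, error_rate, indel_rate, rng)
            b2 = reverse_complement(
                _mutate_segment(seq, p2, m, error_rate, indel_rate, rng)
            )
            q1 = "".join(chr(33 + int(q)) for q in rng.integers(30, 41, size=m))
            q2 = "".join(chr(33 + int(q)) for q in rng.integers(30, 41, size=m))
            rname = f"sim_{i}"
            pair = (
                ReadRecord(rname, b1, q1, mate_index=0),
                ReadRecord(rname, b2, q2, mate_index=1),
            )
            reads.append(pair)
            truth.append(TruthRecord(rname + "/1", name, p1, "+"))
            truth.append(TruthRecord(rname + "/2", name, p2, "-"))

    if out_prefix is not None:
        prefix = Path(out_prefix)
        if insert is None:
            with open(prefix.with_suffix(".fq"), "w") as fh:
                for r in reads:
                    fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.qualities}\n")
        else:
            with open(f"{prefix}_1.fq", "w") as f1, open(f"{prefix}_2.fq", "w") as f2:
                for r1, r2 in reads:
                    f1.write(f"@{r1.name}\n{r1.sequence}\n+\n{r1.qualities}\n")
                    f2.write(f"@{r2.name}\n{r2.sequence}\n+\n{r2.qualities}\n")
        write_truth(truth, f"{prefix}.truth.tsv")
    return reads, truth


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\trecord\tpos\tstrand\n")
        for t in truth:
            fh.write(f"{t.name}\t{t.record}\t{t.pos}\t{t.strand}\n")


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, record, pos, strand = line.rstrip("\n").split("\t")
            out[name] = TruthRecord(name, record, int(pos), strand)
    return out


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a FASTQ (Phred+33) file into ReadRecords."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(33 + q) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq), qual))
    return out


# ---------------------------------------------------------------------------
# SAM output and evaluation
# ---------------------------------------------------------------------------

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def _sam_header(index: HybridIndex) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": span.name, "LN": span.length}
            for span in index.sequence.boundaries
        ],
        "PG": [{"ID": "hybridmap", "PN": "hybridmap", "VN": "0.1.0"}],
    }


def write_sam(
    alignments: Sequence[Optional[AlignmentResult]],
    reads: Sequence[ReadRecord],
    index: HybridIndex,
    path: str | Path,
) -> None:
    """Write one SAM record per read (FLAG 4 for unmapped), 1-based POS.

    ``alignments[i]`` is the placement of ``reads[i]`` or None. The aligned
    orientation of the sequence is stored (reverse-complemented for reverse-
    strand placements) together with NM and AS tags.
    """
    import pysam

    header = pysam.AlignmentHeader.from_dict(_sam_header(index))
    ref_ids = {span.name: i for i, span in enumerate(index.sequence.boundaries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, result in zip(reads, alignments):
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name
            flag = 0
            if read.mate_index is not None:
                flag |= 1 | (64 if read.mate_index == 0 else 128)
            if result is None:
                seg.flag = flag | 4
                seg.query_sequence = read.sequence
                if read.qualities:
                    seg.query_qualities = pysam.qualitystring_to_array(read.qualities)
                out.write(seg)
                continue
            seq = read.sequence
            qual = read.qualities
            if result.strand == "-":
                flag |= 16
                seq = reverse_complement(seq)
                qual = qual[::-1] if qual else None
            if result.pair is not None:
                if result.pair.proper:
                    flag |= 2
                if result.pair.mate_unmapped:
                    flag |= 8
                if result.pair.mate_reverse:
                    flag |= 32
                if result.pair.mate_record is not None:
                    seg.next_reference_id = ref_ids[result.pair.mate_record]
                    seg.next_reference_start = result.pair.mate_pos
                seg.template_length = result.pair.tlen
            seg.flag = flag
            seg.reference_id = ref_ids[result.ref_record]
            seg.reference_start = result.ref_pos
            seg.mapping_quality = result.mapq
            seg.cigartuples = [(_CIGAR_CODE[op], n) for n, op in result.cigar]
            seg.query_sequence = seq
            if qual:
                seg.query_qualities = pysam.qualitystring_to_array(qual)
            seg.set_tag("NM", result.nm)
            seg.set_tag("AS", result.score)
            out.write(seg)


def evaluate_accuracy(
    sam: str | Path | Iterable,
    truth: dict[str, TruthRecord] | Sequence[TruthRecord],
    tolerance_bp: int = 50,
) -> dict:
    """Score SAM placements against the simulator truth.

    An alignment is correct only when it lies on the same record and strand as
    the truth and its leftmost position is within ``tolerance_bp``. "unique"
    means MAPQ >= 1 and "q10" means MAPQ >= 10; percentages are over all
    primary records. Returned keys: aligned, unique, correct, q10,
    unique_correct (all percentages), plus raw counts under ``n_*``.
    """
    import pysam

    if not isinstance(truth, dict):
        truth = {t.name: t for t in truth}

    if isinstance(sam, (str, Path)):
        fh = pysam.AlignmentFile(str(sam), "r")
        records = list(fh)
        fh.close()
    else:
        records = list(sam)

    n = n_aligned = n_unique = n_q10 = n_correct = n_uc = 0
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        name = rec.query_name
        if rec.is_paired:
            name = f"{name}/{2 if rec.is_read2 else 1}"
        t = truth.get(name) or truth.get(rec.query_name)
        if t is None:
            raise EvaluationError(f"read {name} missing from the truth table")
        n += 1
        if rec.is_unmapped:
            continue
        n_aligned += 1
        unique = rec.mapping_quality >= 1
        q10 = rec.mapping_quality >= 10
        correct = (
            rec.reference_name == t.record
            and ("-" if rec.is_reverse else "+") == t.strand
            and abs(rec.reference_start - t.pos) <= tolerance_bp
        )
        n_unique += unique
        n_q10 += q10
        n_correct += correct
        n_uc += unique and correct
    pct = lambda k: 100.0 * k / n if n else 0.0
    return {
        "aligned": pct(n_aligned),
        "unique": pct(n_unique),
        "correct": pct(n_correct),
        "q10": pct(n_q10),
        "unique_correct": pct(n_uc),
        "n_reads": n,
        "n_aligned": n_aligned,
        "n_unique": n_unique,
        "n_correct": n_correct,
        "n_q10": n_q10,
    }


def summarize_run(
    alignments: Sequence[Optional[AlignmentResult]],
    reads: Sequence[ReadRecord],
) -> dict:
    """Mapping-run report: totals, rates, MAPQ histogram, per-position quality."""
    n = len(reads)
    n_aligned = sum(1 for a in alignments if a is not None)
    n_unique = sum(1 for a in alignments if a is not None and a.mapq >= 1)
    hist: dict[str, int] = {}
    for a in alignments:
        if a is None:
            continue
        bucket = f"{(a.mapq // 10) * 10}-{(a.mapq // 10) * 10 + 9}"
        hist[bucket] = hist.get(bucket, 0) + 1
    max_len = max((len(r.sequence) for r in reads), default=0)
    qual_sum = np.zeros(max_len)
    qual_n = np.zeros(max_len)
    for r in reads:
        if r.qualities:
            q = np.frombuffer(r.qualities.encode(), dtype=np.uint8) - 33
            qual_sum[: len(q)] += q
            qual_n[: len(q)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_q = np.where(qual_n > 0, qual_sum / np.maximum(qual_n, 1), np.nan)
    return {
        "total_reads": n,
        "aligned": n_aligned,
        "aligned_pct": 100.0 * n_aligned / n if n else 0.0,
        "unique": n_unique,
        "unique_pct": 100.0 * n_unique / n if n else 0.0,
        "mapq_histogram": dict(sorted(hist.items())),
        "mean_base_quality_by_position": [
            round(float(v), 3) if qn else None for v, qn in zip(mean_q, qual_n)
        ],
    }


def render_summary(summary: dict) -> str:
    """Plain-text rendering of :func:`summarize_run` output."""
    lines = [
        "mapping summary",
        f"  total reads   : {summary['total_reads']}",
        f"  aligned       : {summary['aligned']} ({summary['aligned_pct']:.2f}%)",
        f"  unique (Q>=1) : {summary['unique']} ({summary['unique_pct']:.2f}%)",
        "  MAPQ histogram:",
    ]
    for bucket, count in summary["mapq_histogram"].items():
        lines.append(f"    {bucket:>7}: {count}")
    quals = [q for q in summary["mean_base_quality_by_position"] if q is not None]
    if quals:
        lines.append(
            f"  mean base quality: {sum(quals) / len(quals):.2f} "
            f"(first {quals[0]:.1f}, last {quals[-1]:.1f})"
        )
    return "\n".join(lines)


def run_mapping(
    index: HybridIndex,
    reads1: Sequence[ReadRecord],
    reads2: Optional[Sequence[ReadRecord]] = None,
    config: MapperConfig | None = None,
    out_sam: str | Path | None = None,
) -> tuple[list[Optional[AlignmentResult]], list[ReadRecord], dict]:
    """Map a batch (optionally paired), in input order; returns (alignments, reads, summary)."""
    config = config or MapperConfig()
    flat_reads: list[ReadRecord] = []
    results: list[Optional[AlignmentResult]] = []
    if reads2 is None:
        for r in reads1:
            try:
                hits = map_read(index, r, config)
            except ReadTooShortError:
                hits = []
            flat_reads.append(r)
            results.append(hits[0] if hits else None)
    else:
        for r1, r2 in zip(reads1, reads2):
            r1.mate_index, r2.mate_index = 0, 1
            res = map_pair(index, r1, r2, config)
            flat_reads.extend([r1, r2])
            results.extend(res)
    summary = summarize_run(results, flat_reads)
    if out_sam is not None:
        write_sam(results, flat_reads, index, out_sam)
    return results, flat_reads, summary
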