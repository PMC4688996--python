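"""End-to-end mapping, simulation, SAM output, pairing, evaluation, summary."""

from __future__ import annotations

import json

import numpy as np
import pysam
import pytest

import hybridmap as hm
from hybridmap.errors import EvaluationError, ReadTooShortError

from conftest import EXAMPLE_READ, EXAMPLE_SEQ


@pytest.fixture(scope="module")
def mapped_batch(small_genome_index, small_genome, tmp_path_factory):
    """Map 60 noisy simulated reads once; reused by SAM/evaluation tests."""
    reads, truth = hm.simulate_reads(
        [("chr1", small_genome)], n=60, m=100, error_rate=0.02, indel_rate=0.002, seed=31
    )
    results, flat, summary = hm.run_mapping(small_genome_index, reads)
    sam = tmp_path_factory.mktemp("sam") / "batch.sam"
    hm.write_sam(results, flat, small_genome_index, sam)
    return reads, truth, results, summary, sam


class TestMapRead:
    def test_worked_example_forward_pipeline(self, example_index):
        cfg = hm.MapperConfig(
            seeding=hm.SeedingConfig(q_seed=2, adjacency_limit=10),
            strands="forward",
            extended_enabled=False,
            min_matched_frac=0.4,
        )
        (res,) = hm.map_read(example_index, EXAMPLE_READ, cfg)
        assert res.ref_pos == 5
        assert res.cigar == [(2, "M"), (1, "I"), (3, "M")]

    def test_exact_read_maps_uniquely(self, small_genome_index, small_genome):
        read = small_genome[4000:4030]
        (res,) = hm.map_read(small_genome_index, read, hm.MapperConfig())
        assert (res.ref_pos, res.strand) == (4000, "+")
        assert res.cigar == [(30, "M")] and res.mapq == 60

    def test_reverse_complement_maps_to_same_place(self, small_genome_index, small_genome):
        read = small_genome[4000:4030]
        (fwd,) = hm.map_read(small_genome_index, read, hm.MapperConfig())
        (rev,) = hm.map_read(small_genome_index, hm.reverse_complement(read), hm.MapperConfig())
        assert (rev.ref_pos, rev.strand) == (fwd.ref_pos, "-")
        assert rev.score == fwd.score

    def test_unmappable_read_returns_empty(self, small_genome_index):
        # a read of pure A's almost surely has no 40%-matched placement
        assert hm.map_read(small_genome_index, "A" * 100, hm.MapperConfig()) == []

    def test_too_short_read_raises(self, small_genome_index):
        with pytest.raises(ReadTooShortError):
            hm.map_read(small_genome_index, "ACGT", hm.MapperConfig())

    def test_extended_fallback_recovers_error_dense_read(
        self, small_genome_index, small_genome
    ):
        # error-free config picks a whole-read seed; one substitution kills it,
        # so only the extended pass (halved seed length) can place the read
        start = 9000
        read = list(small_genome[start : start + 60])
        for pos in (25,):
            read[pos] = "ACGT"[("ACGT".index(read[pos]) + 1) % 4]
        read = "".join(read)
        cfg_no = hm.MapperConfig(
            seeding=hm.SeedingConfig(error_rate=0.0), extended_enabled=False
        )
        cfg_ext = hm.MapperConfig(
            seeding=hm.SeedingConfig(error_rate=0.0), extended_enabled=True
        )
        assert hm.map_read(small_genome_index, read, cfg_no) == []
        (res,) = hm.map_read(small_genome_index, read, cfg_ext)
        assert abs(res.ref_pos - start) <= 2


class TestSimulator:
    def test_error_free_reads_are_exact_substrings(self, small_genome):
        reads, truth = hm.simulate_reads([("chr1", small_genome)], n=50, m=40, seed=8)
        for r, t in zip(reads, truth):
            seg = small_genome[t.pos : t.pos + 40]
            expected = seg if t.strand == "+" else hm.reverse_complement(seg)
            assert r.sequence == expected

    def test_same_seed_gives_identical_fastq(self, small_genome, tmp_path):
        for name in ("a", "b"):
            hm.simulate_reads(
                [("chr1", small_genome)], n=30, m=50, error_rate=0.05, indel_rate=0.01,
                seed=99, out_prefix=tmp_path / name,
            )
        assert (tmp_path / "a.fq").read_bytes() == (tmp_path / "b.fq").read_bytes()
        assert (tmp_path / "a.truth.tsv").read_text() == (tmp_path / "b.truth.tsv").read_text()

    def test_substitution_rate_within_three_se(self, small_genome):
        eps, m, n = 0.02, 100, 1000  # 1e5 bases
        reads, truth = hm.simulate_reads(
            [("chr1", small_genome)], n=n, m=m, error_rate=eps, seed=12
        )
        mismatches = 0
        for r, t in zip(reads, truth):
            seg = small_genome[t.pos : t.pos + m]
            seq = r.sequence if t.strand == "+" else hm.reverse_complement(r.sequence)
            mismatches += sum(1 for a, b in zip(seq, seg) if a != b)
        total = n * m
        se = (eps * (1 - eps) / total) ** 0.5
        assert abs(mismatches / total - eps) <= 3 * se

    def test_read_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            hm.simulate_reads([("r", "ACGTACGT")], n=1, m=50, seed=1)

    def test_truth_round_trip(self, tmp_path):
        truth = [hm.TruthRecord("x", "chr1", 123, "-")]
        hm.write_truth(truth, tmp_path / "t.tsv")
        loaded = hm.read_truth(tmp_path / "t.tsv")
        assert loaded["x"] == truth[0]


class TestSamOutput:
    def test_worked_example_record_pos_is_one_based(self, example_index, tmp_path):
        cfg = hm.MapperConfig(
            seeding=hm.SeedingConfig(q_seed=2), strands="forward", extended_enabled=False
        )
        (res,) = hm.map_read(example_index, EXAMPLE_READ, cfg)
        read = hm.ReadRecord("wex", EXAMPLE_READ, "I" * 6)
        path = tmp_path / "wex.sam"
        hm.write_sam([res], [read], example_index, path)
        text = path.read_text()
        assert "\t6\t" in text and "2M1I3M" in text
        rec = next(iter(pysam.AlignmentFile(str(path), "r")))
        assert rec.reference_start == 5 and rec.cigarstring == "2M1I3M"
        assert rec.get_tag("NM") == 1

    def test_unmapped_record_conventions(self, small_genome_index, tmp_path):
        read = hm.ReadRecord("dark", "A" * 60, "I" * 60)
        path = tmp_path / "um.sam"
        hm.write_sam([None], [read], small_genome_index, path)
        rec = next(iter(pysam.AlignmentFile(str(path), "r")))
        assert rec.is_unmapped and rec.flag & 4
        assert rec.cigarstring is None

    def test_output_parses_cleanly_and_conserves_read_lengths(self, mapped_batch):
        *_, sam = mapped_batch
        with pysam.AlignmentFile(str(sam), "r") as fh:
            n = 0
            for rec in fh:
                n += 1
                if not rec.is_unmapped:
                    consumed = sum(
                        l for op, l in rec.cigartuples if op in (0, 1, 4)
                    )
                    assert consumed == rec.query_length
        assert n == 60


class TestPairing:
    def test_proper_pair_flags_and_tlen(self, small_genome_index, small_genome):
        frag, m = 375, 80
        p = 6000
        r1 = hm.ReadRecord("p0", small_genome[p : p + m], None, 0)
        r2 = hm.ReadRecord(
            "p0", hm.reverse_complement(small_genome[p + frag - m : p + frag]), None, 1
        )
        a, b = hm.map_pair(small_genome_index, r1, r2, hm.MapperConfig())
        assert a.pair.proper and b.pair.proper
        assert a.strand == "+" and b.strand == "-"
        assert a.pair.tlen == frag and b.pair.tlen == -frag
        assert a.ref_pos == p and b.ref_pos == p + frag - m

    def test_distant_mates_not_properly_paired(self, small_genome_index, small_genome):
        m = 80
        r1 = hm.ReadRecord("p1", small_genome[1000 : 1000 + m], None, 0)
        r2 = hm.ReadRecord(
            "p1", hm.reverse_complement(small_genome[9000 : 9000 + m]), None, 1
        )
        a, b = hm.map_pair(small_genome_index, r1, r2, hm.MapperConfig(insert_max=1000))
        assert a is not None and b is not None
        assert not a.pair.proper and not b.pair.proper

    def test_one_mate_unmappable(self, small_genome_index, small_genome):
        r1 = hm.ReadRecord("p2", small_genome[2000:2080], None, 0)
        r2 = hm.ReadRecord("p2", "A" * 80, None, 1)
        a, b = hm.map_pair(small_genome_index, r1, r2, hm.MapperConfig())
        assert b is None
        assert a is not None and a.pair.mate_unmapped


class TestEvaluation:
    def test_exact_truth_is_correct(self, mapped_batch):
        reads, truth, results, _, sam = mapped_batch
        metrics = hm.evaluate_accuracy(sam, truth)
        assert metrics["n_reads"] == 60
        assert metrics["correct"] >= 90.0
        assert 0 <= metrics["q10"] <= 100

    def test_tolerance_boundary_at_50bp(self, small_genome_index, tmp_path, small_genome):
        read = small_genome[3000:3060]
        (res,) = hm.map_read(small_genome_index, read, hm.MapperConfig())
        rr = hm.ReadRecord("b", read, None)
        sam = tmp_path / "b.sam"
        hm.write_sam([res], [rr], small_genome_index, sam)
        ok50 = hm.evaluate_accuracy(sam, {"b": hm.TruthRecord("b", "chr1", 3050, "+")})
        bad51 = hm.evaluate_accuracy(sam, {"b": hm.TruthRecord("b", "chr1", 3051, "+")})
        assert ok50["correct"] == 100.0 and bad51["correct"] == 0.0

    def test_wrong_strand_is_incorrect(self, small_genome_index, tmp_path, small_genome):
        read = small_genome[3000:3060]
        (res,) = hm.map_read(small_genome_index, read, hm.MapperConfig())
        rr = hm.ReadRecord("s", read, None)
        sam = tmp_path / "s.sam"
        hm.write_sam([res], [rr], small_genome_index, sam)
        metrics = hm.evaluate_accuracy(sam, {"s": hm.TruthRecord("s", "chr1", 3000, "-")})
        assert metrics["correct"] == 0.0

    def test_missing_truth_read_errors(self, mapped_batch):
        *_, sam = mapped_batch
        with pytest.raises(EvaluationError):
            hm.evaluate_accuracy(sam, {"nope": hm.TruthRecord("nope", "chr1", 0, "+")})


class TestSummary:
    def test_percentages_and_json_round_trip(self, mapped_batch):
        reads, _, results, summary, _ = mapped_batch
        assert summary["total_reads"] == 60
        assert summary["aligned_pct"] == pytest.approx(
            100.0 * summary["aligned"] / 60
        )
        parsed = json.loads(json.dumps(summary))
        assert parsed["mapq_histogram"] == summary["mapq_histogram"]
        assert len(summary["mean_base_quality_by_position"]) == 100

    def test_empty_input_does_not_crash(self):
        summary = hm.summarize_run([], [])
        assert summary["total_reads"] == 0 and summary["aligned_pct"] == 0.0
        assert "total reads   : 0" in hm.mapper.render_summary(summary)


class TestStrandSymmetryProperty:
    def test_mirrored_placements_same_scores(self, small_genome_index, small_genome):
        rng = np.random.default_rng(55)
        cfg = hm.MapperConfig()
        for _ in range(10):
            start = int(rng.integers(0, len(small_genome) - 80))
            read = small_genome[start : start + 80]
            (f,) = hm.map_read(small_genome_index, read, cfg)
            (r,) = hm.map_read(small_genome_index, hm.reverse_complement(read), cfg)
            assert f.ref_pos == r.ref_pos and f.score == r.score
            assert {f.strand, r.strand} == {"+", "-"}
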