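"""Read classification, sample quantification and the SAM counting path."""

import numpy as np
import pytest

from splicesig import (AlignmentParams, DetectionThresholds, ReadSimConfig,
                       align_to_target, classify_read, count_from_alignments,
                       quantify_sample, simulate_reads)
from splicesig.junction import ReadAlignment, write_alignments_sam


def _spliced_read(target, left=15, right=15):
    js = target.junction_start
    return target.spliced_sequence[js - left: js + right]


def _unspliced_read(target, start=120, length=50):
    return target.sequence[start:start + length]


class TestClassifyRead:
    def test_error_free_spliced_read_is_spliced(self, target):
        aln = align_to_target(_spliced_read(target), None, target)
        assert classify_read(aln, target) == "spliced"

    def test_read_entirely_upstream_is_uninformative(self, target):
        read = target.sequence[20:70]
        aln = align_to_target(read, None, target)
        assert classify_read(aln, target) == "uninformative"

    def test_junction_spanning_match_is_unspliced(self, target):
        aln = align_to_target(_unspliced_read(target), None, target)
        assert classify_read(aln, target) == "unspliced"

    def test_unmapped_read_is_uninformative(self, target):
        rng = np.random.default_rng(3)
        read = "".join(rng.choice(list("ACGT"), size=50))
        aln = align_to_target(read, None, target)
        assert classify_read(aln, target) == "uninformative"

    def test_low_quality_junction_base_is_uninformative(self, target):
        read = _unspliced_read(target)
        qual = list(chr(33 + 30) * len(read))
        # the base aligned at junction_start gets Phred 5 < 13
        qual[target.junction_start - 120] = chr(33 + 5)
        aln = align_to_target(read, "".join(qual), target)
        assert classify_read(aln, target) == "uninformative"

    def test_short_anchor_spliced_read_is_not_called(self, target):
        # only 4 bases on the right of the deletion: below min_anchor
        read = _spliced_read(target, left=40, right=4)
        aln = align_to_target(read, None, target)
        assert classify_read(aln, target) != "spliced"

    def test_simulated_truth_labels_recovered_without_errors(self, target):
        cfg = ReadSimConfig(true_spliced_fraction=0.4, n_reads=1200,
                            read_length=50, error_rate=0.0, seed=21,
                            junction_spanning_only=True)
        sim = simulate_reads(target, cfg)
        for (rid, seq, qual), row in zip(sim.reads,
                                         sim.truth.itertuples(index=False)):
            aln = align_to_target(seq, qual, target, read_id=rid)
            assert classify_read(aln, target) == row.origin


class TestQuantifySample:
    def test_unspliced_only_sample_is_zero_percent(self, target):
        reads = [(f"r{i}", _unspliced_read(target), None) for i in range(100)]
        jc = quantify_sample(reads, target)
        assert jc.spliced_percent == 0.0
        assert not jc.pass_threshold
        assert jc.unspliced_count == 100

    @pytest.mark.parametrize("n_spliced,expect_pass", [(2, False), (3, True)])
    def test_min_supporting_reads_boundary(self, target, n_spliced, expect_pass):
        reads = [(f"s{i}", _spliced_read(target), None) for i in range(n_spliced)]
        reads += [(f"u{i}", _unspliced_read(target), None)
                  for i in range(100 - n_spliced)]
        jc = quantify_sample(reads, target)
        assert jc.spliced_count == n_spliced
        assert jc.spliced_percent == pytest.approx(n_spliced)
        assert jc.pass_threshold is expect_pass

    def test_empty_stream_yields_undefined_percentage(self, target):
        jc = quantify_sample([], target)
        assert (jc.spliced_count, jc.unspliced_count, jc.uninformative_count) == (0, 0, 0)
        assert jc.spliced_percent is None
        assert not jc.pass_threshold

    def test_counts_are_read_order_invariant(self, target):
        reads = [(f"s{i}", _spliced_read(target), None) for i in range(5)]
        reads += [(f"u{i}", _unspliced_read(target, start=110 + i), None)
                  for i in range(10)]
        fwd = quantify_sample(reads, target)
        rev = quantify_sample(list(reversed(reads)), target)
        assert (fwd.spliced_count, fwd.unspliced_count) == \
            (rev.spliced_count, rev.unspliced_count)

    def test_conservation_of_read_counts(self, target):
        cfg = ReadSimConfig(true_spliced_fraction=0.3, n_reads=300,
                            read_length=50, error_rate=0.01, seed=9)
        sim = simulate_reads(target, cfg)
        jc = quantify_sample(sim.reads, target)
        assert jc.spliced_count + jc.unspliced_count + jc.uninformative_count == 300

    def test_max_depth_truncates_informative_reads(self, target):
        th = DetectionThresholds(max_depth=10)
        reads = [(f"u{i}", _unspliced_read(target), None) for i in range(25)]
        jc = quantify_sample(reads, target, thresholds=th)
        assert jc.spliced_count + jc.unspliced_count == 10

    def test_fraction_recovery_within_binomial_bound(self, target):
        f, n = 0.30, 2000
        cfg = ReadSimConfig(true_spliced_fraction=f, n_reads=n,
                            read_length=50, error_rate=0.005, seed=42,
                            junction_spanning_only=True)
        sim = simulate_reads(target, cfg)
        jc = quantify_sample(sim.reads, target)
        bound = 3 * 100 * np.sqrt(f * (1 - f) / n)
        assert abs(jc.spliced_percent - 100 * f) <= bound


class TestCountFromAlignments:
    def test_matches_only_sam_stream_is_zero_percent(self, target, tmp_path):
        alns = [align_to_target(_unspliced_read(target, 115 + i), None, target,
                                read_id=f"u{i}") for i in range(6)]
        path = tmp_path / "u.sam"
        write_alignments_sam(alns, target, str(path))
        jc = count_from_alignments(path, target)
        assert jc.spliced_percent == 0.0
        assert jc.unspliced_count == 6

    def test_round_trip_agrees_with_direct_quantification(self, target, tmp_path):
        cfg = ReadSimConfig(true_spliced_fraction=0.4, n_reads=200,
                            read_length=50, error_rate=0.005, seed=77,
                            junction_spanning_only=True)
        sim = simulate_reads(target, cfg)
        direct = quantify_sample(sim.reads, target)
        alns = [align_to_target(seq, qual, target, read_id=rid)
                for rid, seq, qual in sim.reads]
        path = tmp_path / "roundtrip.sam"
        write_alignments_sam(alns, target, str(path))
        via_sam = count_from_alignments(path, target)
        assert (via_sam.spliced_count, via_sam.unspliced_count,
                via_sam.uninformative_count) == \
            (direct.spliced_count, direct.unspliced_count,
             direct.uninformative_count)
        assert via_sam.spliced_percent == direct.spliced_percent

    def test_hand_written_toy_sam_gives_37_5_percent(self, target, tmp_path):
        """3 reads with the 26-nt deletion + 5 spanning matches -> 37.5%."""
        js, ex = target.junction_start, target.excision_length
        qual30 = chr(33 + 30)
        lines = [f"@HD\tVN:1.6", f"@SQ\tSN:{target.transcript_id}\tLN:{len(target.sequence)}"]
        for i in range(3):
            seq = target.spliced_sequence[js - 15: js + 15]
            pos = js - 15 + 1  # SAM is 1-based
            lines.append("\t".join([
                f"sp{i}", "0", target.transcript_id, str(pos), "60",
                "15M26D15M", "*", "0", "0", seq, qual30 * len(seq)]))
        for i in range(5):
            start = 120 + i
            seq = target.sequence[start:start + 50]
            lines.append("\t".join([
                f"un{i}", "0", target.transcript_id, str(start + 1), "60",
                "50M", "*", "0", "0", seq, qual30 * len(seq)]))
        path = tmp_path / "toy.sam"
        path.write_text("\n".join(lines) + "\n")
        jc = count_from_alignments(path, target)
        assert (jc.spliced_count, jc.unspliced_count) == (3, 5)
        assert jc.spliced_percent == pytest.approx(37.5)
        assert jc.pass_threshold

    def test_reference_name_mismatch_is_an_input_error(self, target, tmp_path):
        lines = ["@HD\tVN:1.6", "@SQ\tSN:OTHER\tLN:500",
                 "\t".join(["r0", "0", "OTHER", "10", "60", "20M", "*", "0",
                            "0", "A" * 20, "I" * 20])]
        path = tmp_path / "bad.sam"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="does not match"):
            count_from_alignments(path, target)

    def test_monotone_recovery_across_true_fractions(self, target):
        """Higher true spliced fractions yield higher estimates."""
        estimates = []
        for k, f in enumerate((0.2, 0.5, 0.8)):
            cfg = ReadSimConfig(true_spliced_fraction=f, n_reads=600,
                                read_length=50, error_rate=0.005,
                                seed=900 + k, junction_spanning_only=True)
            sim = simulate_reads(target, cfg)
            estimates.append(quantify_sample(sim.reads, target).spliced_percent)
        assert estimates == sorted(estimates)
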