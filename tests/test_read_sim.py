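"""Read simulation: sampling geometry, error calibration, truth fidelity."""

import math

import numpy as np
import pytest

from mgsim.genome_store import make_synthetic_genome
from mgsim.read_sim import (
    LongReadParams,
    ShortReadParams,
    allocate_reads_per_contig,
    quality_ramp,
    reads_for_depth,
    reconstruct_read,
    revcomp,
    simulate_long,
    simulate_short,
    truncated_lognormal_mean,
)


@pytest.fixture(scope="module")
def contig_10k():
    return make_synthetic_genome(10_000, seed=3, genome_id="gA").contigs[0]


class TestAllocation:
    def test_single_contig_gets_everything(self):
        assert allocate_reads_per_contig(10, [1000]) == [10]

    def test_proportional_when_shares_integral(self):
        assert allocate_reads_per_contig(10, [600, 400]) == [6, 4]

    def test_largest_remainder_breaks_the_tie(self):
        # floors (3,2,1) leave one unit; largest fraction (0.5) is contig 0
        assert allocate_reads_per_contig(7, [500, 300, 200]) == [4, 2, 1]

    def test_empty_contig_list_rejected(self):
        with pytest.raises(ValueError):
            allocate_reads_per_contig(5, [])


class TestShortReads:
    def test_error_free_reads_are_exact_substrings(self, contig_10k):
        params = ShortReadParams(read_length=100, sub_rate=0.0)
        frags = simulate_short(contig_10k, 200, params, seed=1)
        assert len(frags) == 200
        seen_minus = False
        for (read,) in frags:
            t = read.truth
            ref = contig_10k.sequence[t.start : t.start + 100]
            expected = revcomp(ref) if t.strand == "-" else ref
            assert read.sequence == expected
            assert t.edit_ops == [("match", 100, "")]
            seen_minus |= t.strand == "-"
        assert seen_minus  # both strands occur

    def test_depth_arithmetic(self, contig_10k):
        params = ShortReadParams(read_length=100, sub_rate=0.0)
        frags = simulate_short(contig_10k, 10, params, seed=1)
        total = sum(len(r.sequence) for (r,) in frags)
        assert total == 1000

    def test_substitution_rate_calibration(self, contig_10k):
        """10% substitution rate over >= 10 kb lands in the 3-sigma band."""
        rate = 0.1
        params = ShortReadParams(read_length=100, sub_rate=rate)
        frags = simulate_short(contig_10k, 200, params, seed=5)
        bases = sum(len(r.sequence) for (r,) in frags)
        subs = sum(
            l for (r,) in frags for op, l, _ in r.truth.edit_ops if op == "sub"
        )
        assert bases >= 10_000
        sigma = math.sqrt(bases * rate * (1 - rate))
        assert abs(subs - bases * rate) <= 3 * sigma
        assert 0.09 <= subs / bases <= 0.11

    def test_truth_reconstruction_with_errors(self, contig_10k):
        params = ShortReadParams(read_length=80, sub_rate=0.05)
        for (read,) in simulate_short(contig_10k, 100, params, seed=8):
            assert reconstruct_read(contig_10k.sequence, read.truth) == read.sequence

    def test_too_short_contig_yields_empty_stream(self, contig_10k):
        from mgsim.genome_store import Contig

        short = Contig("tiny", "ACGTACGT")
        params = ShortReadParams(read_length=100)
        assert simulate_short(short, 10, params, seed=0) == []

    def test_seed_stability_and_sensitivity(self, contig_10k):
        params = ShortReadParams(read_length=100, sub_rate=0.01)
        a = simulate_short(contig_10k, 50, params, seed=3)
        b = simulate_short(contig_10k, 50, params, seed=3)
        c = simulate_short(contig_10k, 50, params, seed=4)
        assert [r.sequence for (r,) in a] == [r.sequence for (r,) in b]
        assert [r.sequence for (r,) in a] != [r.sequence for (r,) in c]

    def test_quality_ramp_is_linear_and_phred33(self):
        q = quality_ramp(5, 40, 20)
        assert [ord(c) - 33 for c in q] == [40, 35, 30, 25, 20]


class TestPairedReads:
    PARAMS = ShortReadParams(
        read_length=100, paired=True, insert_mean=300, insert_sd=20, sub_rate=0.0
    )

    def test_pair_geometry_fr_orientation(self, contig_10k):
        frags = simulate_short(contig_10k, 200, self.PARAMS, seed=2)
        assert len(frags) == 100  # reads count individually, two per fragment
        for mate1, mate2 in frags:
            t1, t2 = mate1.truth, mate2.truth
            assert {t1.mate, t2.mate} == {1, 2}
            left, right = (t1, t2) if t1.start <= t2.start else (t2, t1)
            assert left.strand == "+" and right.strand == "-"
            insert = right.start + 100 - left.start
            assert 100 <= insert <= contig_10k.length
            # innie: mate2-side read is the reverse complement of its locus
            for read in (mate1, mate2):
                ref = contig_10k.sequence[read.truth.start : read.truth.start + 100]
                expected = revcomp(ref) if read.truth.strand == "-" else ref
                assert read.sequence == expected

    def test_insert_lengths_track_the_normal(self, contig_10k):
        frags = simulate_short(contig_10k, 2000, self.PARAMS, seed=9)
        inserts = []
        for mate1, mate2 in frags:
            s = sorted([mate1.truth.start, mate2.truth.start])
            inserts.append(s[1] + 100 - s[0])
        assert abs(np.mean(inserts) - 300) < 3 * 20 / math.sqrt(len(inserts)) + 1

    def test_truth_reconstruction_paired(self, contig_10k):
        params = ShortReadParams(
            read_length=60, paired=True, insert_mean=200, insert_sd=15, sub_rate=0.03
        )
        for frag in simulate_short(contig_10k, 100, params, seed=4):
            for read in frag:
                assert reconstruct_read(contig_10k.sequence, read.truth) == read.sequence


class TestLongReads:
    def test_error_free_long_reads_are_substrings(self, contig_10k):
        params = LongReadParams(
            length_log_mean=7.0, length_log_sd=0.3, sub_rate=0, ins_rate=0, del_rate=0
        )
        frags = simulate_long(contig_10k, 50, params, seed=1)
        for (read,) in frags:
            t = read.truth
            assert t.edit_ops == [("match", t.aligned_length, "")]
            ref = contig_10k.sequence[t.start : t.start + t.aligned_length]
            assert read.sequence == (revcomp(ref) if t.strand == "-" else ref)

    def test_deletion_rate_calibration(self, contig_10k):
        """del_rate 0.1: deleted fraction of reference-consumed bases in 3 sigma."""
        params = LongReadParams(
            length_log_mean=7.6, length_log_sd=0.2, sub_rate=0, ins_rate=0, del_rate=0.1
        )
        frags = simulate_long(contig_10k, 60, params, seed=6)
        ref_bases = sum(r.truth.aligned_length for (r,) in frags)
        dels = sum(l for (r,) in frags for op, l, _ in r.truth.edit_ops if op == "del")
        assert ref_bases >= 100_000
        sigma = math.sqrt(ref_bases * 0.1 * 0.9)
        assert abs(dels - 0.1 * ref_bases) <= 3 * sigma

    def test_length_log_moment_recovery(self):
        """5000 error-free draws recover (log_mean, log_sd) = (8, 0.4) within 5%."""
        contig = make_synthetic_genome(120_000, seed=12).contigs[0]
        params = LongReadParams(
            length_log_mean=8.0, length_log_sd=0.4, sub_rate=0, ins_rate=0, del_rate=0
        )
        frags = simulate_long(contig, 5000, params, seed=13)
        logs = np.log([r.truth.aligned_length for (r,) in frags])
        assert abs(logs.mean() - 8.0) / 8.0 < 0.05
        assert abs(logs.std(ddof=1) - 0.4) / 0.4 < 0.05

    def test_truth_reconstruction_with_indels(self, contig_10k):
        params = LongReadParams(
            length_log_mean=6.5, length_log_sd=0.3, sub_rate=0.02, ins_rate=0.02,
            del_rate=0.02,
        )
        for (read,) in simulate_long(contig_10k, 40, params, seed=3):
            assert reconstruct_read(contig_10k.sequence, read.truth) == read.sequence

    def test_rates_summing_to_one_rejected(self):
        with pytest.raises(ValueError):
            LongReadParams(sub_rate=0.5, ins_rate=0.3, del_rate=0.2)

    def test_short_contig_skipped(self):
        from mgsim.genome_store import Contig

        tiny = Contig("tiny", "ACGT" * 10)
        params = LongReadParams(min_length=100)
        assert simulate_long(tiny, 5, params, seed=0) == []


class TestReadsForDepth:
    def test_single_end_arithmetic(self):
        params = ShortReadParams(read_length=100)
        assert reads_for_depth(1.0, 1000, params) == 10
        assert reads_for_depth(0.0, 1000, params) == 0

    def test_paired_count_is_even(self):
        params = ShortReadParams(read_length=100, paired=True, insert_mean=300)
        assert reads_for_depth(10.0, 100_000, params) == 10_000
        assert reads_for_depth(1.0, 250, params) == 2  # 2.5 reads floored to even

    def test_long_footprint_is_truncated_lognormal_mean(self):
        params = LongReadParams(length_log_mean=8.0, length_log_sd=0.4, min_length=100)
        fp = truncated_lognormal_mean(8.0, 0.4, 100)
        # mild truncation: mean close to the untruncated lognormal mean
        assert fp == pytest.approx(math.exp(8.0 + 0.4**2 / 2), rel=1e-3)
        assert reads_for_depth(2.0, 1_000_000, params) == round(2.0 * 1_000_000 / fp)

    def test_truncation_raises_the_mean(self):
        # cutting the left tail at the median must raise the mean
        assert truncated_lognormal_mean(8.0, 0.5, math.exp(8.0)) > math.exp(
            8.0 + 0.5**2 / 2
        )


class TestUniformity:
    def test_window_coverage_consistent_with_poisson(self):
        """Depth 20 on 100 kb: no 10 kb window deviates beyond 5 sigma."""
        genome = make_synthetic_genome(100_000, seed=21, genome_id="gU")
        contig = genome.contigs[0]
        params = ShortReadParams(read_length=100, sub_rate=0.0)
        n_reads = reads_for_depth(20.0, 100_000, params)
        frags = simulate_short(contig, n_reads, params, seed=22)
        window = 10_000
        cover = np.zeros(100_000 // window)
        for (read,) in frags:
            cover[read.truth.start // window] += 100
        depth_per_window = cover / window
        sigma = math.sqrt(20.0 / (window / 100))  # Poisson on read counts
        assert np.all(np.abs(depth_per_window - 20.0) <= 5 * sigma)
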