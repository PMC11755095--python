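"""Unit conversion, abundance distributions, apportionment, replicates."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mgsim.community_design import (
    CommunityDesign,
    CommunityEntry,
    DesignError,
    draw_even,
    draw_lognormal,
    expand_replicates,
    largest_remainder,
    lognormal_raw,
    read_community_table,
    to_coverage,
)


def entries(unit, *quantities):
    return [
        CommunityEntry(genome_id=f"g{i}", quantity=q, unit=unit)
        for i, q in enumerate(quantities)
    ]


class TestDistributions:
    def test_even_fractions(self):
        assert draw_even(["a", "b", "c", "d"]) == [0.25] * 4
        assert draw_even(["a"]) == [1.0]
        assert abs(sum(draw_even(list("abc"))) - 1.0) < 1e-12

    def test_even_empty_rejected(self):
        with pytest.raises(DesignError):
            draw_even([])

    def test_lognormal_deterministic_and_normalized(self):
        a = draw_lognormal(list("abcde"), seed=42)
        b = draw_lognormal(list("abcde"), seed=42)
        assert a == b
        assert abs(sum(a) - 1.0) < 1e-12
        assert draw_lognormal(list("abcde"), seed=43) != a

    def test_lognormal_sigma_must_be_positive(self):
        with pytest.raises(DesignError):
            draw_lognormal(["a"], sigma=0.0)

    def test_sigma_to_zero_limit_approaches_even(self):
        fracs = draw_lognormal(list("abcd"), mu=1.0, sigma=1e-9, seed=1)
        assert np.allclose(fracs, 0.25, atol=1e-8)

    def test_log_moment_recovery(self):
        """Raw draws recover (mu, sigma) = (1, 2) from 10,000 samples."""
        raw = lognormal_raw(10_000, 1.0, 2.0, np.random.default_rng(7))
        logs = np.log(raw)
        assert abs(logs.mean() - 1.0) / 1.0 < 0.05
        assert abs(logs.std(ddof=1) - 2.0) / 2.0 < 0.05


class TestLargestRemainder:
    def test_exact_integral_shares(self):
        assert largest_remainder([600, 400], 10) == [6, 4]

    def test_remainder_goes_to_largest_fraction(self):
        assert largest_remainder([500, 300, 200], 7) == [4, 2, 1]

    @given(
        weights=st.lists(st.floats(0.01, 1000), min_size=1, max_size=20),
        total=st.integers(0, 10_000),
    )
    def test_sum_is_exact_and_near_proportional(self, weights, total):
        alloc = largest_remainder(weights, total)
        assert sum(alloc) == total
        s = sum(weights)
        for w, a in zip(weights, alloc):
            assert abs(a - w / s * total) < 1.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DesignError):
            largest_remainder([0, 0], 5)


class TestToCoverage:
    LENGTHS = {"g0": 100_000, "g1": 100_000}

    def test_coverage_unit_is_identity(self):
        d = CommunityDesign("s", entries("coverage", 5.0, 2.5))
        plan = to_coverage(d, self.LENGTHS, read_footprint=100)
        assert plan.depth("g0") == 5.0
        assert plan.depth("g1") == 2.5

    def test_reads_unit(self):
        d = CommunityDesign("s", [CommunityEntry("g0", 2000, "reads")])
        plan = to_coverage(d, {"g0": 100_000}, read_footprint=100)
        assert plan.depth("g0") == pytest.approx(2.0)
        assert plan.genomes[0].expected_reads == 2000

    def test_bases_unit(self):
        d = CommunityDesign("s", [CommunityEntry("g0", 50_000, "bases")])
        plan = to_coverage(d, {"g0": 100_000}, read_footprint=100)
        assert plan.depth("g0") == pytest.approx(0.5)

    def test_seq_abundance_allocates_reads_by_fraction(self):
        d = CommunityDesign("s", entries("seq_abundance", 1.0, 3.0), total_reads=1000)
        plan = to_coverage(d, self.LENGTHS, read_footprint=100)
        assert [g.expected_reads for g in plan.genomes] == [250, 750]
        assert plan.total_reads == 1000

    def test_seq_abundance_requires_total_reads(self):
        d = CommunityDesign("s", entries("seq_abundance", 1.0, 1.0))
        with pytest.raises(DesignError, match="total_reads"):
            to_coverage(d, self.LENGTHS, read_footprint=100)

    def test_tax_abundance_hand_example(self):
        """Equal taxonomic abundance on 1 Mb + 2 Mb with 3 Mb budget:
        C_tot = 3e6 / 1.5e6 = 2, both depths 1.0, read shares 1/3 vs 2/3."""
        lengths = {"g0": 1_000_000, "g1": 2_000_000}
        d = CommunityDesign(
            "s", entries("tax_abundance", 0.5, 0.5), total_bases=3_000_000
        )
        plan = to_coverage(d, lengths, read_footprint=100)
        assert plan.depth("g0") == pytest.approx(1.0)
        assert plan.depth("g1") == pytest.approx(1.0)
        reads = [g.expected_reads for g in plan.genomes]
        assert reads[0] / sum(reads) == pytest.approx(1 / 3, abs=1e-4)
        assert sum(g.expected_bases for g in plan.genomes) == 3_000_000

    def test_tax_abundance_requires_a_budget(self):
        d = CommunityDesign("s", entries("tax_abundance", 0.5, 0.5))
        with pytest.raises(DesignError):
            to_coverage(d, self.LENGTHS, read_footprint=100)

    def test_missing_genome_length_is_lookup_error(self):
        d = CommunityDesign("s", [CommunityEntry("missing", 1.0, "coverage")])
        with pytest.raises(KeyError):
            to_coverage(d, self.LENGTHS, read_footprint=100)

    def test_all_zero_quantities_rejected(self):
        d = CommunityDesign("s", entries("coverage", 0.0, 0.0))
        with pytest.raises(DesignError):
            to_coverage(d, self.LENGTHS, read_footprint=100)

    def test_mixed_abundance_units_rejected(self):
        with pytest.raises(DesignError):
            CommunityDesign(
                "s",
                [
                    CommunityEntry("g0", 0.5, "tax_abundance"),
                    CommunityEntry("g1", 5.0, "coverage"),
                ],
            )

    def test_paired_counts_are_even_and_total_exact(self):
        d = CommunityDesign("s", entries("seq_abundance", 1, 1, 1), total_reads=1000)
        plan = to_coverage(
            d, {"g0": 10_000, "g1": 10_000, "g2": 10_000}, 100, paired=True
        )
        for g in plan.genomes:
            assert g.expected_reads % 2 == 0
        assert plan.total_reads == 1000


class TestConservation:
    @given(
        fracs=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8),
        lengths=st.lists(st.integers(10_000, 500_000), min_size=2, max_size=8),
    )
    def test_tax_abundance_base_budget_conserved(self, fracs, lengths):
        """Sum of depth_i * L_i equals the requested base budget."""
        n = min(len(fracs), len(lengths))
        fracs, lengths = fracs[:n], lengths[:n]
        lmap = {f"g{i}": l for i, l in enumerate(lengths)}
        d = CommunityDesign("s", entries("tax_abundance", *fracs), total_bases=5_000_000)
        plan = to_coverage(d, lmap, read_footprint=100)
        implied = sum(g.coverage_depth * lmap[g.genome_id] for g in plan.genomes)
        assert implied == pytest.approx(5_000_000, rel=1e-9)

    @given(fracs=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8))
    def test_tax_abundance_depth_ratios_match_input(self, fracs):
        lmap = {f"g{i}": 50_000 + 10_000 * i for i in range(len(fracs))}
        d = CommunityDesign("s", entries("tax_abundance", *fracs), total_bases=10**6)
        plan = to_coverage(d, lmap, read_footprint=100)
        depths = np.array([g.coverage_depth for g in plan.genomes])
        expect = np.array(fracs) / sum(fracs)
        assert np.allclose(depths / depths.sum(), expect, atol=1e-9)

    @given(fracs=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8))
    def test_seq_abundance_read_shares_match_input(self, fracs):
        lmap = {f"g{i}": 100_000 for i in range(len(fracs))}
        d = CommunityDesign("s", entries("seq_abundance", *fracs), total_reads=100_000)
        plan = to_coverage(d, lmap, read_footprint=100)
        reads = [g.expected_reads for g in plan.genomes]
        expect = np.array(fracs) / sum(fracs)
        assert sum(reads) == 100_000
        for r, e in zip(reads, expect):
            assert abs(r - e * 100_000) < 1.0  # largest-remainder error bound


class TestReplicates:
    def test_zero_sd_identical_depths_distinct_seeds(self):
        d = CommunityDesign(
            "s", entries("coverage", 2.0, 4.0), n_replicates=3, seed=9
        )
        plans = expand_replicates(d, {"g0": 10_000, "g1": 10_000}, 100)
        assert len(plans) == 3
        depths = [[g.coverage_depth for g in p.genomes] for p in plans]
        assert depths[0] == depths[1] == depths[2] == [2.0, 4.0]
        seeds = [p.seed for p in plans]
        assert len(set(seeds)) == 3

    def test_same_master_seed_reproduces_child_seeds(self):
        d = CommunityDesign("s", entries("coverage", 1.0), n_replicates=4, seed=123)
        seeds_a = [p.seed for p in expand_replicates(d, {"g0": 1000}, 100)]
        seeds_b = [p.seed for p in expand_replicates(d, {"g0": 1000}, 100)]
        assert seeds_a == seeds_b

    def test_perturbation_never_goes_negative(self):
        """SD of 10x the quantity: every perturbed depth stays >= 0."""
        d = CommunityDesign(
            "s",
            entries("coverage", 1.0, 0.5),
            n_replicates=1000,
            replicate_sd=10.0,
            seed=2,
        )
        plans = expand_replicates(d, {"g0": 1000, "g1": 1000}, 100)
        assert len(plans) == 1000
        assert all(g.coverage_depth >= 0 for p in plans for g in p.genomes)
        # perturbation actually moves quantities
        assert len({p.genomes[0].coverage_depth for p in plans}) > 10

    def test_replicate_count_validated(self):
        with pytest.raises(DesignError):
            CommunityDesign("s", entries("coverage", 1.0), n_replicates=0)


class TestCommunityTable:
    def test_round_trip_by_sample(self, tmp_path):
        p = tmp_path / "community.tsv"
        p.write_text(
            "sample_id\tgenome_id\tquantity\tunit\n"
            "s1\tg0\t0.5\ttax_abundance\n"
            "s1\tg1\t0.5\ttax_abundance\n"
            "s2\tg0\t3\tcoverage\n"
        )
        samples = read_community_table(p)
        assert set(samples) == {"s1", "s2"}
        assert len(samples["s1"]) == 2
        assert samples["s2"][0].unit == "coverage"

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tgenome_id\n s\tg\n")
        with pytest.raises(DesignError, match="missing columns"):
            read_community_table(p)
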