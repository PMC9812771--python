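"""Synthetic-cohort generator: reads, expansion, amplification, downsampling."""

import numpy as np
import pytest

from tropic.motifs import decode, detect_irr, repeat_purity
from tropic.profiling import scan_alignments
from tropic.sim import (
    RepeatSpec,
    SimulationConfig,
    downsample,
    expand_reference,
    merge_reads,
    oracle_align,
    random_reference,
    simulate_amplification,
    simulate_cohort,
    simulate_reads,
    write_fasta,
    write_fastq,
)


@pytest.fixture(scope="module")
def genome():
    return random_reference(
        60_000,
        [RepeatSpec("GAAA", 3, 100, position=20_000), RepeatSpec("AGC", 16, None)],
        seed=11,
    )


class TestConfig:
    def test_seed_is_mandatory_and_bounds_enforced(self):
        with pytest.raises(TypeError):
            SimulationConfig()
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, error_rate=0.3)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, coverage=0)


class TestExpandReference:
    def test_expansion_grows_sequence_and_shifts_downstream(self, genome):
        start0 = int(genome.truth.loc[0, "start"])
        assert genome.truth.loc[0, "end"] - start0 == 12  # 3 x GAAA
        expanded = expand_reference(genome, {0: 100})
        grown = (100 - 3) * 4
        assert len(expanded.sequences["chr1"]) == len(genome.sequences["chr1"]) + grown
        assert expanded.truth.loc[0, "end"] - expanded.truth.loc[0, "start"] == 400
        # downstream locus shifted by exactly the growth
        assert expanded.truth.loc[1, "start"] == genome.truth.loc[1, "start"] + grown
        # rewritten tract is perfect copies
        s, e = int(expanded.truth.loc[0, "start"]), int(expanded.truth.loc[0, "end"])
        assert decode(expanded.sequences["chr1"][s:e]) == "GAAA" * 100

    def test_identity_when_target_equals_reference(self, genome):
        same = expand_reference(genome, {0: 3})
        assert np.array_equal(same.sequences["chr1"], genome.sequences["chr1"])

    def test_coordinate_map_round_trip(self, genome):
        expanded = expand_reference(genome, {0: 100})
        # positions upstream unchanged, downstream shifted back by the growth
        assert expanded.to_ref("chr1", np.array([100]))[0] == 100
        tail = len(expanded.sequences["chr1"]) - 10
        assert expanded.to_ref("chr1", np.array([tail]))[0] == tail - 388

    def test_impure_reference_tract_rejected(self, genome):
        bad = genome.truth.copy()
        corrupted = random_reference(10_000, [RepeatSpec("GAAA", 5, None)], seed=1)
        s = int(corrupted.truth.loc[0, "start"])
        corrupted.sequences["chr1"][s : s + 10] = 1  # overwrite tract with C's
        with pytest.raises(ValueError, match="does not match"):
            expand_reference(corrupted, {0: 50})
        del bad


class TestSimulateReads:
    def test_pair_count_formula(self, genome):
        config = SimulationConfig(seed=3, coverage=30.0)
        reads = simulate_reads(genome, config)
        L = len(genome.sequences["chr1"])
        assert reads.n_pairs == round(30.0 * L / (2 * 100))

    def test_error_free_reads_are_genome_substrings(self, genome):
        config = SimulationConfig(seed=3, coverage=2.0, error_rate=0.0)
        reads = simulate_reads(genome, config)
        arr = genome.sequences["chr1"]
        for i in range(0, reads.n_pairs, 37):
            s1 = reads.start1[i]
            assert np.array_equal(reads.seq1[i], arr[s1 : s1 + 100])
            s2 = reads.start2[i]
            # mate 2 is sequenced from the reverse strand
            assert np.array_equal((3 - reads.seq2[i])[::-1], arr[s2 : s2 + 100])

    def test_error_rate_observed(self, genome):
        config = SimulationConfig(seed=3, coverage=5.0, error_rate=0.02)
        reads = simulate_reads(genome, config)
        arr = genome.sequences["chr1"]
        mism = total = 0
        for i in range(0, reads.n_pairs, 11):
            s1 = reads.start1[i]
            mism += int((reads.seq1[i] != arr[s1 : s1 + 100]).sum())
            total += 100
        assert mism / total == pytest.approx(0.02, rel=0.3)

    def test_same_seed_reproduces_byte_identical_reads(self, genome):
        config = SimulationConfig(seed=9, coverage=3.0)
        r1 = simulate_reads(genome, config)
        r2 = simulate_reads(genome, config)
        assert np.array_equal(r1.seq1, r2.seq1)
        assert np.array_equal(r1.seq2, r2.seq2)
        assert np.array_equal(r1.start1, r2.start1)


class TestOracleAlign:
    def test_mapq_model(self, genome):
        expanded = expand_reference(genome, {0: 100})
        config = SimulationConfig(seed=5, coverage=10.0, error_rate=0.0)
        reads = simulate_reads(expanded, config)
        aln = oracle_align(reads, expanded)
        s, e = int(expanded.truth.loc[0, "start"]), int(expanded.truth.loc[0, "end"])
        interior = (reads.start1 >= s) & (reads.start1 + 100 <= e)
        flank = (reads.start1 + 100 <= s) | (reads.start1 >= e + 400)
        assert np.all(aln.mapq1[interior] == 0)
        assert np.all(aln.mapq1[flank] == 60)

    def test_straddling_fragment_becomes_anchored_event(self, genome):
        expanded = expand_reference(genome, {0: 100})
        config = SimulationConfig(seed=5, coverage=30.0)
        aln = oracle_align(simulate_reads(expanded, config), expanded)
        prof = scan_alignments(aln, "t", role="tumour")
        assert len(prof.events) > 0
        # events localize near the reference-frame locus start
        ref_start = int(genome.truth.loc[0, "start"])
        assert all(abs(e.anchor_pos - ref_start) < 1200 for e in prof.events
                   if e.motif.sequence == "AAAG")


class TestAmplification:
    def test_copy_number_two_adds_nothing(self, genome):
        config = SimulationConfig(seed=6, coverage=30.0)
        rng = np.random.default_rng(0)
        assert simulate_amplification(genome, [1], 2, config, rng).n_pairs == 0

    def test_invalid_copy_number_rejected(self, genome):
        config = SimulationConfig(seed=6, coverage=30.0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_amplification(genome, [1], 1, config, rng)
        with pytest.raises(ValueError):
            simulate_amplification(genome, [1], 2.5, config, rng)

    def test_regional_depth_matches_copy_number(self, genome):
        config = SimulationConfig(seed=6, coverage=30.0)
        base = simulate_reads(genome, config, rng=np.random.default_rng(1))
        extra = simulate_amplification(genome, [1], 4, config, np.random.default_rng(2))
        merged = oracle_align(merge_reads(base, extra), genome)
        s, e = int(genome.truth.loc[1, "start"]), int(genome.truth.loc[1, "end"])
        cov = merged.coverage("chr1", s - 200, e + 200)
        assert cov == pytest.approx(60.0, rel=0.10)


class TestCohort:
    def test_zero_carrier_frequency_means_no_expansions(self, genome):
        config = SimulationConfig(seed=7, coverage=5.0, n_pairs=2, carrier_frequency=0.0)
        cohort = simulate_cohort(genome, config)
        assert not cohort.truth_pairs["carrier"].any()

    def test_truth_table_consistent_with_sequences(self, genome):
        config = SimulationConfig(seed=8, coverage=2.0, n_pairs=4, carrier_frequency=0.5)
        cohort = simulate_cohort(genome, config)
        t = cohort.truth_pairs
        assert set(t["pair_id"]) == {f"P{i:02d}" for i in range(4)}
        # binomial draw is recorded exactly and within the support
        assert 0 <= t["carrier"].sum() <= 4

    def test_no_designated_loci_rejected(self):
        plain = random_reference(20_000, [RepeatSpec("AGC", 10, None)], seed=1)
        with pytest.raises(ValueError, match="designated"):
            simulate_cohort(plain, SimulationConfig(seed=1, n_pairs=2))

    def test_same_config_reproduces_cohort(self, genome):
        config = SimulationConfig(seed=13, coverage=2.0, n_pairs=2)
        c1 = simulate_cohort(genome, config)
        c2 = simulate_cohort(genome, config)
        for sid in c1.alignments:
            assert np.array_equal(c1.alignments[sid].pos1, c2.alignments[sid].pos1)
            assert np.array_equal(c1.alignments[sid].seq1, c2.alignments[sid].seq1)


class TestDownsample:
    def test_fraction_one_is_identity(self, genome):
        config = SimulationConfig(seed=3, coverage=2.0)
        reads = simulate_reads(genome, config)
        kept = downsample(reads, 1.0, seed=0)
        assert kept.n_pairs == reads.n_pairs

    def test_binomial_bound_and_mates_kept_together(self, genome):
        config = SimulationConfig(seed=3, coverage=30.0)
        reads = simulate_reads(genome, config)
        kept = downsample(reads, 0.5, seed=1)
        n, k = reads.n_pairs, kept.n_pairs
        sd = (n * 0.25) ** 0.5
        assert abs(k - 0.5 * n) < 3.5 * sd
        assert len(kept.start1) == len(kept.start2) == k

    def test_seed_determinism_and_invalid_fraction(self, genome):
        config = SimulationConfig(seed=3, coverage=2.0)
        reads = simulate_reads(genome, config)
        assert np.array_equal(
            downsample(reads, 0.3, seed=5).start1, downsample(reads, 0.3, seed=5).start1
        )
        with pytest.raises(ValueError):
            downsample(reads, 0.0, seed=1)


def test_fasta_fastq_round_trip(tmp_path, genome):
    write_fasta(genome, tmp_path / "ref.fa")
    from tropic.sim import genome_from_fasta

    back = genome_from_fasta(tmp_path / "ref.fa")
    assert np.array_equal(back.sequences["chr1"], genome.sequences["chr1"])

    config = SimulationConfig(seed=3, coverage=0.5)
    reads = simulate_reads(genome, config)
    write_fastq(reads, tmp_path / "r1.fq", tmp_path / "r2.fq")
    lines = (tmp_path / "r1.fq").read_text().splitlines()
    assert len(lines) == 4 * reads.n_pairs
    assert lines[1] == decode(reads.seq1[0])


def test_reference_tracts_are_pure(genome):
    for idx, row in genome.truth.iterrows():
        s, e = int(row["start"]), int(row["end"])
        tract = decode(genome.sequences["chr1"][s:e])
        assert repeat_purity(tract, row["motif"]) >= 0.9
        if e - s >= 2 * len(row["motif"]):
            assert detect_irr(tract)[0] or e - s < 20
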