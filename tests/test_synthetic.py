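"""Generator invariants: divergence model, read simulation, mixing."""

import numpy as np
import pytest
from scipy import stats

from xenosort.io import write_fastq_pair
from xenosort.synthetic import (
    DivergenceSpec,
    SimParams,
    generate_genome_pair,
    mix_reads,
    random_expression_profile,
    revcomp,
    simulate_reads,
)


def _plain_pair(n_genes, gene_length, div, seed, **kw):
    """Pair without reference-incompleteness effects, for clean invariants."""
    kw.setdefault("host_missing_fraction", 0.0)
    kw.setdefault("graft_missing_fraction", 0.0)
    return generate_genome_pair(n_genes, gene_length, div, seed, **kw)


class TestGenomePair:
    def test_zero_divergence_identity(self):
        pair = _plain_pair(10, 2000, DivergenceSpec(0.0, 0.0, 1.0), seed=1)
        for a, b in zip(pair.graft_all.loci, pair.host_all.loci):
            assert a.seq == b.seq

    def test_snv_count_within_binomial_interval(self):
        n = 10_000
        pair = _plain_pair(
            1, n, DivergenceSpec(0.10, 0.0, 1.0), seed=7,
            flank_length=0, host_exon_extension=0, rate_heterogeneity_sd=0.0,
        )
        g, h = pair.graft_all.loci[0].seq, pair.host_all.loci[0].seq
        mismatches = sum(a != b for a, b in zip(g, h))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.10)
        assert lo <= mismatches <= hi

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_gene_count_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_genome_pair(bad, 1000, DivergenceSpec(), seed=1)

    def test_locus_counts_equal_and_intervals_valid(self):
        pair = generate_genome_pair(40, 800, DivergenceSpec(0.08, 0.01, 3.0), seed=3)
        assert len(pair.graft_all) == len(pair.host_all)
        for loc in pair.graft_all.loci + pair.host_all.loci:
            for s, e in loc.exons:
                assert 0 <= s < e <= len(loc.seq)

    def test_indel_changes_length_and_liftover_stays_inside(self):
        pair = _plain_pair(
            5, 3000, DivergenceSpec(0.0, 0.02, 3.0), seed=9,
            rate_heterogeneity_sd=0.0,
        )
        lengths_differ = any(
            len(a.seq) != len(b.seq)
            for a, b in zip(pair.graft_all.loci, pair.host_all.loci)
        )
        assert lengths_differ

    def test_determinism(self):
        p1 = generate_genome_pair(8, 500, DivergenceSpec(0.05, 0.01), seed=42)
        p2 = generate_genome_pair(8, 500, DivergenceSpec(0.05, 0.01), seed=42)
        assert all(a.seq == b.seq for a, b in zip(p1.host_all.loci, p2.host_all.loci))


class TestSimulateReads:
    @pytest.fixture(scope="class")
    def small(self):
        pair = _plain_pair(2, 2000, DivergenceSpec(0.0, 0.0), seed=5)
        profile = {g: 0.5 for g in pair.graft_transcribed}
        return pair, profile

    def test_error_free_reads_are_exact_substrings(self, small):
        pair, profile = small
        reads = simulate_reads(
            pair.graft_all, profile,
            SimParams(n_fragments=200, seed=1, base_error_rate=0.0),
        )
        for r in reads:
            locus = pair.graft_all[r.truth.gene_id]
            assert r.seq1 in locus.seq
            assert revcomp(r.seq2) in locus.seq

    def test_default_mates_are_100_bases(self, small):
        pair, profile = small
        reads = simulate_reads(
            pair.graft_all, profile, SimParams(n_fragments=10, seed=2)
        )
        assert all(len(r.seq1) == len(r.seq2) == 100 for r in reads)
        assert all(len(r.qual1) == len(r.qual2) == 100 for r in reads)

    def test_equal_abundance_passes_chi_square(self, small):
        pair, profile = small
        reads = simulate_reads(
            pair.graft_all, profile, SimParams(n_fragments=10_000, seed=3)
        )
        counts = {g: 0 for g in profile}
        for r in reads:
            counts[r.truth.gene_id] += 1
        observed = list(counts.values())
        assert stats.chisquare(observed).pvalue > 0.01

    def test_unknown_profile_gene_rejected(self, small):
        pair, _ = small
        with pytest.raises(ValueError, match="unannotated"):
            simulate_reads(
                pair.graft_all, {"nope": 1.0}, SimParams(n_fragments=1, seed=1)
            )

    def test_truth_interval_matches_locus(self, small):
        pair, profile = small
        reads = simulate_reads(
            pair.graft_all, profile,
            SimParams(n_fragments=50, seed=4, base_error_rate=0.0),
        )
        for r in reads:
            locus = pair.graft_all[r.truth.gene_id]
            assert locus.seq[r.truth.start : r.truth.start + 100] == r.seq1

    def test_identical_seeds_identical_fastq_bytes(self, small, tmp_path):
        pair, profile = small
        params = SimParams(n_fragments=100, seed=8)
        for tag in ("a", "b"):
            reads = simulate_reads(pair.graft_all, profile, params)
            write_fastq_pair(reads, tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()


class TestMixReads:
    @pytest.fixture(scope="class")
    def pools(self):
        pair = _plain_pair(2, 1500, DivergenceSpec(0.1, 0.0), seed=6)
        gp = {g: 1 / len(pair.graft_transcribed) for g in pair.graft_transcribed}
        hp = {g: 1 / len(pair.host_transcribed) for g in pair.host_transcribed}
        graft = simulate_reads(pair.graft_all, gp, SimParams(n_fragments=1200, seed=1))
        host = simulate_reads(pair.host_all, hp, SimParams(n_fragments=1200, seed=2),
                              species="host", id_prefix="host")
        return graft, host

    def test_zero_fraction_gives_host_only(self, pools):
        graft, host = pools
        mix = mix_reads(graft, host, 0.0, 500, seed=1)
        assert len(mix) == 500
        assert all(r.truth.species == "host" for r in mix)

    def test_half_fraction_exact_split(self, pools):
        graft, host = pools
        mix = mix_reads(graft, host, 0.5, 2000, seed=2)
        n_graft = sum(r.truth.species == "graft" for r in mix)
        assert n_graft == 1000 and len(mix) == 2000

    def test_round_half_even(self, pools):
        graft, host = pools
        # 10 * 0.05 = 0.5 rounds to 0 under round-half-even
        mix = mix_reads(graft, host, 0.05, 10, seed=3)
        assert sum(r.truth.species == "graft" for r in mix) == 0
        # 10 * 0.15 = 1.5 rounds to 2
        mix = mix_reads(graft, host, 0.15, 10, seed=3)
        assert sum(r.truth.species == "graft" for r in mix) == 2

    def test_requesting_more_than_available_fails(self, pools):
        graft, host = pools
        with pytest.raises(ValueError, match="graft"):
            mix_reads(graft, host, 1.0, 5000, seed=1)

    def test_shuffle_deterministic(self, pools):
        graft, host = pools
        a = [r.fid for r in mix_reads(graft, host, 0.3, 400, seed=9)]
        b = [r.fid for r in mix_reads(graft, host, 0.3, 400, seed=9)]
        assert a == b


def test_substitution_counts_match_binomial_across_seeds():
    """Divergence realizations across 20 seeds stay inside central CIs."""
    n, rate = 4000, 0.05
    inside = 0
    for seed in range(20):
        pair = _plain_pair(
            1, n, DivergenceSpec(rate, 0.0), seed=seed,
            flank_length=0, host_exon_extension=0, rate_heterogeneity_sd=0.0,
        )
        mm = sum(
            a != b for a, b in zip(pair.graft_all.loci[0].seq, pair.host_all.loci[0].seq)
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], n, rate)
        inside += lo <= mm <= hi
    assert inside >= 19


def test_expression_profile_normalized():
    prof = random_expression_profile([f"g{i}" for i in range(50)], seed=1)
    assert np.isclose(sum(prof.values()), 1.0)
    assert all(v >= 0 for v in prof.values())
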