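"""Species assignment rules, confusion accounting, false-positive anatomy."""

import math

import numpy as np
import pytest

from xenosort.align import AlignParams, DualAligner, FragmentHit
from xenosort.sort import (
    FalsePositiveAnatomy,
    assign_species,
    confusion,
    false_positive_anatomy,
    partition_reads,
    sort_readset,
)
from xenosort.synthetic import (
    DivergenceSpec,
    Genome,
    Locus,
    ReadRecord,
    SimParams,
    Truth,
    generate_genome_pair,
    mix_reads,
    simulate_reads,
)


def _hit(genome, score, locus="gene0000", start=0, end=200):
    return FragmentHit(genome=genome, locus_id=locus, start=start, end=end,
                       score=score, hits=(None, None))


class TestAssignSpecies:
    def test_graft_only_hit(self):
        call = assign_species("f", {"graft": _hit("graft", 0.95), "host": None})
        assert call.label == "graft" and call.margin is None

    def test_higher_score_wins(self):
        call = assign_species(
            "f", {"graft": _hit("graft", 0.95), "host": _hit("host", 0.92)}
        )
        assert call.label == "graft"
        assert call.margin == pytest.approx(0.03)

    def test_exact_tie_is_ambiguous(self):
        call = assign_species(
            "f", {"graft": _hit("graft", 0.95), "host": _hit("host", 0.95)}
        )
        assert call.label == "ambiguous"

    def test_no_hits_unaligned(self):
        assert assign_species("f", {"graft": None, "host": None}).label == "unaligned"

    def test_tie_tolerance_widens_ambiguity(self):
        scores = {"graft": _hit("graft", 0.95), "host": _hit("host", 0.94)}
        assert assign_species("f", scores).label == "graft"
        assert assign_species("f", scores, tie_tolerance=0.02).label == "ambiguous"


class TestSortReadset:
    def test_identical_genomes_almost_all_ambiguous(self):
        pair = generate_genome_pair(
            6, 1200, DivergenceSpec(0.0, 0.0), seed=2,
            host_missing_fraction=0.0, graft_missing_fraction=0.0,
            host_exon_extension=0,
        )
        profile = {g: 1 / 6 for g in pair.graft_transcribed}
        reads = simulate_reads(
            pair.graft_all, profile, SimParams(n_fragments=400, seed=3)
        )
        calls = sort_readset(reads, pair)
        frac_ambiguous = np.mean([c.label == "ambiguous" for c in calls])
        assert frac_ambiguous >= 0.99

    def test_high_divergence_error_free_is_perfect(self):
        pair = generate_genome_pair(
            20, 1200, DivergenceSpec(0.20, 0.005), seed=4,
            host_missing_fraction=0.0, graft_missing_fraction=0.0,
        )
        gp = {g: 1 / len(pair.graft_transcribed) for g in pair.graft_transcribed}
        hp = {g: 1 / len(pair.host_transcribed) for g in pair.host_transcribed}
        graft = simulate_reads(
            pair.graft_all, gp,
            SimParams(n_fragments=500, seed=5, base_error_rate=0.0),
        )
        host = simulate_reads(
            pair.host_all, hp,
            SimParams(n_fragments=500, seed=6, base_error_rate=0.0),
            species="host", id_prefix="host",
        )
        mixture = mix_reads(graft, host, 0.5, 1000, seed=7)
        calls = sort_readset(mixture, pair)
        rep = confusion(calls, mixture)
        assert rep.counts.loc["host", "graft"] == 0
        assert rep.counts.loc["graft", "host"] == 0

    def test_label_partition_and_fastq_split(self, pair8, aligner8, pools8):
        graft, host = pools8
        mixture = mix_reads(graft, host, 0.25, 800, seed=8)
        calls = sort_readset(mixture, aligner8)
        parts = partition_reads(mixture, calls)
        assert sum(len(v) for v in parts.values()) == len(mixture)
        fids = {r.fid for part in parts.values() for r in part}
        assert fids == {r.fid for r in mixture}

    def test_determinism(self, pair8, pools8):
        graft, host = pools8
        mixture = mix_reads(graft, host, 0.1, 300, seed=9)
        a = [c.label for c in sort_readset(mixture, pair8)]
        b = [c.label for c in sort_readset(mixture, pair8)]
        assert a == b


class TestConfusion:
    def _frag(self, fid, species):
        return ReadRecord(fid, "A" * 60, "I" * 60, "A" * 60, "I" * 60,
                          truth=Truth(species, "g", 0, 120))

    def test_all_correct(self):
        frags = [self._frag(f"f{i}", "graft") for i in range(5)]
        calls = [assign_species(r.fid, {"graft": _hit("graft", 1.0), "host": None})
                 for r in frags]
        rep = confusion(calls, frags)
        assert rep.false_to_host == 0.0
        assert math.isnan(rep.false_to_graft)  # no host-truth fragments

    def test_hand_built_rates(self):
        # 8 correct host, 1 falsely to graft, 1 ambiguous
        frags = [self._frag(f"f{i}", "host") for i in range(10)]
        calls = []
        for i, r in enumerate(frags):
            if i == 0:
                scores = {"graft": _hit("graft", 0.99), "host": None}
            elif i == 1:
                scores = {"graft": _hit("graft", 0.95), "host": _hit("host", 0.95)}
            else:
                scores = {"graft": None, "host": _hit("host", 0.99)}
            calls.append(assign_species(r.fid, scores))
        rep = confusion(calls, frags)
        assert rep.false_to_graft == pytest.approx(0.1)
        assert rep.ambiguous_rate("host") == pytest.approx(0.1)
        assert rep.counts.loc["host"].sum() == 10

    def test_empty_calls_give_nan_rates(self):
        rep = confusion([], [])
        assert math.isnan(rep.false_to_graft)
        assert math.isnan(rep.ambiguous_rate("host"))

    def test_missing_truth_rejected(self):
        frag = ReadRecord("f", "A" * 60, "I" * 60, "A" * 60, "I" * 60)
        call = assign_species("f", {"graft": None, "host": None})
        with pytest.raises(ValueError, match="truth"):
            confusion([call], [frag])


class TestFalsePositiveAnatomy:
    @pytest.fixture()
    def genome(self):
        return Genome("graft", [Locus("gA", "A" * 1000, [(300, 700)]),
                                Locus("gB", "C" * 1000, [])])

    def _false_call(self, fid, locus, start, end):
        return assign_species(
            fid, {"graft": _hit("graft", 0.95, locus, start, end), "host": None}
        )

    def _host_frag(self, fid):
        return ReadRecord(fid, "A" * 60, "I" * 60, "A" * 60, "I" * 60,
                          truth=Truth("host", "x", 0, 120))

    def test_inside_exon_is_genic(self, genome):
        calls = [self._false_call("f0", "gA", 400, 600)]
        frags = [self._host_frag("f0")]
        an = false_positive_anatomy(calls, frags, genome)
        assert an.genic_fraction == 1.0

    def test_flank_is_non_exon(self, genome):
        calls = [self._false_call("f0", "gA", 0, 200)]
        an = false_positive_anatomy(calls, [self._host_frag("f0")], genome)
        assert an.non_exon_fraction == 1.0

    def test_three_genic_one_non_exon(self, genome):
        calls = [
            self._false_call("f0", "gA", 350, 550),
            self._false_call("f1", "gA", 690, 890),  # 10-base exon overlap: genic
            self._false_call("f2", "gA", 299, 499),
            self._false_call("f3", "gB", 100, 300),  # unannotated locus
        ]
        frags = [self._host_frag(f"f{i}") for i in range(4)]
        an = false_positive_anatomy(calls, frags, genome)
        assert an.genic_fraction == pytest.approx(0.75)
        assert an.non_exon_fraction == pytest.approx(0.25)

    def test_no_false_positives_gives_nan(self, genome):
        an = false_positive_anatomy([], [], genome)
        assert math.isnan(an.genic_fraction)


def test_theta_monotonicity(pair8, pools8):
    """Raising theta can only move fragments toward unaligned, never create
    new false assignments."""
    graft, host = pools8
    mixture = mix_reads(graft, host, 0.3, 600, seed=10)
    false_counts = []
    for theta in (0.85, 0.90, 0.95):
        aligner = DualAligner(pair8, AlignParams(theta=theta))
        calls = sort_readset(mixture, aligner)
        rep = confusion(calls, mixture)
        false_counts.append(
            int(rep.counts.loc["host", "graft"] + rep.counts.loc["graft", "host"])
        )
    assert false_counts[0] >= false_counts[1] >= false_counts[2]
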