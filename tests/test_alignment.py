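"""Genome alignment, signal attachment, list averaging and baselines."""

import math

import numpy as np
import pytest

from methylsem import alignment as al
from methylsem.io import Genome, IntervalSet, Motif, SignalTrack, revcomp

from _oracle import dense_signal, find_occurrences, footprint_mean


def toy_genome(seq="TTAACGTTGG"):
    return Genome({"chr1": seq})


def full_region(genome):
    return IntervalSet.from_tuples(
        [(c, 0, len(s)) for c, s in genome.sequences.items()]
    )


class TestAlignKmers:
    def test_both_strand_hits_on_toy_genome(self):
        genome = toy_genome("TTAACGTT")
        hits = al.align_kmers(genome, {"AACG"}, full_region(genome))
        locs = {(o.start, o.strand) for o in hits["AACG"]}
        # plus-strand AACG at 2; minus-strand at 4 (revcomp CGTT)
        assert locs == {(2, "+"), (4, "-")}

    def test_footprint_must_be_contained_in_region(self):
        genome = toy_genome("TTAACGTT")
        regions = IntervalSet.from_tuples([("chr1", 0, 5)])  # cuts AACG at 2..6
        hits = al.align_kmers(genome, {"AACG"}, regions)
        assert hits["AACG"] == []

    def test_palindrome_yields_two_strand_observations(self):
        genome = toy_genome("TTACGTAA")
        hits = al.align_kmers(genome, {"ACGT"}, full_region(genome))
        locs = {(o.start, o.strand) for o in hits["ACGT"]}
        assert locs == {(2, "+"), (2, "-")}

    def test_matches_sliding_window_oracle_on_random_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = Genome({"chr1": seq})
        regions = IntervalSet.from_tuples(
            [("chr1", 100, 700), ("chr1", 900, 1800)]
        )
        kmer_set = {"ACGTA", "TTTTT", "GCGCG", "TACGT"}
        hits = al.align_kmers(genome, kmer_set, regions)
        for kmer in kmer_set:
            expected = find_occurrences(genome, kmer, regions)
            got = sorted((o.chrom, o.start, o.strand) for o in hits[kmer])
            assert got == expected

    def test_n_bases_never_match(self):
        # an N in the genome can never equal a kmer base: AACG matches the
        # N-free genome but not the one with the second A replaced by N
        clean = toy_genome("TTAACGTT")
        masked = toy_genome("TTANCGTT")
        region = full_region(clean)
        clean_hits = {
            (o.start, o.strand)
            for o in al.align_kmers(clean, {"AACG"}, region)["AACG"]
        }
        assert clean_hits == {(2, "+"), (4, "-")}
        masked_hits = {
            (o.start, o.strand)
            for o in al.align_kmers(masked, {"AACG"}, region)["AACG"]
        }
        # the plus-strand window now covers the N and no longer matches;
        # the minus-strand footprint (CGTT at 4) is untouched
        assert masked_hits == {(4, "-")}
        # kmers themselves must be ACGT-only
        with pytest.raises(ValueError, match="ACGT"):
            al.align_kmers(masked, {"ANCG"}, region)


class TestAttachSignal:
    def test_constant_track_gives_constant_signal(self):
        genome = toy_genome("TTAACGTT")
        track = SignalTrack.from_records([("chr1", 0, 8, 3.5)])
        obs = al.align_kmers(genome, {"AACG"}, full_region(genome))["AACG"]
        for o in al.attach_signal(obs, track):
            assert o.signal == pytest.approx(3.5)

    def test_partial_coverage_mean_matches_per_base_oracle(self):
        track = SignalTrack.from_records([("chr1", 0, 2, 2.0)])
        genome = toy_genome("AACGAACG")
        obs = al.align_kmers(genome, {"AACG"}, full_region(genome))["AACG"]
        attached = al.attach_signal(obs, track)
        dense = dense_signal(track)
        for o in attached:
            assert o.signal == pytest.approx(
                footprint_mean(dense, "chr1", o.start, o.end)
            )
        by_start = {o.start: o.signal for o in attached if o.strand == "+"}
        assert by_start[0] == pytest.approx(1.0)  # half footprint at 2.0
        assert by_start[4] == pytest.approx(0.0)

    def test_empty_track_gives_zero(self):
        genome = toy_genome("AACGAACG")
        obs = al.align_kmers(genome, {"AACG"}, full_region(genome))["AACG"]
        assert all(o.signal == 0.0 for o in al.attach_signal(obs, SignalTrack()))

    def test_max_statistic_option(self):
        genome = toy_genome("TTAACGTT")
        track = SignalTrack.from_records([("chr1", 2, 4, 1.0), ("chr1", 4, 6, 9.0)])
        obs = al.align_kmers(genome, {"AACG"}, full_region(genome))["AACG"]
        plus = [o for o in al.attach_signal(obs, track, stat="max") if o.strand == "+"]
        assert plus[0].signal == pytest.approx(9.0)


class TestAverages:
    def test_equal_values(self):
        obs = [al.AlignedObservation("c", 0, "+", "AA", signal=4.0)] * 2
        assert al.average_list(obs) == (4.0, 0.0, 2)

    def test_hand_arithmetic_stderr(self):
        obs = [
            al.AlignedObservation("c", 0, "+", "AA", signal=2.0),
            al.AlignedObservation("c", 5, "+", "AA", signal=6.0),
        ]
        mean, stderr, n = al.average_list(obs)
        assert mean == pytest.approx(4.0)
        # sample sd = 2*sqrt(2), stderr = sd/sqrt(2) = 2
        assert stderr == pytest.approx(2.0)
        assert n == 2

    def test_empty_list_undefined(self):
        mean, stderr, n = al.average_list([])
        assert math.isnan(mean) and math.isnan(stderr) and n == 0

    def test_mean_within_list_range(self, rng):
        values = rng.uniform(0, 50, size=17)
        obs = [
            al.AlignedObservation("c", i, "+", "AA", signal=v)
            for i, v in enumerate(values)
        ]
        mean, _, _ = al.average_list(obs)
        assert values.min() <= mean <= values.max()


class TestBaselines:
    def test_endogenous_is_mean_over_universe_alignments(self):
        assert al.endogenous_baseline([2.0, 4.0, 6.0]) == pytest.approx(4.0)

    def test_endogenous_errors_on_empty_or_zero(self):
        with pytest.raises(ValueError, match="baseline"):
            al.endogenous_baseline([])
        with pytest.raises(ValueError, match="zero"):
            al.endogenous_baseline([0.0, 0.0])

    def test_scrambled_equal_signal_gives_zero(self):
        assert al.scrambled_baseline([5.0, 5.0], endogenous=5.0) == pytest.approx(0.0)

    def test_scrambled_fallback_uses_smallest_positive_track_value(self):
        track = SignalTrack.from_records([("chr1", 0, 5, 0.125), ("chr1", 5, 9, 8.0)])
        value = al.scrambled_baseline([], endogenous=8.0, track=track)
        assert value == pytest.approx(math.log2(0.125 / 8.0))

    def test_scrambled_low_signal_is_negative(self):
        assert al.scrambled_baseline([0.01], endogenous=10.0) < -5


class TestRefineIterate:
    def _setup(self, rng, all_deleterious=False):
        from methylsem.synth import SyntheticTruth, build_fixture, demo_exact_truth

        if all_deleterious:
            # every variant binds worse than the consensus, so the motif
            # rebuilt from mean signal keeps the same optimum
            gen = np.random.default_rng(1)
            effect = np.zeros((5, 6))
            consensus = "ATCTG"
            for i, letter in enumerate(consensus):
                for b, col in zip("ACGT", range(4)):
                    if b != letter:
                        effect[i, col] = gen.uniform(-3.0, -0.5)
            truth = SyntheticTruth(consensus=consensus, effect=effect,
                                   fixed_fractions={})
        else:
            truth = demo_exact_truth(1)
        genome, sites, peaks, signal, meth, motif = build_fixture(
            truth, n_sites=150, genome_length=12000, seed=1, mode="cycle",
            forbidden_radius=1,
        )
        return genome, peaks, signal, motif

    def test_single_iteration_independent_of_tol(self, rng):
        genome, peaks, signal, motif = self._setup(rng)
        out_a = al.refine_iterate(motif, genome, peaks, signal, max_iter=1, tol=1e-3)
        out_b = al.refine_iterate(motif, genome, peaks, signal, max_iter=1, tol=0.5)
        assert out_a[0] == out_b[0]
        assert np.allclose(out_a[3][0], out_b[3][0], equal_nan=True)

    def test_matching_start_motif_converges_quickly(self, rng):
        genome, peaks, signal, motif = self._setup(rng, all_deleterious=True)
        universe, lists, aligned, raw, trace = al.refine_iterate(
            motif, genome, peaks, signal, max_iter=4, tol=1e-3
        )
        assert 1 <= len(trace) <= 2  # converged within two iterations
        assert trace[-1] >= 1 - 1e-3

    def test_invalid_max_iter(self, rng):
        genome, peaks, signal, motif = self._setup(rng)
        with pytest.raises(ValueError):
            al.refine_iterate(motif, genome, peaks, signal, max_iter=0)


def test_alignment_observation_matches_genome_substring(noisy_run):
    truth, parts, result = noisy_run
    genome = parts[0]
    for obs_list in result.kmer_alignments.values():
        for o in obs_list[:3]:
            window = genome.sequences[o.chrom][o.start : o.end]
            assert (window if o.strand == "+" else revcomp(window)) == o.kmer
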