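import itertools

import numpy as np
import pytest

from xnapore import (ConsensusTrack, LevelSequence, MeasuredLevel,
                     SimulationConfig, align_levels, build_consensus,
                     ideal_level_series, orient_for_sequence,
                     simulate_level_read)
from xnapore.align import DEFAULT_MOVE_PENALTIES, gaussian_loglik
from xnapore.simulate import config_with_seed

from conftest import make_steps


def read_from_means(means, rate=5000.0):
    levels = [MeasuredLevel(float(m), 0.5, 0.05, i * 250)
              for i, m in enumerate(means)]
    return LevelSequence(levels, rate, "test")


def brute_force_alignment_score(means, ref, emission_sd, pen):
    """Oracle: enumerate every legal alignment recursively."""
    n, m = len(means), len(ref)
    emit = gaussian_loglik(np.asarray(means), np.asarray(ref), emission_sd)

    def best(i, p):
        if i == n:
            return 0.0 if p == m else -np.inf
        cands = []
        if p + 1 <= m:
            cands.append(emit[i, p] + pen["step"] + best(i + 1, p + 1))
        if p >= 1 and p + 2 <= m:
            cands.append(emit[i, p + 1] + pen["skip"] + best(i + 1, p + 2))
        if p >= 1:
            cands.append(emit[i, p - 1] + pen["stay_backstep"] + best(i + 1, p))
        if p >= 2:
            cands.append(emit[i, p - 2] + pen["stay_backstep"] + best(i + 1, p - 1))
        cands.append(pen["spurious"] + best(i + 1, p))
        return max(cands)

    return best(0, 0)


class TestAlignment:
    def test_perfect_read_identity_alignment(self, steps_phi29):
        read = read_from_means(steps_phi29.temporal_currents())
        aln = align_levels(read, steps_phi29)
        assert [a for a, _ in aln.assignments] == list(
            range(1, len(steps_phi29) + 1))
        assert all(m == "step" for _, m in aln.assignments)

    def test_duplicated_level_labeled_stay_backstep(self, steps_phi29):
        cur = list(steps_phi29.temporal_currents())
        dup = cur[:8] + [cur[7]] + cur[8:]
        aln = align_levels(read_from_means(dup), steps_phi29)
        moves = [m for _, m in aln.assignments]
        assert moves.count("stay_backstep") == 1
        assert moves[8] == "stay_backstep"
        assert aln.assignments[8][0] == 8
        assert all(m == "step" for i, m in enumerate(moves) if i != 8)

    def test_backstep_pattern_recovered(self, steps_phi29):
        cur = list(steps_phi29.temporal_currents())
        # enzyme pattern: ... 8, 7, 8, 9 ... (one-level retraction)
        walk = cur[:8] + [cur[6], cur[7]] + cur[8:]
        aln = align_levels(read_from_means(walk), steps_phi29)
        refs = [a for a, _ in aln.assignments]
        assert refs[:11] == [1, 2, 3, 4, 5, 6, 7, 8, 7, 8, 9]

    def test_skipped_level_recovered(self, steps_phi29):
        cur = list(steps_phi29.temporal_currents())
        missing = cur[:8] + cur[9:]  # level 9 never emitted
        aln = align_levels(read_from_means(missing), steps_phi29)
        moves = [m for _, m in aln.assignments]
        assert moves.count("skip") == 1
        assert aln.assignments[8] == (10, "skip")

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_score_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 7))
        n = int(rng.integers(max(1, m - 2), 7))
        ref = rng.uniform(20, 60, size=m)
        means = rng.uniform(20, 60, size=n)
        read = read_from_means(means)
        try:
            aln = align_levels(read, make_steps(ref), emission_sd=2.0)
        except ValueError:
            # no legal alignment; oracle must agree it is impossible
            assert brute_force_alignment_score(
                means, ref, 2.0, DEFAULT_MOVE_PENALTIES) == -np.inf
            return
        oracle = brute_force_alignment_score(means, ref, 2.0,
                                             DEFAULT_MOVE_PENALTIES)
        assert aln.score == pytest.approx(oracle)

    def test_sharper_emission_penalizes_mismatched_read(self, steps_phi29):
        # a uniformly offset read: every emission is a 4 pA mismatch, so
        # sharpening the emission model must lower the attainable score
        read = read_from_means(steps_phi29.temporal_currents() + 4.0)
        scores = [align_levels(read, steps_phi29, emission_sd=sd).score
                  for sd in (3.0, 1.5, 0.75)]
        assert scores[0] > scores[1] > scores[2]

    def test_empty_inputs_rejected(self, steps_phi29):
        with pytest.raises(ValueError):
            align_levels(LevelSequence([], 5000.0), steps_phi29)


class TestConsensus:
    def test_identical_reads_zero_sd(self, steps_phi29):
        read = read_from_means(steps_phi29.temporal_currents())
        reads = [read] * 5
        alns = [align_levels(r, steps_phi29) for r in reads]
        track = build_consensus(alns, reads, steps_phi29)
        np.testing.assert_allclose(track.mean, steps_phi29.temporal_currents())
        np.testing.assert_allclose(track.sd, 0.0, atol=1e-9)
        assert np.all(track.n_reads == 5)

    def test_se_definition(self, steps_phi29):
        cfg = SimulationConfig(seed=0)
        reads = [simulate_level_read(steps_phi29, config_with_seed(cfg, s))
                 for s in range(8)]
        alns = [align_levels(r, steps_phi29) for r in reads]
        track = build_consensus(alns, reads, steps_phi29)
        cov = track.n_reads > 1
        np.testing.assert_allclose(track.se[cov] * np.sqrt(track.n_reads[cov]),
                                   track.sd[cov])
        assert np.all(track.se[cov] <= track.sd[cov] + 1e-12)

    def test_permutation_invariance(self, steps_phi29):
        cfg = SimulationConfig(seed=1)
        reads = [simulate_level_read(steps_phi29, config_with_seed(cfg, s))
                 for s in range(6)]
        alns = [align_levels(r, steps_phi29) for r in reads]
        fwd = build_consensus(alns, reads, steps_phi29)
        rev = build_consensus(alns[::-1], reads[::-1], steps_phi29)
        np.testing.assert_allclose(fwd.mean, rev.mean)
        np.testing.assert_allclose(fwd.sd, rev.sd)

    def test_consensus_tracks_truth_at_41_reads(self, steps_phi29):
        cfg = SimulationConfig(seed=2)
        reads = [simulate_level_read(steps_phi29, config_with_seed(cfg, 500 + s))
                 for s in range(41)]
        alns = [align_levels(r, steps_phi29) for r in reads]
        track = build_consensus(alns, reads, steps_phi29)
        truth = steps_phi29.temporal_currents()
        ok = np.abs(track.mean - truth) <= 2 * np.maximum(track.se, 1e-9)
        assert ok.mean() >= 0.90

    def test_min_score_floor_rejects_reads(self, steps_phi29):
        good = read_from_means(steps_phi29.temporal_currents())
        bad = read_from_means(steps_phi29.temporal_currents() + 20.0)
        alns = [align_levels(r, steps_phi29) for r in (good, bad)]
        track = build_consensus(alns, [good, bad], steps_phi29,
                                min_score=alns[0].score - 1)
        assert track.metadata["n_reads_used"] == 1
        with pytest.raises(ValueError):
            build_consensus([alns[1]], [bad], steps_phi29,
                            min_score=alns[0].score)

    def test_rms_error_shrinks_with_ensemble_size(self, steps_phi29):
        cfg = SimulationConfig(seed=3)
        truth = steps_phi29.temporal_currents()
        rms = []
        seed0 = 0
        for n in (5, 41):
            reads = [simulate_level_read(steps_phi29,
                                         config_with_seed(cfg, seed0 + s))
                     for s in range(n)]
            seed0 += n
            alns = [align_levels(r, steps_phi29) for r in reads]
            track = build_consensus(alns, reads, steps_phi29)
            rms.append(float(np.sqrt(np.nanmean((track.mean - truth) ** 2))))
        assert rms[1] < rms[0]


class TestOrientation:
    def test_phi29_unchanged(self, steps_phi29):
        track = ConsensusTrack(np.arange(5.0), np.ones(5), np.ones(5) / 2,
                               np.full(5, 4), "phi29")
        assert orient_for_sequence(track) is track

    def test_hel308_reversal_and_involution(self):
        track = ConsensusTrack(np.arange(7.0), np.ones(7), np.ones(7) / 2,
                               np.full(7, 4), "hel308", orientation="time")
        flipped = orient_for_sequence(track)
        assert flipped.orientation == "sequence"
        # index i maps to n+1-i
        np.testing.assert_allclose(flipped.mean, track.mean[::-1])
        back = orient_for_sequence(flipped)
        np.testing.assert_allclose(back.mean, track.mean)
        assert back.orientation == "time"

    def test_hel308_round_trip_recovers_sequence_order(self, context_seq,
                                                       table4):
        steps = ideal_level_series(context_seq, table4, "hel308")
        read = read_from_means(steps.temporal_currents())
        aln = align_levels(read, steps)
        track = orient_for_sequence(build_consensus([aln], [read], steps))
        np.testing.assert_allclose(track.mean, steps.currents)


def test_consensus_tsv_round_trip(tmp_path, steps_phi29):
    read = read_from_means(steps_phi29.temporal_currents())
    aln = align_levels(read, steps_phi29)
    track = build_consensus([aln], [read], steps_phi29)
    path = tmp_path / "c.tsv"
    track.to_tsv(path)
    back = ConsensusTrack.from_tsv(path)
    np.testing.assert_allclose(back.mean, track.mean)
    assert back.enzyme_mode == "phi29"
    assert list(back.n_reads) == list(track.n_reads)
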